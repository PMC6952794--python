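"""Shared fixtures: a small published-style Ct fixture and helpers.

The ``panel_matrix`` fixture reproduces the four germ-cell-tumor cell-line
blocks (cells vs matched conditioned medium) of the canonical worked table,
with the shared fetal-calf-serum negative control at the non-detect
sentinel for every human assay.
"""

import pandas as pd
import pytest

from liqmir import CtMatrix, Material, Role, SampleMeta

# (assay, cell Ct, media Ct) per cell line; 40 encodes a non-detect.
TABLE_BLOCKS = {
    "TCam-2": [
        ("hsa-miR-371a-3p", 25.4, 25.9),
        ("hsa-miR-372-3p", 19.8, 20.9),
        ("hsa-miR-373-3p", 27.3, 24.7),
        ("hsa-miR-367", 24.6, 26.0),
    ],
    "NT2": [
        ("hsa-miR-371a-3p", 33.4, 33.2),
        ("hsa-miR-372-3p", 28.4, 40.0),
        ("hsa-miR-373-3p", 40.0, 40.0),
        ("hsa-miR-367", 17.4, 23.7),
    ],
    "NCCIT": [
        ("hsa-miR-371a-3p", 31.3, 33.0),
        ("hsa-miR-372-3p", 25.9, 26.6),
        ("hsa-miR-373-3p", 29.8, 40.0),
        ("hsa-miR-367", 20.9, 27.2),
    ],
    "2102Ep": [
        ("hsa-miR-371a-3p", 27.1, 26.7),
        ("hsa-miR-372-3p", 21.5, 22.4),
        ("hsa-miR-373-3p", 30.4, 26.1),
        ("hsa-miR-367", 26.5, 24.6),
    ],
}


@pytest.fixture()
def panel_matrix() -> CtMatrix:
    assays = [a for a, _, _ in TABLE_BLOCKS["TCam-2"]]
    data = {}
    for line, rows in TABLE_BLOCKS.items():
        data[f"{line}_cells"] = [c for _, c, _ in rows]
        data[f"{line}_media"] = [m for _, _, m in rows]
    data["FCS"] = [40.0] * len(assays)
    return CtMatrix(pd.DataFrame(data, index=assays))


@pytest.fixture()
def panel_meta() -> list[SampleMeta]:
    meta = []
    for line in TABLE_BLOCKS:
        meta.append(SampleMeta(f"{line}_cells", Material.CELLS, Role.CASE, line))
        meta.append(SampleMeta(f"{line}_media", Material.MEDIUM, Role.CASE, line))
    meta.append(SampleMeta("FCS", Material.FCS, Role.BACKGROUND, "FCS"))
    return meta
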