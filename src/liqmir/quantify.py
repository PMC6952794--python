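"""Relative quantification by the 2^-ddCt method.

Each sample is first normalized within itself: dCt = Ct(target) -
Ct(normalizer), with hsa-miR-30b-5p as the default endogenous reference.
Relative levels are then expressed against a calibrator:

* **control-mean mode** (default) — ddCt = dCt - mean dCt of the control
  group, so the control group's mean log2 relative level is exactly 0;
* **highest-Ct mode** — the least-abundant evaluable sample serves as the
  calibrator (used when controls are part of the comparison itself rather
  than a baseline).

Reported values are log2 relative levels, log2_rel = -ddCt (the log2 of
2^-ddCt); the fold change 2^-ddCt is strictly positive by construction.

Non-detect handling: a sample whose *normalizer* is non-detect is not
evaluable (no within-sample scale exists).  A non-detect *target* is, by
default, also not evaluable; under the ``"ceiling"`` policy its Ct is
censored at the non-detect sentinel and the resulting dCt flagged as a
lower bound on Ct, i.e. an upper bound on abundance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import CtMatrix, SampleMeta

__all__ = ["RelQuant", "delta_ct", "delta_delta_ct", "reference_sample_mode"]


@dataclass(frozen=True)
class RelQuant:
    """Relative quantification of one assay in one sample."""

    sample_id: str
    assay: str
    delta_ct: float
    delta_delta_ct: float
    log2_rel: float
    censored: bool = False

    @property
    def fold_change(self) -> float:
        """2^-ddCt, strictly positive."""
        return float(2.0 ** self.log2_rel)


def delta_ct(
    matrix: CtMatrix,
    assay: str,
    normalizer: str,
    nondetect_policy: str = "drop",
) -> pd.DataFrame:
    """Per-sample dCt = Ct(target) - Ct(normalizer).

    Returns a DataFrame indexed by sample with columns ``delta_ct`` (NaN
    when not evaluable) and ``censored`` (target was non-detect and the
    ceiling policy applied).  ``nondetect_policy`` is ``"drop"`` (target
    non-detect -> not evaluable) or ``"ceiling"`` (censor at the sentinel).
    """
    if normalizer not in matrix.assays:
        raise ValueError(f"normalizer {normalizer!r} absent from panel")
    if assay not in matrix.assays:
        raise ValueError(f"assay {assay!r} absent from panel")
    if nondetect_policy not in ("drop", "ceiling"):
        raise ValueError(f"unknown nondetect policy {nondetect_policy!r}")
    target = matrix.ct.loc[assay].astype(float)
    norm = matrix.ct.loc[normalizer].astype(float)
    code = matrix.nondetect_code
    dct = target - norm
    censored = (target >= code) & (norm < code)
    evaluable = norm < code
    if nondetect_policy == "drop":
        evaluable &= target < code
        censored &= False
    dct[~evaluable] = np.nan
    return pd.DataFrame({"delta_ct": dct, "censored": censored & evaluable})


def delta_delta_ct(
    matrix: CtMatrix,
    meta: Sequence[SampleMeta],
    assay: str,
    normalizer: str,
    control_group: str,
    nondetect_policy: str = "drop",
) -> list[RelQuant]:
    """ddCt of every evaluable sample relative to the control-group mean dCt.

    The calibrator is the arithmetic mean dCt of evaluable samples whose
    metadata ``group`` equals ``control_group``; their mean log2_rel is 0 by
    construction.  Raises when no control is evaluable.
    """
    dct = delta_ct(matrix, assay, normalizer, nondetect_policy)
    control_ids = [m.sample_id for m in meta
                   if m.group == control_group and m.sample_id in dct.index]
    control_vals = dct.loc[control_ids, "delta_ct"].dropna()
    if control_vals.empty:
        raise ValueError(
            f"no evaluable control sample in group {control_group!r}"
        )
    calibrator = float(control_vals.mean())
    out = []
    for m in meta:
        if m.sample_id not in dct.index:
            continue
        d = dct.at[m.sample_id, "delta_ct"]
        if np.isnan(d):
            continue
        ddct = float(d) - calibrator
        out.append(RelQuant(
            sample_id=m.sample_id,
            assay=assay,
            delta_ct=float(d),
            delta_delta_ct=ddct,
            log2_rel=-ddct,
            censored=bool(dct.at[m.sample_id, "censored"]),
        ))
    return out


def reference_sample_mode(
    matrix: CtMatrix,
    meta: Sequence[SampleMeta],
    assay: str,
    normalizer: str | None = None,
    nondetect_policy: str = "drop",
) -> str:
    """Calibrator sample under the highest-Ct convention.

    Returns the evaluable sample with the highest dCt (least abundant),
    used as reference when controls are included in the comparison itself.
    Ties break toward the lexicographically first sample id.
    """
    from .core_io import StudyConfig

    normalizer = normalizer or StudyConfig().normalizer_assay
    dct = delta_ct(matrix, assay, normalizer, nondetect_policy)["delta_ct"]
    ids = [m.sample_id for m in meta if m.sample_id in dct.index]
    vals = dct.loc[ids].dropna()
    if vals.empty:
        raise ValueError("no evaluable sample to serve as calibrator")
    top = vals.max()
    return sorted(vals.index[vals == top])[0]


def relquant_frame(rel: Sequence[RelQuant]) -> pd.DataFrame:
    """Tabulate RelQuant rows (the CSV output of the quantify step)."""
    return pd.DataFrame([r.__dict__ for r in rel])
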