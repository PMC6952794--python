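"""Data model and I/O for RT-qPCR Ct matrices and sample metadata.

The pipeline's universal currency is the Ct matrix: one quantification-cycle
value per (microRNA assay, sample).  Non-detects ("Undetermined" wells) are
stored as a sentinel Ct, 40 cycles by default, matching the instrument's
cycle limit; a boolean non-detect mask is always derivable and never stored.

Supported table dialects:

* ``wide``  — assay rows x sample columns, first column holds assay ids
              (canonical for fixtures and array-card exports);
* ``long``  — three columns ``assay,sample,ct``, one row per well.

Duplicate wells (technical replicates, or the same assay appearing on two
array cards) are collapsed by arithmetic mean on the Ct (log) scale.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_NONDETECT_CT",
    "UNDETERMINED_TOKENS",
    "Material",
    "Role",
    "CtMatrix",
    "SampleMeta",
    "StudyConfig",
    "CtTableError",
    "read_ct_table",
    "write_ct_table",
    "merge_runs",
    "read_sample_meta",
    "write_sample_meta",
    "read_config",
    "write_config",
]

#: Sentinel Ct encoding "Undetermined" / no amplification within the run.
DEFAULT_NONDETECT_CT = 40.0

#: Tokens in input files mapped to the non-detect sentinel (case-insensitive).
UNDETERMINED_TOKENS = {"undetermined", "undet", "n/a", "na", ""}


class CtTableError(ValueError):
    """Malformed Ct table or metadata file."""


class Material(str, Enum):
    """Biological material a sample was derived from."""

    CELLS = "cells"
    MEDIUM = "medium"
    FCS = "fcs"
    XENOGRAFT = "xenograft"
    PLASMA = "plasma"
    SERUM = "serum"
    CSF = "csf"
    TISSUE_MIX = "tissue_mix"


class Role(str, Enum):
    """Analytic role of a sample in a comparison."""

    CASE = "case"
    CONTROL = "control"
    BACKGROUND = "background"


@dataclass(frozen=True)
class CtMatrix:
    """Rectangular table of Ct values, assays x samples.

    Parameters
    ----------
    ct
        DataFrame indexed by assay identifier with one column per sample.
        Every value must be finite and lie in ``(0, nondetect_code]``.
    nondetect_code
        Ct value encoding a non-detect, default 40 cycles.
    """

    ct: pd.DataFrame
    nondetect_code: float = DEFAULT_NONDETECT_CT

    def __post_init__(self) -> None:
        if self.ct.index.has_duplicates:
            raise CtTableError("duplicate assay identifiers")
        if self.ct.columns.has_duplicates:
            raise CtTableError("duplicate sample identifiers")
        vals = self.ct.to_numpy(dtype=float)
        if vals.size and not np.all(np.isfinite(vals)):
            raise CtTableError("non-finite Ct value")
        if vals.size and (np.any(vals <= 0) or np.any(vals > self.nondetect_code)):
            raise CtTableError(
                f"Ct values must lie in (0, {self.nondetect_code}]"
            )

    @property
    def assays(self) -> list[str]:
        return list(self.ct.index)

    @property
    def samples(self) -> list[str]:
        return list(self.ct.columns)

    def value(self, assay: str, sample: str) -> float:
        return float(self.ct.at[assay, sample])

    def is_nondetect(self) -> pd.DataFrame:
        """Boolean mask of non-detect cells (Ct at the sentinel)."""
        return self.ct >= self.nondetect_code

    def subset_samples(self, samples: Sequence[str]) -> "CtMatrix":
        return CtMatrix(self.ct.loc[:, list(samples)].copy(), self.nondetect_code)

    def equals(self, other: "CtMatrix") -> bool:
        return (
            self.nondetect_code == other.nondetect_code
            and self.ct.shape == other.ct.shape
            and list(self.ct.index) == list(other.ct.index)
            and list(self.ct.columns) == list(other.ct.columns)
            and np.allclose(self.ct.to_numpy(), other.ct.to_numpy(), atol=0.0)
        )


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotation driving filters and comparisons."""

    sample_id: str
    material: Material
    role: Role
    group: str = ""
    hemolysis_score: int | None = None
    time_h: float | None = None
    paired_with: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "material", Material(self.material))
        object.__setattr__(self, "role", Role(self.role))
        if self.hemolysis_score is not None and self.hemolysis_score not in range(6):
            raise ValueError("hemolysis_score must be in 0..5")
        if self.material is Material.FCS and self.role is not Role.BACKGROUND:
            raise ValueError("fetal calf serum samples must have role=background")


def validate_meta(meta: Iterable[SampleMeta]) -> list[SampleMeta]:
    """Check cross-record invariants (unique ids, resolvable pairing)."""
    meta = list(meta)
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in metadata")
    known = set(ids)
    for m in meta:
        if m.paired_with is not None and m.paired_with not in known:
            raise ValueError(f"paired_with refers to unknown sample {m.paired_with!r}")
    return meta


@dataclass(frozen=True)
class StudyConfig:
    """Run-level thresholds and assay identities.

    Defaults encode the shipped analysis conventions: detection calls use a
    strict Ct < 34 rule, spike-in recovery must stay within +/-2 Ct of the
    cohort median, and the miR-23a/451a hemolysis ratio ships with a 9.15
    cutoff (recalibratable per cohort).
    """

    detection_threshold: float = 34.0
    spike_assay: str = "ath-miR-159a"
    spike_tolerance: float = 2.0
    normalizer_assay: str = "hsa-miR-30b-5p"
    hemolysis_cutoff: float = 9.15
    plasma_detection_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.detection_threshold < DEFAULT_NONDETECT_CT:
            raise ValueError("detection_threshold must be in (0, nondetect_code)")
        if self.spike_tolerance <= 0:
            raise ValueError("spike_tolerance must be positive")
        if not 0 <= self.plasma_detection_fraction <= 1:
            raise ValueError("plasma_detection_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# Ct table reading / writing
# ---------------------------------------------------------------------------

def _parse_ct_cell(raw: object, nondetect_code: float, where: str) -> float:
    if isinstance(raw, float) and np.isnan(raw):
        return nondetect_code
    text = str(raw).strip()
    if text.lower() in UNDETERMINED_TOKENS:
        return nondetect_code
    try:
        val = float(text)
    except ValueError as exc:
        raise CtTableError(f"non-numeric Ct {text!r} at {where}") from exc
    return val


def read_ct_table(
    path: str | os.PathLike,
    dialect: str = "wide",
    nondetect_code: float = DEFAULT_NONDETECT_CT,
) -> CtMatrix:
    """Read a Ct table from CSV.

    Cells holding the undetermined token (or left blank) are mapped to
    ``nondetect_code``; duplicate (assay, sample) pairs are collapsed by
    arithmetic mean Ct.
    """
    if dialect not in ("wide", "long"):
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect == "wide":
        if raw.shape[1] < 1:
            raise CtTableError("wide table needs an assay column")
        assay_col = raw.columns[0]
        long = raw.melt(id_vars=[assay_col], var_name="sample", value_name="ct")
        long = long.rename(columns={assay_col: "assay"})
    else:
        required = {"assay", "sample", "ct"}
        missing = required - set(raw.columns)
        if missing:
            raise CtTableError(
                f"long table missing column(s): {', '.join(sorted(missing))}"
            )
        long = raw[["assay", "sample", "ct"]].copy()
    long["ct"] = [
        _parse_ct_cell(v, nondetect_code, f"row {i}")
        for i, v in enumerate(long["ct"])
    ]
    wide = (
        long.groupby(["assay", "sample"], sort=False)["ct"]
        .mean()
        .unstack("sample")
    )
    # preserve first-appearance order
    wide = wide.reindex(index=pd.unique(long["assay"]),
                        columns=pd.unique(long["sample"]))
    return CtMatrix(wide, nondetect_code)


def write_ct_table(matrix: CtMatrix, path: str | os.PathLike) -> str:
    """Write a Ct matrix as a wide CSV; non-detects serialize as 'Undetermined'.

    Round-trips exactly through :func:`read_ct_table`.
    """
    out = matrix.ct.copy().astype(object)
    mask = matrix.is_nondetect()
    out = out.where(~mask, "Undetermined")
    out.index.name = "assay"
    out.to_csv(path)
    return str(path)


def merge_runs(matrices: Sequence[CtMatrix]) -> CtMatrix:
    """Merge several runs (e.g. array cards A+B) over an identical sample set.

    Assay sets may be disjoint (union taken) or overlap (overlapping assays
    averaged per sample on the Ct scale).
    """
    if not matrices:
        raise ValueError("no matrices to merge")
    codes = {m.nondetect_code for m in matrices}
    if len(codes) > 1:
        raise CtTableError(f"conflicting nondetect_code values: {sorted(codes)}")
    sample_sets = {tuple(sorted(m.samples)) for m in matrices}
    if len(sample_sets) > 1:
        raise CtTableError("sample sets differ across runs")
    samples = matrices[0].samples
    stacked = pd.concat([m.ct[samples] for m in matrices])
    merged = stacked.groupby(level=0, sort=False).mean()
    order = list(pd.unique(stacked.index))
    return CtMatrix(merged.loc[order], matrices[0].nondetect_code)


# ---------------------------------------------------------------------------
# Sample metadata and config files
# ---------------------------------------------------------------------------

_META_COLS = [
    "sample_id", "material", "role", "group",
    "hemolysis_score", "time_h", "paired_with",
]


def read_sample_meta(path: str | os.PathLike) -> list[SampleMeta]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"sample_id", "material", "role"} - set(df.columns)
    if missing:
        raise CtTableError(
            f"metadata missing column(s): {', '.join(sorted(missing))}"
        )
    out: list[SampleMeta] = []
    for _, row in df.iterrows():
        def opt(col: str) -> str | None:
            v = str(row[col]).strip() if col in df.columns else ""
            return v or None

        score = opt("hemolysis_score")
        t = opt("time_h")
        out.append(
            SampleMeta(
                sample_id=row["sample_id"],
                material=Material(row["material"]),
                role=Role(row["role"]),
                group=opt("group") or "",
                hemolysis_score=int(score) if score is not None else None,
                time_h=float(t) if t is not None else None,
                paired_with=opt("paired_with"),
            )
        )
    return validate_meta(out)


def write_sample_meta(meta: Sequence[SampleMeta], path: str | os.PathLike) -> str:
    rows = []
    for m in meta:
        rows.append({
            "sample_id": m.sample_id,
            "material": m.material.value,
            "role": m.role.value,
            "group": m.group,
            "hemolysis_score": "" if m.hemolysis_score is None else m.hemolysis_score,
            "time_h": "" if m.time_h is None else m.time_h,
            "paired_with": m.paired_with or "",
        })
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, index=False)
    return str(path)


def write_config(config: StudyConfig, path: str | os.PathLike) -> str:
    """Serialize a StudyConfig as a flat key=value text file."""
    with open(path, "w") as fh:
        for f in fields(config):
            fh.write(f"{f.name}={getattr(config, f.name)}\n")
    return str(path)


def read_config(path: str | os.PathLike) -> StudyConfig:
    kwargs: dict[str, object] = {}
    types = {f.name: f.type for f in fields(StudyConfig)}
    casts = {
        "detection_threshold": float, "spike_tolerance": float,
        "hemolysis_cutoff": float, "plasma_detection_fraction": float,
        "seed": int, "spike_assay": str, "normalizer_assay": str,
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise CtTableError(f"malformed config line {lineno}: {line!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in types:
                raise CtTableError(f"unknown config key {key!r}")
            kwargs[key] = casts[key](value.strip())
    return StudyConfig(**kwargs)
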