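"""The biomarker identification model.

From a profiled Ct matrix the model proceeds in four steps:

1. **Detection filtering** — an assay is detected in a sample when its Ct is
   strictly below the detection threshold (default 34 cycles).  A Ct exactly
   at the threshold counts as NOT detected.
2. **Background subtraction** — assays detected in ANY negative-control
   sample of the matching material class (fetal calf serum for conditioned
   media; normal-animal tissue and plasma for xenograft work) are excluded:
   they reflect the culture medium or host, not the tumor.
3. **Secretion classification** — for each cell line, the matched
   cells / conditioned-medium / FCS triplet classifies every assay as
   secreted (in cells and medium, not in FCS), not_secreted (in cells only),
   background (in FCS, regardless of the rest), or not_expressed.
4. **Tissue-to-biofluid concordance** — an in-vivo candidate marker must be
   detected in ALL tumor xenografts of a histology group, absent from every
   normal-animal control, and detected in at least a configurable fraction
   (default 50%) of matched endpoint plasmas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import CtMatrix, Material, Role, SampleMeta, StudyConfig
from .validation import round_half_up

__all__ = [
    "SecretionStatus",
    "SecretionCall",
    "CandidateSet",
    "DetectionSummary",
    "detection_filter",
    "subtract_background",
    "classify_secretion",
    "detection_venn",
    "xenograft_plasma_concordance",
    "detection_summary",
    "percentage",
]

#: Which foreground materials each background material controls for.
BACKGROUND_COVERS: dict[Material, frozenset[Material]] = {
    Material.FCS: frozenset({Material.MEDIUM}),
    Material.TISSUE_MIX: frozenset({Material.XENOGRAFT, Material.TISSUE_MIX}),
    Material.PLASMA: frozenset({Material.PLASMA}),
    Material.SERUM: frozenset({Material.SERUM}),
    Material.CSF: frozenset({Material.CSF}),
    Material.CELLS: frozenset({Material.CELLS}),
    Material.MEDIUM: frozenset({Material.MEDIUM}),
    Material.XENOGRAFT: frozenset({Material.XENOGRAFT}),
}


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """Report-style percentage with half-up rounding (e.g. 101/291 -> 34.7)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, decimals)


def detection_filter(matrix: CtMatrix, config: StudyConfig) -> pd.DataFrame:
    """Boolean detection calls, one cell per (assay, sample).

    Detected means Ct strictly below ``config.detection_threshold``.
    """
    return matrix.ct < config.detection_threshold


# ---------------------------------------------------------------------------
# Background subtraction
# ---------------------------------------------------------------------------

def subtract_background(
    calls: pd.DataFrame,
    meta: Sequence[SampleMeta],
) -> dict[str, list[str]]:
    """Per-group detected assay lists after negative-control exclusion.

    A group's detected set is the union over its non-background samples; an
    assay is removed when detected in ANY background sample whose material
    class covers a material present in the group.  With no background
    samples at all, sets pass through unchanged with a warning.
    """
    meta = [m for m in meta if m.sample_id in calls.columns]
    background = [m for m in meta if m.role is Role.BACKGROUND]
    foreground = [m for m in meta if m.role is not Role.BACKGROUND]
    if not background:
        warnings.warn("no background samples; detection sets not subtracted",
                      stacklevel=2)
    out: dict[str, list[str]] = {}
    groups = sorted({m.group for m in foreground})
    for group in groups:
        members = [m for m in foreground if m.group == group]
        materials = {m.material for m in members}
        detected = calls[[m.sample_id for m in members]].any(axis=1)
        bg_ids = [b.sample_id for b in background
                  if BACKGROUND_COVERS[b.material] & materials]
        if bg_ids:
            in_background = calls[bg_ids].any(axis=1)
            detected &= ~in_background
        out[group] = sorted(detected.index[detected])
    return out


# ---------------------------------------------------------------------------
# Secretion classification
# ---------------------------------------------------------------------------

class SecretionStatus:
    SECRETED = "secreted"
    NOT_SECRETED = "not_secreted"
    BACKGROUND = "background"
    NOT_EXPRESSED = "not_expressed"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class SecretionCall:
    """Per-assay secretion label for one cell line, with the Ct evidence."""

    assay: str
    cell_line: str
    status: str
    cell_ct: float
    media_ct: float
    fcs_ct: float


def _material_mean(
    matrix: CtMatrix,
    meta: Sequence[SampleMeta],
    material: Material,
    group: str | None,
    cell_line: str,
) -> pd.Series:
    ids = [m.sample_id for m in meta
           if m.material is material
           and (group is None or m.group == group)
           and m.sample_id in matrix.samples]
    if not ids:
        which = material.value if group is None else f"{material.value} for {group}"
        raise ValueError(f"no {which} sample found for cell line {cell_line!r}")
    return matrix.ct[ids].astype(float).mean(axis=1)


def classify_secretion(
    matrix: CtMatrix,
    meta: Sequence[SampleMeta],
    cell_line: str,
    config: StudyConfig,
) -> list[SecretionCall]:
    """Classify every assay of one cell line from its cells/medium/FCS triplet.

    Rule precedence (T = detection threshold, strict comparisons):
    FCS Ct < T -> background, regardless of cells or medium;
    cells < T and medium < T -> secreted;
    cells < T and medium >= T -> not_secreted;
    cells >= T -> not_expressed.
    Replicate samples of a material are averaged on the Ct scale.
    """
    cells = _material_mean(matrix, meta, Material.CELLS, cell_line, cell_line)
    media = _material_mean(matrix, meta, Material.MEDIUM, cell_line, cell_line)
    fcs = _material_mean(matrix, meta, Material.FCS, None, cell_line)
    T = config.detection_threshold
    calls = []
    for assay in matrix.assays:
        c, m, f = float(cells[assay]), float(media[assay]), float(fcs[assay])
        if f < T:
            status = SecretionStatus.BACKGROUND
        elif c < T and m < T:
            status = SecretionStatus.SECRETED
        elif c < T:
            status = SecretionStatus.NOT_SECRETED
        else:
            status = SecretionStatus.NOT_EXPRESSED
        calls.append(SecretionCall(assay, cell_line, status, c, m, f))
    return calls


def secretion_counts(calls: Sequence[SecretionCall]) -> dict[str, int]:
    """Status counts over a cell line's secretion calls."""
    out: dict[str, int] = {}
    for c in calls:
        out[c.status] = out.get(c.status, 0) + 1
    return out


# ---------------------------------------------------------------------------
# Venn-style detection summaries
# ---------------------------------------------------------------------------

def detection_venn(
    calls: pd.DataFrame,
    meta: Sequence[SampleMeta],
    groups: Sequence[str],
) -> dict[tuple[str, ...], int]:
    """Exact-membership counts of detected assays across groups.

    An assay belongs to a group when detected in at least one of the group's
    samples.  The returned mapping has one entry per subset of ``groups``
    (keyed by the sorted member tuple; the empty tuple counts assays
    detected in none); region counts sum to the panel size.
    """
    if len(groups) < 1:
        raise ValueError("need at least one group")
    membership = {}
    for g in groups:
        ids = [m.sample_id for m in meta
               if m.group == g and m.sample_id in calls.columns]
        if not ids:
            raise ValueError(f"group {g!r} has no samples in the call table")
        membership[g] = calls[ids].any(axis=1)
    frame = pd.DataFrame(membership)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(len(groups) + 1):
        for combo in combinations(groups, r):
            in_set = frame[list(combo)].all(axis=1) if combo else pd.Series(
                True, index=frame.index)
            out_set = frame[[g for g in groups if g not in combo]]
            exact = in_set & ~out_set.any(axis=1) if len(combo) < len(groups) \
                else in_set
            regions[tuple(sorted(combo))] = int(exact.sum())
    return regions


# ---------------------------------------------------------------------------
# Tissue-to-biofluid concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateSet:
    """Markers surviving the tissue-to-biofluid concordance rules."""

    histology_group: str
    candidates: tuple[tuple[str, float, float], ...]  # (assay, tissue_f, fluid_f)
    excluded_by_control: tuple[str, ...]

    def assay_names(self) -> list[str]:
        return [a for a, _, _ in self.candidates]


def xenograft_plasma_concordance(
    matrix: CtMatrix,
    meta: Sequence[SampleMeta],
    histology_group: str,
    config: StudyConfig,
) -> CandidateSet:
    """Select candidate markers for one histology group.

    A candidate must be (i) detected in ALL tumor xenografts of the group,
    (ii) undetected in every normal-animal control (tissue mix and plasma,
    role=background), and (iii) detected in at least
    ``config.plasma_detection_fraction`` of the group's endpoint plasmas.
    Matched pairing via ``paired_with`` is honored when present; otherwise
    the group-level plasma fraction is used.
    """
    calls = detection_filter(matrix, config)
    meta = [m for m in meta if m.sample_id in calls.columns]
    xeno = [m for m in meta if m.material is Material.XENOGRAFT
            and m.group == histology_group and m.role is not Role.BACKGROUND]
    plasma = [m for m in meta if m.material is Material.PLASMA
              and m.group == histology_group and m.role is not Role.BACKGROUND]
    controls = [m for m in meta if m.role is Role.BACKGROUND
                and m.material in (Material.TISSUE_MIX, Material.PLASMA)]
    if not xeno or not plasma:
        raise ValueError(
            f"group {histology_group!r} needs >=1 xenograft and >=1 plasma"
        )
    if not controls:
        raise ValueError("normal-animal controls required for concordance")

    xeno_ids = [m.sample_id for m in xeno]
    # honor explicit matching when every plasma is paired to a group xenograft
    paired = [m for m in plasma if m.paired_with in set(xeno_ids)]
    plasma_ids = [m.sample_id for m in (paired if len(paired) == len(plasma)
                                        else plasma)]
    control_ids = [m.sample_id for m in controls]

    in_all_xeno = calls[xeno_ids].all(axis=1)
    in_any_control = calls[control_ids].any(axis=1)
    tissue_consistent = in_all_xeno.index[in_all_xeno]
    excluded = sorted(a for a in tissue_consistent if in_any_control[a])
    fluid_frac = calls[plasma_ids].mean(axis=1)

    candidates = []
    for assay in tissue_consistent:
        if in_any_control[assay]:
            continue
        frac = float(fluid_frac[assay])
        if frac >= config.plasma_detection_fraction:
            candidates.append((assay, 1.0, frac))
    candidates.sort(key=lambda c: (-c[2], c[0]))
    return CandidateSet(
        histology_group=histology_group,
        candidates=tuple(candidates),
        excluded_by_control=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# Detection summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionSummary:
    """Panel-wide detection counts over a set of samples."""

    n_total: int
    n_samples: int
    n_detected_all: int
    n_detected_none: int
    per_sample: Mapping[str, int]
    fraction_all: float
    fraction_none: float

    @property
    def percent_none(self) -> int:
        """Fraction of never-detected assays, nearest integer percent."""
        return int(round_half_up(100.0 * self.fraction_none, 0))

    @property
    def percent_all(self) -> int:
        return int(round_half_up(100.0 * self.fraction_all, 0))


def detection_summary(
    calls: pd.DataFrame,
    meta: Sequence[SampleMeta] | None = None,
    group: str | None = None,
) -> DetectionSummary:
    """Summarize a detection-call table (optionally one metadata group)."""
    if group is not None:
        if meta is None:
            raise ValueError("group selection requires metadata")
        ids = [m.sample_id for m in meta
               if m.group == group and m.sample_id in calls.columns]
        if not ids:
            raise ValueError(f"group {group!r} has no samples")
        calls = calls[ids]
    n_total, n_samples = calls.shape
    if n_samples == 0:
        raise ValueError("no samples to summarize")
    det_all = int(calls.all(axis=1).sum())
    det_none = int((~calls.any(axis=1)).sum())
    return DetectionSummary(
        n_total=n_total,
        n_samples=n_samples,
        n_detected_all=det_all,
        n_detected_none=det_none,
        per_sample={s: int(calls[s].sum()) for s in calls.columns},
        fraction_all=det_all / n_total,
        fraction_none=det_none / n_total,
    )
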