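"""Sample-level quality control.

Three gates are applied before any biological comparison:

* **Spike-in recovery** — an exogenous plant microRNA (ath-miR-159a by
  default) is added in fixed amount before isolation; a sample passes when
  its spike Ct deviates from the cohort median by at most the configured
  tolerance (default +/-2 Ct).  The gate is defined by variation within the
  cohort, not an absolute Ct.
* **Hemolysis** — red-cell lysis floods a specimen with erythrocyte
  microRNAs.  The miR-23a/451a ratio, computed here on the Ct-difference
  (log2-abundance) scale as Ct(miR-23a-3p) - Ct(miR-451a), rises with
  hemolysis; the shipped cutoff 9.15 can be recalibrated per cohort against
  visual scores (0 = clean vs 1-5 = any discoloration) by Youden's index.
* **Inhibition** — PCR inhibitors (e.g. heparin) depress both the spike-in
  and the endogenous normalizer; the joint shift flags possible inhibition,
  distinguishing it from a simple recovery failure.

Failing samples are flagged, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import CtMatrix, SampleMeta, StudyConfig
from .validation import GroupComparison, compare_groups, roc

__all__ = [
    "HEMOLYSIS_STABLE_ASSAY",
    "HEMOLYSIS_SENSITIVE_ASSAY",
    "QcReport",
    "HemolysisCalibration",
    "spike_in_qc",
    "hemolysis_ratio",
    "calibrate_hemolysis_cutoff",
    "assess_hemolysis_impact",
    "inhibition_check",
]

#: Hemolysis-stable reference assay of the ratio.
HEMOLYSIS_STABLE_ASSAY = "hsa-miR-23a-3p"
#: Erythrocyte-enriched assay of the ratio (rodent-annotated probe, mature
#: sequence shared with human miR-451a).
HEMOLYSIS_SENSITIVE_ASSAY = "mmu-miR-451a"


@dataclass(frozen=True)
class QcReport:
    """Per-sample QC outcome."""

    sample_id: str
    spike_ct: float
    spike_deviation: float
    spike_pass: bool
    hemolysis_ratio: float | None
    hemolysis_flag: bool | None
    inhibition_flag: bool


@dataclass(frozen=True)
class HemolysisCalibration:
    """Cohort-specific miR-23a/451a cutoff chosen by Youden's index."""

    cutoff: float
    auc: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    roc_points: tuple[tuple[float, float, float], ...]


def spike_in_qc(
    matrix: CtMatrix,
    meta: Sequence[SampleMeta],
    config: StudyConfig,
) -> list[QcReport]:
    """Gate every sample on spike-in recovery relative to the cohort median.

    Also evaluates the hemolysis ratio (against ``config.hemolysis_cutoff``)
    and the inhibition flag, so the returned reports are complete.
    """
    if config.spike_assay not in matrix.assays:
        raise ValueError(f"spike assay {config.spike_assay!r} not in matrix")
    sample_ids = [m.sample_id for m in meta if m.sample_id in matrix.samples]
    if not sample_ids:
        raise ValueError("no metadata samples present in the matrix")
    spike = matrix.ct.loc[config.spike_assay, sample_ids].astype(float)
    median = float(spike.median())
    has_norm = config.normalizer_assay in matrix.assays
    if has_norm:
        norm = matrix.ct.loc[config.normalizer_assay, sample_ids].astype(float)
        norm_median = float(norm.median())
    reports = []
    for sid in sample_ids:
        ct = float(spike[sid])
        dev = ct - median
        ratio = hemolysis_ratio(matrix, sid)
        inhibition = False
        if has_norm and dev > config.spike_tolerance:
            inhibition = (float(norm[sid]) - norm_median) > config.spike_tolerance
        reports.append(QcReport(
            sample_id=sid,
            spike_ct=ct,
            spike_deviation=dev,
            spike_pass=abs(dev) <= config.spike_tolerance,
            hemolysis_ratio=ratio,
            hemolysis_flag=None if ratio is None else ratio > config.hemolysis_cutoff,
            inhibition_flag=inhibition,
        ))
    return reports


def hemolysis_ratio(matrix: CtMatrix, sample: str) -> float | None:
    """miR-23a/451a hemolysis ratio for one sample.

    Computed as Ct(miR-23a-3p) - Ct(miR-451a): the log2 abundance of the
    erythrocyte marker relative to the stable reference, so larger values
    indicate more hemolysis.  Returns None (not evaluable) when either
    assay is missing from the panel or non-detect in the sample.
    """
    for assay in (HEMOLYSIS_STABLE_ASSAY, HEMOLYSIS_SENSITIVE_ASSAY):
        if assay not in matrix.assays:
            return None
    ct23 = matrix.value(HEMOLYSIS_STABLE_ASSAY, sample)
    ct451 = matrix.value(HEMOLYSIS_SENSITIVE_ASSAY, sample)
    if ct23 >= matrix.nondetect_code or ct451 >= matrix.nondetect_code:
        return None
    return ct23 - ct451


def calibrate_hemolysis_cutoff(
    ratios: Sequence[float],
    visual_scores: Sequence[int],
) -> HemolysisCalibration:
    """Calibrate the ratio cutoff against visual hemolysis scores.

    Positive class is any visible hemolysis (score >= 1).  The ROC is built
    over all observed ratio thresholds; the reported cutoff maximizes
    Youden's J (ties broken toward higher specificity) and sits at the
    midpoint between adjacent observed ratios.
    """
    ratios = np.asarray(ratios, dtype=float)
    scores = np.asarray(visual_scores, dtype=int)
    if ratios.shape != scores.shape:
        raise ValueError("ratios and scores must have equal length")
    if np.any((scores < 0) | (scores > 5)):
        raise ValueError("visual scores must be in 0..5")
    labels = scores >= 1
    if labels.all() or not labels.any():
        raise ValueError("both score classes (0 vs 1-5) must be present")
    res = roc(ratios, labels)
    return HemolysisCalibration(
        cutoff=res.youden_cutoff,
        auc=res.auc,
        sensitivity_at_cutoff=res.sensitivity_at_cutoff,
        specificity_at_cutoff=res.specificity_at_cutoff,
        roc_points=res.points,
    )


def assess_hemolysis_impact(
    matrix: CtMatrix,
    meta: Sequence[SampleMeta],
    targets: Sequence[str],
    grouping: str = "visual",
    config: StudyConfig | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare Ct distributions of target assays between hemolysed and clean
    samples.

    ``grouping`` is ``visual`` (score 0 vs scores 1-5) or ``ratio_cutoff``
    (miR-23a/451a ratio above the configured cutoff).  Returns one row per
    target with group medians, the rank-sum p-value, and a ``flagged``
    column (p < alpha).  Groups that cannot be formed leave the assay
    marked not evaluable (p None).
    """
    if grouping not in ("visual", "ratio_cutoff"):
        raise ValueError(f"unknown grouping {grouping!r}")
    config = config or StudyConfig()
    clean, hemolysed = [], []
    for m in meta:
        if m.sample_id not in matrix.samples:
            continue
        if grouping == "visual":
            if m.hemolysis_score is None:
                continue
            is_hem = m.hemolysis_score >= 1
        else:
            ratio = hemolysis_ratio(matrix, m.sample_id)
            if ratio is None:
                continue
            is_hem = ratio > config.hemolysis_cutoff
        (hemolysed if is_hem else clean).append(m.sample_id)
    rows = []
    for assay in targets:
        if assay not in matrix.assays or not clean or not hemolysed:
            rows.append({"assay": assay, "n_clean": len(clean),
                         "n_hemolysed": len(hemolysed),
                         "median_clean": np.nan, "median_hemolysed": np.nan,
                         "p_value": None, "flagged": False})
            continue
        a = matrix.ct.loc[assay, clean].astype(float).to_numpy()
        b = matrix.ct.loc[assay, hemolysed].astype(float).to_numpy()
        cmp: GroupComparison = compare_groups([a, b])
        rows.append({
            "assay": assay,
            "n_clean": len(clean),
            "n_hemolysed": len(hemolysed),
            "median_clean": float(np.median(a)),
            "median_hemolysed": float(np.median(b)),
            "p_value": cmp.p_value,
            "flagged": cmp.p_value is not None and cmp.p_value < alpha,
        })
    return pd.DataFrame(rows)


def inhibition_check(
    matrix: CtMatrix,
    meta: Sequence[SampleMeta],
    config: StudyConfig,
) -> list[str]:
    """Samples flagged for possible PCR inhibition.

    A sample is flagged when its spike Ct exceeds the cohort median by more
    than the spike tolerance AND its endogenous normalizer is depressed by
    the same margin — a spike failure alone indicates poor recovery, not
    inhibition.
    """
    return [r.sample_id for r in spike_in_qc(matrix, meta, config)
            if r.inhibition_flag]


def qc_report_frame(reports: Sequence[QcReport]) -> pd.DataFrame:
    """Tabulate QC reports, one row per sample (for the CSV report)."""
    return pd.DataFrame([r.__dict__ for r in reports])
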