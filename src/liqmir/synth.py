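"""Synthetic cohort generator.

No raw array-card data are deposited for the study design this pipeline
targets, so every downstream module is exercised on simulated cohorts whose
statistical structure matches what the pipeline assumes:

* Ct-space additive Gaussian noise (log-normal abundance), sigma 0.3 Ct by
  default, with a hard detection ceiling at Ct 40 encoding non-detects;
* cell-line-specific expressed assay sets carrying latent secretion
  indicators; conditioned medium shows a secreted assay at approximately
  its cellular Ct, a non-secreted assay at the ceiling;
* a background fraction of the panel present in fetal calf serum (and hence
  in every conditioned medium) and host-animal assays present in normal
  mouse tissue/plasma controls;
* a spike-in channel with small independent noise;
* hemolysis depressing the erythrocyte marker miR-451a Ct linearly with the
  visual score;
* tumor markers transferring from xenograft to matched plasma independently
  with a fixed detection probability;
* exponential post-operative decay with multiplicative log-normal noise.

Every generator is fully deterministic under a fixed seed and returns a
truth table for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import CtMatrix, Material, Role, SampleMeta, StudyConfig
from .kinetics import DecaySeries
from .qc import HEMOLYSIS_SENSITIVE_ASSAY, HEMOLYSIS_STABLE_ASSAY

__all__ = [
    "SimSpec",
    "simulate_cell_media_fcs",
    "simulate_xenograft_plasma",
    "simulate_patient_cohort",
    "simulate_postop_series",
]

# Ct placement of simulated populations (cycles).  Expressed assays sit well
# inside the detection range so that at sigma=0 classification is exact.
_EXPRESSED_CT_SD = 3.0
_EXPRESSED_CT_MIN = 18.0
_EXPRESSED_CT_MAX = 33.0
_BACKGROUND_MEAN_CT = 28.0
_BACKGROUND_CT_SD = 2.0
_NORMALIZER_MEAN_CT = 25.0
_MARKER_BASE_DELTA_CT = 6.0
_HEMOLYSIS_STABLE_MEAN_CT = 22.0
_HEMOLYSIS_SENSITIVE_MEAN_CT = 23.0
_PLASMA_MARKER_MEAN_CT = 30.0


@dataclass(frozen=True)
class SimSpec:
    """Shared simulation parameters (units: PCR cycles, hours, fractions)."""

    n_assays: int = 768
    seed: int = 0
    ct_noise_sd: float = 0.3
    detection_ceiling: float = 40.0
    expressed_mean_ct: float = 26.0
    expressed_fraction: float = 0.4
    background_assay_fraction: float = 0.3
    secretion_probability: float = 0.35
    secreted_media_offset_ct: float = 0.0
    hemolysis_effect_per_score: float = 2.0
    spike_mean_ct: float = 22.0
    spike_sd: float = 0.3
    transfer_detection_prob: float = 0.5
    decay_half_life_h: float = 3.0

    def __post_init__(self) -> None:
        for name in ("expressed_fraction", "background_assay_fraction",
                     "secretion_probability", "transfer_detection_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ct_noise_sd < 0 or self.spike_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.detection_ceiling <= self.expressed_mean_ct:
            raise ValueError("ceiling must exceed the expressed mean Ct")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _assay_names(n: int, prefix: str = "hsa-miR-sim") -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]


def _clip(ct: np.ndarray, ceiling: float) -> np.ndarray:
    return np.clip(ct, 5.0, ceiling)


def _study_config(spec: SimSpec) -> StudyConfig:
    return StudyConfig(seed=spec.seed)


# ---------------------------------------------------------------------------
# In-vitro: cells / conditioned medium / fetal calf serum
# ---------------------------------------------------------------------------

def simulate_cell_media_fcs(
    spec: SimSpec,
    cell_lines: Sequence[str],
    n_expressed: int | None = None,
    n_secreted: int | None = None,
) -> tuple[CtMatrix, list[SampleMeta], pd.DataFrame]:
    """Simulate the cells / matched-medium / FCS design.

    Each cell line gets an expressed assay set (Bernoulli
    ``expressed_fraction`` per assay, or exactly ``n_expressed`` planted
    assays when given); each expressed assay carries a latent secretion
    indicator (Bernoulli ``secretion_probability``, or exactly
    ``n_secreted`` of the expressed set).  Medium Ct equals cell Ct plus
    ``secreted_media_offset_ct`` for secreted assays and the ceiling
    otherwise; a global background fraction of the panel is present in FCS
    and every medium.  Gaussian Ct noise sigma ``ct_noise_sd`` throughout.

    Returns (matrix, metadata, truth) where truth has one row per
    (assay, cell_line) with boolean ``expressed``, ``secreted`` and the
    panel-wide ``background`` indicator.
    """
    rng = spec.rng()
    ceiling = spec.detection_ceiling
    assays = _assay_names(spec.n_assays)
    spike = StudyConfig().spike_assay
    normalizer = StudyConfig().normalizer_assay
    all_assays = assays + [spike, normalizer]

    background = rng.random(spec.n_assays) < spec.background_assay_fraction
    fcs_base = _clip(rng.normal(_BACKGROUND_MEAN_CT, _BACKGROUND_CT_SD,
                                spec.n_assays), ceiling)

    columns: dict[str, np.ndarray] = {}
    meta: list[SampleMeta] = []
    truth_rows = []

    def noise(n: int) -> np.ndarray:
        return rng.normal(0.0, spec.ct_noise_sd, n)

    for line in cell_lines:
        if n_expressed is None:
            expressed = rng.random(spec.n_assays) < spec.expressed_fraction
        else:
            perm = rng.permutation(spec.n_assays)
            expressed = np.zeros(spec.n_assays, dtype=bool)
            expressed[perm[:n_expressed]] = True
        exp_idx = np.flatnonzero(expressed)
        secreted = np.zeros(spec.n_assays, dtype=bool)
        if n_secreted is None:
            secreted[exp_idx] = rng.random(exp_idx.size) < spec.secretion_probability
        else:
            chosen = rng.permutation(exp_idx)[:n_secreted]
            secreted[chosen] = True

        cell_ct = np.full(spec.n_assays, ceiling)
        base = np.clip(
            rng.normal(spec.expressed_mean_ct, _EXPRESSED_CT_SD, exp_idx.size),
            _EXPRESSED_CT_MIN, _EXPRESSED_CT_MAX,
        )
        cell_ct[exp_idx] = base
        media_ct = np.full(spec.n_assays, ceiling)
        sec_idx = np.flatnonzero(secreted)
        media_ct[sec_idx] = cell_ct[sec_idx] + spec.secreted_media_offset_ct
        media_ct[background] = fcs_base[background]

        columns[f"{line}_cells"] = _clip(cell_ct + noise(spec.n_assays), ceiling)
        columns[f"{line}_media"] = _clip(media_ct + noise(spec.n_assays), ceiling)
        meta.append(SampleMeta(f"{line}_cells", Material.CELLS, Role.CASE, line))
        meta.append(SampleMeta(f"{line}_media", Material.MEDIUM, Role.CASE, line))
        for i, assay in enumerate(assays):
            truth_rows.append({
                "assay": assay, "cell_line": line,
                "expressed": bool(expressed[i]),
                "secreted": bool(secreted[i]),
                "background": bool(background[i]),
            })

    fcs_ct = np.full(spec.n_assays, ceiling)
    fcs_ct[background] = fcs_base[background]
    columns["FCS"] = _clip(fcs_ct + noise(spec.n_assays), ceiling)
    meta.append(SampleMeta("FCS", Material.FCS, Role.BACKGROUND, "FCS"))

    frame = pd.DataFrame(columns, index=assays)
    n_samples = frame.shape[1]
    frame.loc[spike] = _clip(
        rng.normal(spec.spike_mean_ct, spec.spike_sd, n_samples), ceiling)
    frame.loc[normalizer] = _clip(
        rng.normal(_NORMALIZER_MEAN_CT, spec.ct_noise_sd, n_samples), ceiling)
    matrix = CtMatrix(frame, ceiling)
    truth = pd.DataFrame(truth_rows)
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# In-vivo: xenografts and matched endpoint plasma
# ---------------------------------------------------------------------------

def simulate_xenograft_plasma(
    spec: SimSpec,
    histology_groups: Sequence[str],
    n_per_group: int,
    n_markers_per_group: int = 5,
    n_control_contaminated: int = 0,
    n_normal_tissue: int = 2,
    n_normal_plasma: int = 3,
) -> tuple[CtMatrix, list[SampleMeta], pd.DataFrame]:
    """Simulate the xenograft -> matched endpoint plasma design.

    Each histology group gets ``n_per_group`` animals, each contributing a
    xenograft and a paired plasma sample.  ``n_markers_per_group`` planted
    tumor markers are present in every xenograft of their group and
    transfer to each matched plasma independently with probability
    ``transfer_detection_prob``.  A host-animal (``mmu-``) background
    fraction of the panel is present in every mouse-derived sample,
    including the normal tissue-mix and plasma controls.
    ``n_control_contaminated`` markers per group are additionally planted
    into the normal plasma controls (they must end up control-excluded).

    Truth rows: (assay, group, kind) with kind in
    {planted_marker, contaminated_marker, mouse_background}.
    """
    rng = spec.rng()
    ceiling = spec.detection_ceiling
    n_human = spec.n_assays // 2
    n_mouse = spec.n_assays - n_human
    human = _assay_names(n_human, "hsa-miR-sim")
    mouse = _assay_names(n_mouse, "mmu-miR-sim")
    assays = human + mouse

    mouse_bg = np.zeros(len(assays), dtype=bool)
    mouse_bg[n_human:] = rng.random(n_mouse) < spec.background_assay_fraction
    bg_ct = _clip(rng.normal(_BACKGROUND_MEAN_CT, _BACKGROUND_CT_SD,
                             len(assays)), ceiling)

    # disjoint planted marker sets per group, drawn from the human namespace
    per_group_total = n_markers_per_group + n_control_contaminated
    pool = rng.permutation(n_human)
    marker_idx: dict[str, np.ndarray] = {}
    contaminated_idx: dict[str, np.ndarray] = {}
    cursor = 0
    for g in histology_groups:
        marker_idx[g] = pool[cursor:cursor + n_markers_per_group]
        cursor += n_markers_per_group
        contaminated_idx[g] = pool[cursor:cursor + n_control_contaminated]
        cursor += n_control_contaminated
    if cursor > n_human:
        raise ValueError("too many planted markers for the panel size")

    columns: dict[str, np.ndarray] = {}
    meta: list[SampleMeta] = []
    truth_rows = []

    def noise() -> np.ndarray:
        return rng.normal(0.0, spec.ct_noise_sd, len(assays))

    def base_mouse_sample() -> np.ndarray:
        ct = np.full(len(assays), ceiling)
        ct[mouse_bg] = bg_ct[mouse_bg]
        return ct

    for g in histology_groups:
        planted = np.concatenate([marker_idx[g], contaminated_idx[g]]).astype(int)
        for i in range(n_per_group):
            xeno_id, plasma_id = f"{g}_xeno{i}", f"{g}_plasma{i}"
            xeno = base_mouse_sample()
            xeno[planted] = np.clip(
                rng.normal(spec.expressed_mean_ct, 2.0, planted.size),
                _EXPRESSED_CT_MIN, _EXPRESSED_CT_MAX)
            plasma = base_mouse_sample()
            transfer = rng.random(planted.size) < spec.transfer_detection_prob
            hit = planted[transfer]
            plasma[hit] = np.clip(
                rng.normal(_PLASMA_MARKER_MEAN_CT, 1.0, hit.size), 20.0, 33.0)
            columns[xeno_id] = _clip(xeno + noise(), ceiling)
            columns[plasma_id] = _clip(plasma + noise(), ceiling)
            meta.append(SampleMeta(xeno_id, Material.XENOGRAFT, Role.CASE, g))
            meta.append(SampleMeta(plasma_id, Material.PLASMA, Role.CASE, g,
                                   paired_with=xeno_id))
        for kind, idx in (("planted_marker", marker_idx[g]),
                          ("contaminated_marker", contaminated_idx[g])):
            for j in idx:
                truth_rows.append({"assay": assays[j], "group": g, "kind": kind})

    for i in range(n_normal_tissue):
        sid = f"normal_tissue{i}"
        columns[sid] = _clip(base_mouse_sample() + noise(), ceiling)
        meta.append(SampleMeta(sid, Material.TISSUE_MIX, Role.BACKGROUND, "normal"))
    contaminated_all = np.concatenate(
        [contaminated_idx[g] for g in histology_groups]
    ).astype(int) if histology_groups else np.array([], dtype=int)
    for i in range(n_normal_plasma):
        sid = f"normal_plasma{i}"
        ct = base_mouse_sample()
        ct[contaminated_all] = np.clip(
            rng.normal(_PLASMA_MARKER_MEAN_CT, 1.0, contaminated_all.size),
            20.0, 33.0)
        columns[sid] = _clip(ct + noise(), ceiling)
        meta.append(SampleMeta(sid, Material.PLASMA, Role.BACKGROUND, "normal"))

    for j in np.flatnonzero(mouse_bg):
        truth_rows.append({"assay": assays[j], "group": "", "kind": "mouse_background"})

    matrix = CtMatrix(pd.DataFrame(columns, index=assays), ceiling)
    return matrix, meta, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Patient cohorts: cases vs controls, with hemolysis artefacts
# ---------------------------------------------------------------------------

def simulate_patient_cohort(
    spec: SimSpec,
    n_cases: int,
    n_controls: int,
    effect_log2: float,
    hemolysis_scores: Sequence[int] | None = None,
    marker: str = "hsa-miR-885-5p",
) -> tuple[CtMatrix, list[SampleMeta], pd.DataFrame]:
    """Simulate a targeted serum cohort for validation statistics.

    The marker's dCt is shifted by ``-effect_log2`` in cases (an
    ``effect_log2``-fold log2 elevation); the normalizer is stable; the
    spike-in is drawn with ``spike_sd``; miR-451a Ct is depressed by
    ``hemolysis_effect_per_score`` x visual score.  ``hemolysis_scores``
    must list one score per sample (cases first), defaulting to all zeros.

    Truth rows: one per sample with group, hemolysis score and true marker
    dCt shift.
    """
    rng = spec.rng()
    ceiling = spec.detection_ceiling
    n = n_cases + n_controls
    if hemolysis_scores is None:
        hemolysis_scores = [0] * n
    if len(hemolysis_scores) != n:
        raise ValueError("need one hemolysis score per sample")
    config = StudyConfig(seed=spec.seed)
    assays = [config.spike_assay, config.normalizer_assay, marker,
              HEMOLYSIS_STABLE_ASSAY, HEMOLYSIS_SENSITIVE_ASSAY]

    sample_ids = [f"case{i}" for i in range(n_cases)] + \
                 [f"control{i}" for i in range(n_controls)]
    is_case = np.array([1] * n_cases + [0] * n_controls, dtype=bool)
    scores = np.asarray(hemolysis_scores, dtype=int)

    spike_ct = rng.normal(spec.spike_mean_ct, spec.spike_sd, n)
    norm_ct = rng.normal(_NORMALIZER_MEAN_CT, spec.ct_noise_sd, n)
    shift = np.where(is_case, -effect_log2, 0.0)
    marker_ct = norm_ct + _MARKER_BASE_DELTA_CT + shift \
        + rng.normal(0.0, spec.ct_noise_sd, n)
    ct23 = rng.normal(_HEMOLYSIS_STABLE_MEAN_CT, spec.ct_noise_sd, n)
    ct451 = rng.normal(_HEMOLYSIS_SENSITIVE_MEAN_CT, spec.ct_noise_sd, n) \
        - spec.hemolysis_effect_per_score * scores

    frame = pd.DataFrame(
        _clip(np.vstack([spike_ct, norm_ct, marker_ct, ct23, ct451]), ceiling),
        index=assays, columns=sample_ids,
    )
    meta = [
        SampleMeta(sid, Material.SERUM,
                   Role.CASE if c else Role.CONTROL,
                   "case" if c else "control",
                   hemolysis_score=int(s))
        for sid, c, s in zip(sample_ids, is_case, scores)
    ]
    truth = pd.DataFrame({
        "sample_id": sample_ids,
        "group": ["case" if c else "control" for c in is_case],
        "hemolysis_score": scores,
        "marker_delta_ct_shift": shift,
    })
    return CtMatrix(frame, ceiling), meta, truth


# ---------------------------------------------------------------------------
# Post-operative decay series
# ---------------------------------------------------------------------------

def simulate_postop_series(
    spec: SimSpec,
    n_patients: int,
    sampling_h: Sequence[float],
    assay: str = "hsa-miR-371a-3p",
) -> list[DecaySeries]:
    """Simulate post-surgery decay series, one per patient.

    Levels follow an exponential with half-life ``decay_half_life_h``,
    multiplied by log-normal noise of sigma ``ct_noise_sd`` (log2 units,
    matching the Ct-space noise model).  The grid must start at or before 0.
    """
    times = tuple(float(t) for t in sampling_h)
    if not times or times[0] > 0:
        raise ValueError("sampling grid must start at a baseline time <= 0")
    rng = spec.rng()
    out = []
    for p in range(n_patients):
        noise = rng.normal(0.0, spec.ct_noise_sd, len(times))
        levels = tuple(
            float(100.0 * 2.0 ** (-t / spec.decay_half_life_h + e))
            for t, e in zip(times, noise)
        )
        out.append(DecaySeries(f"patient{p}", assay, times, levels))
    return out
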