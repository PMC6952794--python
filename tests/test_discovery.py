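"""Identification model: detection calls, background subtraction, secretion
classification, Venn summaries and tissue-to-biofluid concordance."""

import numpy as np
import pandas as pd
import pytest

from liqmir import (
    CtMatrix, Material, Role, SampleMeta, SimSpec, StudyConfig,
    classify_secretion, detection_filter, detection_summary, detection_venn,
    percentage, simulate_cell_media_fcs, simulate_xenograft_plasma,
    subtract_background, xenograft_plasma_concordance,
)
from liqmir.discovery import SecretionStatus, secretion_counts


class TestDetectionFilter:
    def test_strict_threshold(self, panel_matrix):
        calls = detection_filter(panel_matrix, StudyConfig())
        assert calls.at["hsa-miR-371a-3p", "TCam-2_media"]        # Ct 25.9
        assert not calls.at["hsa-miR-372-3p", "NT2_media"]        # Ct 40
        boundary = CtMatrix(pd.DataFrame({"s": [34.0]}, index=["m"]))
        assert not detection_filter(boundary, StudyConfig()).at["m", "s"]

    def test_raising_threshold_never_shrinks_detected_sets(self):
        rng = np.random.default_rng(0)
        m = CtMatrix(pd.DataFrame(
            rng.uniform(20, 40, (50, 4)).round(1).clip(None, 40),
            index=[f"miR-{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(4)]))
        low = detection_filter(m, StudyConfig(detection_threshold=30.0))
        high = detection_filter(m, StudyConfig(detection_threshold=36.0))
        assert (high | low).equals(high)  # low ⊆ high cellwise


class TestSubtractBackground:
    def _setup(self):
        frame = pd.DataFrame(
            {
                "A_media": [25.0, 25.0, 40.0],
                "B_media": [25.0, 40.0, 25.0],
                "FCS": [25.0, 40.0, 40.0],
            },
            index=["miR-bg", "miR-a", "miR-b"])
        meta = [
            SampleMeta("A_media", Material.MEDIUM, Role.CASE, "A"),
            SampleMeta("B_media", Material.MEDIUM, Role.CASE, "B"),
            SampleMeta("FCS", Material.FCS, Role.BACKGROUND, "FCS"),
        ]
        return detection_filter(CtMatrix(frame), StudyConfig()), meta

    def test_any_background_positive_excludes(self):
        calls, meta = self._setup()
        sets = subtract_background(calls, meta)
        assert sets["A"] == ["miR-a"]     # miR-bg excluded: present in FCS
        assert sets["B"] == ["miR-b"]

    def test_one_of_several_controls_suffices(self):
        frame = pd.DataFrame(
            {"tumor_plasma": [25.0], "np1": [25.0], "np2": [40.0],
             "np3": [40.0]},
            index=["miR-x"])
        meta = [
            SampleMeta("tumor_plasma", Material.PLASMA, Role.CASE, "tum"),
            SampleMeta("np1", Material.PLASMA, Role.BACKGROUND, "normal"),
            SampleMeta("np2", Material.PLASMA, Role.BACKGROUND, "normal"),
            SampleMeta("np3", Material.PLASMA, Role.BACKGROUND, "normal"),
        ]
        calls = detection_filter(CtMatrix(frame), StudyConfig())
        assert subtract_background(calls, meta)["tum"] == []

    def test_no_background_passes_through_with_warning(self):
        calls, meta = self._setup()
        with pytest.warns(UserWarning, match="background"):
            sets = subtract_background(calls, meta[:2])
        assert sets["A"] == ["miR-a", "miR-bg"]


class TestClassifySecretion:
    @pytest.mark.parametrize("line, assay, expected", [
        ("TCam-2", "hsa-miR-371a-3p", SecretionStatus.SECRETED),
        ("NCCIT", "hsa-miR-373-3p", SecretionStatus.NOT_SECRETED),
        ("NT2", "hsa-miR-372-3p", SecretionStatus.NOT_SECRETED),
        ("NT2", "hsa-miR-373-3p", SecretionStatus.NOT_EXPRESSED),
    ])
    def test_published_triplets(self, panel_matrix, panel_meta, line, assay,
                                expected):
        calls = classify_secretion(panel_matrix, panel_meta, line, StudyConfig())
        assert {c.assay: c.status for c in calls}[assay] == expected

    def test_fcs_positive_is_background_regardless_of_media(self, panel_matrix,
                                                            panel_meta):
        frame = panel_matrix.ct.copy()
        frame.loc["hsa-miR-371a-3p", "FCS"] = 28.0
        calls = classify_secretion(CtMatrix(frame), panel_meta, "TCam-2",
                                   StudyConfig())
        assert {c.assay: c.status for c in calls}["hsa-miR-371a-3p"] \
            == SecretionStatus.BACKGROUND

    def test_missing_triplet_member_names_material(self, panel_matrix,
                                                   panel_meta):
        meta = [m for m in panel_meta if m.material is not Material.FCS]
        with pytest.raises(ValueError, match="fcs"):
            classify_secretion(panel_matrix, meta, "TCam-2", StudyConfig())

    def test_statuses_partition_panel_and_recover_planted_truth(self):
        spec = SimSpec(seed=9, n_assays=400, ct_noise_sd=0.0)
        matrix, meta, truth = simulate_cell_media_fcs(spec, ["L1"])
        calls = classify_secretion(matrix, meta, "L1", StudyConfig())
        counts = secretion_counts(calls)
        assert sum(counts.values()) == len(matrix.assays)
        t = truth.set_index("assay")
        by_assay = {c.assay: c.status for c in calls
                    if c.assay in t.index}
        for assay, status in by_assay.items():
            row = t.loc[assay]
            if row["background"]:
                assert status == SecretionStatus.BACKGROUND
            elif row["expressed"] and row["secreted"]:
                assert status == SecretionStatus.SECRETED
            elif row["expressed"]:
                assert status == SecretionStatus.NOT_SECRETED
            else:
                assert status == SecretionStatus.NOT_EXPRESSED

    def test_zero_secretion_probability_yields_zero_secreted(self):
        spec = SimSpec(seed=2, n_assays=200, ct_noise_sd=0.0,
                       secretion_probability=0.0)
        matrix, meta, _ = simulate_cell_media_fcs(spec, ["L1"])
        counts = secretion_counts(classify_secretion(matrix, meta, "L1",
                                                     StudyConfig()))
        assert counts.get(SecretionStatus.SECRETED, 0) == 0


class TestDetectionVenn:
    def _calls(self, frame):
        meta = [SampleMeta(s, Material.CELLS, Role.CASE, s)
                for s in frame.columns]
        return detection_filter(CtMatrix(frame), StudyConfig()), meta

    def test_disjoint_sets(self):
        frame = pd.DataFrame(
            {"g1": [25.0] * 3 + [40.0] * 7, "g2": [40.0] * 3 + [25.0] * 4 + [40.0] * 3},
            index=[f"m{i}" for i in range(10)])
        calls, meta = self._calls(frame)
        regions = detection_venn(calls, meta, ["g1", "g2"])
        assert regions[("g1",)] == 3
        assert regions[("g2",)] == 4
        assert regions[("g1", "g2")] == 0
        assert regions[()] == 3

    def test_planted_shared_core_and_region_sum(self):
        spec = SimSpec(seed=4, n_assays=300, ct_noise_sd=0.0)
        lines = ["A", "B", "C", "D"]
        matrix, meta, truth = simulate_cell_media_fcs(spec, lines)
        calls = detection_filter(matrix, StudyConfig())
        cell_meta = [m for m in meta if m.material is Material.CELLS]
        calls = calls.loc[[a for a in matrix.assays if a.startswith("hsa-miR-sim")]]
        regions = detection_venn(calls, cell_meta, lines)
        assert sum(regions.values()) == len(calls)
        expressed = truth.pivot(index="assay", columns="cell_line",
                                values="expressed")
        assert regions[tuple(sorted(lines))] == int(expressed.all(axis=1).sum())

    def test_single_group_degenerate_partition(self):
        frame = pd.DataFrame({"g1": [25.0, 40.0]}, index=["a", "b"])
        calls, meta = self._calls(frame)
        regions = detection_venn(calls, meta, ["g1"])
        assert regions == {("g1",): 1, (): 1}


class TestConcordance:
    def test_planted_markers_recovered_with_full_transfer(self):
        spec = SimSpec(seed=7, n_assays=200, transfer_detection_prob=1.0)
        matrix, meta, truth = simulate_xenograft_plasma(spec, ["benign"], 4)
        cand = xenograft_plasma_concordance(matrix, meta, "benign",
                                            StudyConfig())
        planted = set(truth[truth.kind == "planted_marker"].assay)
        assert set(cand.assay_names()) == planted
        assert all(bf == 1.0 for _, _, bf in cand.candidates)

    def test_half_transfer_markers_pass_at_default_fraction(self):
        # 2 of 4 plasmas is exactly the >=50% rule
        spec = SimSpec(seed=1, n_assays=100, ct_noise_sd=0.0)
        matrix, meta, truth = simulate_xenograft_plasma(spec, ["g"], 4)
        calls = detection_filter(matrix, StudyConfig())
        planted = sorted(truth[truth.kind == "planted_marker"].assay)
        plasma_ids = [m.sample_id for m in meta
                      if m.material is Material.PLASMA and m.group == "g"]
        frac = calls.loc[planted, plasma_ids].mean(axis=1)
        cand = xenograft_plasma_concordance(matrix, meta, "g", StudyConfig())
        expected = {a for a in planted if frac[a] >= 0.5}
        assert set(cand.assay_names()) == expected
        assert {a: bf for a, _, bf in cand.candidates} == \
            {a: pytest.approx(frac[a]) for a in expected}

    def test_control_contaminated_marker_always_excluded(self):
        spec = SimSpec(seed=3, n_assays=150, transfer_detection_prob=1.0)
        matrix, meta, truth = simulate_xenograft_plasma(
            spec, ["g"], 4, n_control_contaminated=2)
        cand = xenograft_plasma_concordance(matrix, meta, "g", StudyConfig())
        contaminated = set(truth[truth.kind == "contaminated_marker"].assay)
        assert contaminated <= set(cand.excluded_by_control)
        assert contaminated.isdisjoint(cand.assay_names())

    def test_monotone_in_plasma_fraction_threshold(self):
        spec = SimSpec(seed=5, n_assays=150, transfer_detection_prob=0.6)
        matrix, meta, _ = simulate_xenograft_plasma(spec, ["g"], 6,
                                                    n_markers_per_group=10)
        sets = {}
        for f in (0.0, 0.5, 1.0):
            config = StudyConfig(plasma_detection_fraction=f)
            sets[f] = set(xenograft_plasma_concordance(
                matrix, meta, "g", config).assay_names())
        assert sets[1.0] <= sets[0.5] <= sets[0.0]

    def test_missing_controls_is_an_error(self):
        spec = SimSpec(seed=5, n_assays=60)
        matrix, meta, _ = simulate_xenograft_plasma(spec, ["g"], 2)
        no_controls = [m for m in meta if m.role is not Role.BACKGROUND]
        with pytest.raises(ValueError, match="control"):
            xenograft_plasma_concordance(matrix, no_controls, "g",
                                         StudyConfig())


class TestDetectionSummary:
    def test_counts_and_integer_percent(self):
        rng = np.random.default_rng(0)
        n, k = 384, 307
        frame = pd.DataFrame(40.0, index=[f"m{i}" for i in range(n)],
                             columns=[f"csf{j}" for j in range(4)])
        detected = rng.choice(n, n - k, replace=False)
        for i in detected:
            frame.iloc[i, rng.integers(0, 4)] = 30.0
        calls = detection_filter(CtMatrix(frame), StudyConfig())
        summary = detection_summary(calls)
        assert summary.n_detected_none == k
        assert summary.percent_none == 80
        assert summary.fraction_none == pytest.approx(k / n)

    def test_fully_detected_panel(self):
        frame = pd.DataFrame(25.0, index=["a", "b"], columns=["s1", "s2"])
        summary = detection_summary(detection_filter(CtMatrix(frame),
                                                     StudyConfig()))
        assert summary.n_detected_all == summary.n_total == 2
        assert summary.n_detected_none == 0

    def test_report_percentage_rounding(self):
        assert percentage(101, 291) == 34.7
        assert percentage(182, 300) == 60.7
        assert percentage(1, 3, 0) == 33.0
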