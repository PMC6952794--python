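# Methods

## Data model

The pipeline's currency is the Ct matrix: one PCR quantification-cycle
value per (assay, sample), with non-detects stored at a sentinel of 40
cycles (the run's cycle limit). All values are kept on the Ct (log2
abundance) scale until the final report; technical replicates and
overlapping array cards are averaged on that scale, because qPCR noise is
approximately Gaussian in cycles, not in linear abundance. Assay
identifiers are matched exactly and case-sensitively: species prefixes
(`hsa-`, `mmu-`, `ath-`, `cel-`) are semantically distinct (the spike-in
is a plant microRNA precisely so that it cannot be endogenous).

## Detection and classification rules

Detection is strict: Ct < 34. The boundary value 34.0 itself counts as
not detected; the choice is arbitrary at measurement precision but is
fixed and documented so that detected sets are monotone in the threshold.

Secretion classification uses the cells / conditioned-medium / fetal-calf-
serum triplet with FCS taking precedence: any assay detected in FCS is
`background` regardless of the cellular signal, because the culture medium
itself contains (mostly bovine) microRNAs picked up by imperfectly
species-specific assays. Among the rest, `secreted` requires detection in
both cells and medium, `not_secreted` detection in cells only, and
`not_expressed` covers the remainder. These four labels partition the
panel.

Background subtraction is deliberately conservative: detection in ANY
negative-control sample of the matching material class excludes an assay.
The concordance rule for in-vivo candidates requires detection in ALL
xenografts of a histology group (strict, no tolerance for a missing
replicate) and in at least `plasma_detection_fraction` (default 0.5) of
matched plasmas. Matched pairing via `paired_with` metadata is honored
when complete; otherwise group-level fractions are used.

## Quantification

ΔCt = Ct(target) − Ct(normalizer), with hsa-miR-30b-5p as default
endogenous reference; ΔΔCt subtracts the arithmetic mean ΔCt of the
control group (mean taken on the ΔCt scale), so the control group's mean
log2 relative level is exactly 0. An alternative calibrator — the
evaluable sample with the highest ΔCt — is available for analyses where
controls belong to the comparison itself; the two modes are never mixed
within one analysis.

Non-detect policy: a sample whose normalizer is non-detect has no
within-sample scale and is not evaluable (this is why CSF, where
miR-30b-5p is essentially absent, cannot be normalized this way). A
non-detect target is dropped by default, or — under the explicit
`ceiling` policy — censored at the sentinel and flagged, never imputed
below the detection ceiling.

## QC gates

Spike-in recovery is judged against the cohort median (±2 Ct), not an
absolute Ct, since the gate is defined by within-run variation.
The hemolysis ratio is computed as Ct(miR-23a-3p) − Ct(miR-451a), a
log2-ratio convention chosen because the shipped cutoff magnitude (9.15)
and the visual-score relationship are expressed on the Ct-difference
scale; user-supplied cutoffs are never converted silently. Calibration
treats any visible hemolysis (visual score ≥ 1) as the positive class,
maximizes Youden's J over all observed thresholds, reports the midpoint
between the bracketing observed ratios, and breaks ties toward higher
specificity — the QC goal is to avoid discarding clean samples. The
shipped 9.15 default is cohort-specific and recalibratable.
Inhibition (e.g. heparin) is flagged only when the spike-in exceeds the
cohort median by more than the tolerance AND the endogenous normalizer is
depressed by the same margin; a spike shift alone is a recovery failure.

## Validation statistics

ROC curves are built over all observed thresholds with strict `>` calls
plus ±∞ sentinels; AUC is the trapezoid over (FPR, TPR) traversed in
descending-threshold order, which equals the Mann-Whitney concordance
U/(n₁n₂) including tie credit — an identity the tests assert on random
inputs. ROC/Youden code is written in-package because the midpoint-cutoff
and specificity tie-break conventions differ from library defaults;
scikit-learn serves as an independent cross-check in tests only.

Two-group comparisons use the Mann-Whitney U test (Wilcoxon signed-rank
when paired); three or more use Kruskal-Wallis followed by Dunn's
rank-based pairwise test with tie correction. Dunn p-values are two-tailed
and Holm-adjusted over the pairwise family; the adjustment method is
recorded in the output since conventions vary. All-tied input returns
p = 1 with a warning rather than an error.

Performance metrics (sensitivity, specificity, PPV, NPV, accuracy) are
reported as percentages with half-up rounding to one decimal; ratios with
a zero denominator are reported absent, never as 0. One printed
performance cell in the published table this package's fixtures mirror
(a PPV of 100 alongside specificity 83.3 and accuracy 81.0 under 15
cases / 6 controls) is arithmetically inconsistent with any integer
confusion matrix; the tests reproduce the three self-consistent rows and
leave that cell aside.

Combined marker rules operate on the log2 relative scale with strict `>`:
`any_above` (positive if at least one marker exceeds its cutoff) is
monotone — its calls always contain the `all_above` calls.

## Decay kinetics

Series are rescaled to percent of the preoperative baseline (the last
sample at time ≤ 0; "preoperative" is singular per patient). The
half-life comes from a least-squares fit of log2(level) vs time
(−1/slope hours), which is robust to irregular sampling grids; the
descriptive companion estimate, the log-interpolated time to 50% of
baseline, equals the fitted half-life exactly on a pure exponential.
Monotone decline is evaluated on the raw levels — a marker that
fluctuates upward after surgery is unreliable for follow-up regardless of
its fitted slope. Non-positive levels are censored at half the smallest
positive observed level and flagged.

## Synthetic cohorts

The generator emulates exactly the structure the pipeline assumes:
additive Gaussian noise in Ct space (σ = 0.3 cycles by default, matching
typical replicate scatter; equivalently log-normal abundance), a hard
ceiling at Ct 40, expressed assays placed at mean Ct 26 (clipped to
18–33, i.e. well inside the detection range so σ = 0 classification is
exact), a 30% FCS/host background fraction, 35% secretion probability
among expressed assays, secreted media Ct equal to cellular Ct (offset 0,
matching observed comparable cell/media values), spike-in at Ct 22 ±0.3,
a 2-cycle miR-451a depression per hemolysis visual score, 50%
tissue-to-plasma transfer probability, and a 3 h decay half-life. Test
problem sizes (panels of 30–768 assays, cohorts of 12–2000 samples,
500-replicate transfer sweeps) were chosen as the smallest designs at
which each statistical check is well powered.

What the generator does **not** emulate: amplification-efficiency
differences between assays, primer cross-reactivity within microRNA
clusters, plate/batch effects, sample-volume differences between serum
and plasma, and non-Gaussian heavy-tailed contamination. Passing tests
therefore demonstrate the correctness of the computational rules and
their statistical behavior under the stated noise model — not robustness
to every real-world artefact, which is exactly why the QC gates exist.

## Known limitations

- The hemolysis cutoff and the detection threshold are instrument- and
  protocol-dependent; shipped defaults should be recalibrated per cohort.
- Dunn's adjustment method is not standardized across software; Holm is
  used and recorded per run.
- Efficiency-corrected (Pfaffl) quantification and absolute standard-curve
  quantification are out of scope; ΔΔCt assumes comparable amplification
  efficiencies.
- The amplification-quality pre-filter applied by array-card vendor
  software is not reproducible from exported Ct values; analyses that need
  one should subset the Ct matrix to the assays that passed it upstream —
  no attempt is made to infer it.
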