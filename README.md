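# liqmir

Identification and validation of circulating microRNA biomarkers from
RT-qPCR Ct matrices — a reusable implementation of the liquid-biopsy
discovery workflow used in germ-cell-tumor research: screen widely in
vitro and in vivo with the right negative controls, then validate the few
candidates that survive with targeted statistics.

## Who this is for

Groups running TaqMan-array-style RT-qPCR panels on cells, conditioned
media, xenograft tissue, plasma, serum or CSF, who need a reproducible
path from raw Cq exports to validated marker candidates — including the
pre-analytical quality gates (spike-in recovery, hemolysis, inhibition)
that routinely confound liquid-biopsy studies.

## The model

Every quantity lives in Ct (quantification-cycle) space, where one cycle
is a two-fold abundance difference and lower Ct means more template.
Non-detects are encoded at the cycle ceiling (Ct 40).

- **Detection**: an assay is detected when Ct < 34 (strict).
- **Secretion** (per cell line, from the cells / conditioned-medium / FCS
  triplet): *secreted* = detected in cells and medium but not in fetal
  calf serum; *not secreted* = detected in cells only; anything detected
  in FCS is culture background, never a candidate.
- **Concordance** (in vivo): a candidate for a histology group must be
  detected in **all** tumor xenografts of the group, in **none** of the
  normal-animal controls, and in at least 50% of matched endpoint plasmas.
- **Quantification**: ΔCt = Ct(target) − Ct(miR-30b-5p), ΔΔCt = ΔCt −
  mean ΔCt of controls, reported as log2 relative level = −ΔΔCt
  (i.e. log2 of 2^−ΔΔCt).
- **Validation**: Mann-Whitney / Kruskal-Wallis–Dunn group comparisons,
  ROC with trapezoidal AUC (provably equal to the rank concordance),
  Youden-index cutoffs, confusion-matrix performance, and combined
  marker rules (positive when *any* / *all* markers exceed their cutoffs).
- **QC**: spike-in (ath-miR-159a) recovery within ±2 Ct of the cohort
  median; hemolysis via the miR-23a/451a ratio, Ct(23a) − Ct(451a), with
  a recalibratable Youden cutoff (shipped default 9.15); inhibition
  flagged when spike **and** normalizer are jointly depressed.
- **Kinetics**: post-surgery decay fitted as log2(level) vs time; a
  useful marker shows a monotone decline with a short half-life
  (ln 2 / decay rate).

A seeded synthetic-cohort generator (`liqmir.synth`) reproduces the
statistical structure of all of these designs, so the entire pipeline is
testable without any external data.

## Worked example

Simulate a xenograft/plasma study, then select benign-histology candidates:

```
$ liqmir simulate --preset in_vivo --seed 7 --out-dir sim
wrote sim/ct_matrix.csv
$ liqmir discover --ct sim/ct_matrix.csv --meta sim/sample_meta.csv \
      --mode in_vivo --group benign --out-dir disc
benign: 4 candidates, 116 control-excluded
$ head -3 disc/candidates.csv
assay,tissue_fraction,biofluid_fraction
hsa-miR-sim0337,1.0,0.75
hsa-miR-sim0364,1.0,0.75
```

Four markers were detected in all four benign xenografts, absent from the
normal-mouse controls, and found in ≥50% of matched plasmas (the two shown
in 3 of 4); 116 assays — mostly host-animal background — were discarded
because they appeared in normal-control samples.

Quantify and validate a planted serum marker against controls:

```
$ liqmir quantify --ct simc/ct_matrix.csv --meta simc/sample_meta.csv \
      --assay hsa-miR-885-5p --control-group control --out-dir quant
quantified 21 samples for hsa-miR-885-5p
$ liqmir validate --rel quant/relquant.csv --meta simc/sample_meta.csv \
      --assay hsa-miR-885-5p --out-dir val
hsa-miR-885-5p: AUC 1.000, cutoff 1.866
```

The cohort preset plants a 4-fold (log2) case elevation over 15 cases and
6 controls, which this cohort separates perfectly (AUC 1.0); the Youden
cutoff 1.87 on the log2 relative scale sits between the two groups.

Every subcommand writes a plain-text manifest (parameters, seed, input
digests) next to its outputs; re-running a manifest reproduces the outputs
byte for byte.

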