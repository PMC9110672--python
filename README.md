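# pribin

Bin-based analysis and visualization of high-dimensional cytometry data — an
implementation of **PRI** ("pattern recognition of immune cells") for mass
cytometry (CyTOF) and flow cytometry, aimed at immunologists and
computational biologists who want reproducible, non-clustering sample
comparison.

## The method

Instead of clustering cells, PRI grids the plane of two markers *x* and *y*
(after the arcsinh transform, `asinh(0.1·I)` with signal intensity *I*) into
fixed bins of width 0.2 × 0.2 asinh and summarizes a third marker *z* per
bin:

- **MSI** — mean signal intensity of *z* over all cells in a bin;
- **MSI⁺** — mean of *z* over only the *z*-positive cells (`z ≥ threshold`);
- **density** — cells per bin.

Bin plots color these statistics blue → yellow → red; all events enter the
analysis but only bins with ≥ 5 cells are displayed. One threshold per axis
cuts the plane into quadrants Q1–Q4, annotated with the percentage of all
cells per quadrant (black) and the percentage of *z*⁺ cells within each
quadrant (red). From these, per-sample scalar features are engineered —
threshold-independent legend endpoints (max bin-MSI, bin-MSI range) and
threshold-dependent quadrant frequencies — and compared between two groups
with the exact Mann-Whitney U test (`*` p ≤ 0.05 … `****` p ≤ 0.0001).
Supporting tools cover cohort QC (median-profile MDS, Ward clustering,
non-redundancy score for marker ranking), four-parameter co-expression pie
charts, FCS 3.0/3.1 I/O, rectangular sequential gating, and a synthetic
cohort generator with planted, ground-truth-tracked group effects.

## Worked example

`examples/feature_classification.py` builds the default synthetic cohort —
6 "effective" vs 6 "ineffective" samples of 50,000 CD4⁺ T cells over a
9-marker panel, with the effective arm's CD90-high/CD44⁺ effector population
shifted by +0.8 asinh in CD86 and +0.5 in Ki67 — extracts the CD90 × CD44
feature panel and compares the groups:

```
feature matrix: 12 samples x 53 features
                              median_a  median_b  p_value stars
feature
CD90_CD44_CD86__bin_msi_span    2.0829    1.2025   0.0022    **
CD90_CD44_CD86__max_bin_msi     2.2415    1.3891   0.0022    **
CD90_CD44_CD86__pct_zpos_Q3    89.4312   17.1795   0.0022    **
CD90_CD44_Ki67__max_bin_msi     2.4810    1.9927   0.0022    **
CD90_CD44_Ki67__bin_msi_span    2.4552    1.9170   0.0022    **
CD90_CD44_Ki67__pct_zpos_Q3    95.8539   92.1378   0.0022    **
CD90_CD44_CD86__pct_zpos_Q2     4.9028    2.5542   0.0649    ns
CD90_CD44_Ki67__pct_zpos_Q4     0.0000   75.0000   0.0652    ns
```

The planted CD86 and Ki67 effects surface as the top features at
p = 0.0022 — the smallest two-sided p attainable for 6 vs 6 (2/924) — while
`median_a` (effective) vs `median_b` (ineffective) gives the direction:
e.g. the maximum CD86 bin-MSI rises from 1.39 to 2.24 asinh and the CD86⁺
share of Q3 (CD90-high/CD44⁺) from 17% to 89%. Unshifted markers such as
CD27 stay non-significant. Other walkthroughs: `examples/bin_plot_basics.py`
(bin plot + quadrant numbers), `examples/cohort_qc.py` (MDS, flags, NRS
ranking), `examples/coexpression_pies.py` (Ki67/Tbet co-expression).

## Command line

```bash
pri simulate --out cohort/ --seed 1          # synthetic FCS cohort + manifest
pri qc --samples cohort/manifest.csv --out qc/
pri plot --input cohort/effective_1.fcs --x CD90 --y CD44 --z CD86 \
    --stat msi --thresholds 2.6 1.6 1.5 --out plot.png
pri run --config run.yaml --out results/     # full pipeline
```

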