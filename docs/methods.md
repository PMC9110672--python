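# Methods

## Model and procedure

PRI treats every pair of markers (x, y) as a plane of "mini-gates": after
variance stabilization, the plane is cut into square bins and a third
marker z is summarized per bin. The analysis is deliberately
non-clustering — partially overlapping subpopulations that frustrate
cluster assignment still produce distinct bin patterns — and every
computed number is a deterministic function of the events, so results are
exactly reproducible.

Stages: FCS read → arcsinh transform → sequential rectangular gating →
cohort QC → bin grids and plots → per-sample features → two-group
Mann-Whitney comparison. Each stage consumes only the previous stage's
output and serializes its artifacts, so a run can be audited or restarted
stage by stage.

## Transform

Signal intensities are transformed channel-wise with
`t = asinh(c · I)`, cofactor `c = 0.1` by default. The cofactor sets the
linear-to-logarithmic transition scale: counts below ~1/c behave linearly,
larger counts logarithmically. Some ecosystems write the same family as
`asinh(I / b)`; both conventions are supported
(`TransformSpec(convention="multiply" | "divide")`) and the multiply form
is the documented default. The transform is strictly monotone per channel,
applied exactly once (a second application raises), and invertible, which
the tests exploit.

## Binning and statistics

- Bin index of an event: `(floor(x/w), floor(y/w))` with width `w = 0.2`
  asinh. The grid is anchored at the origin of the transformed scale —
  reproducible and parameter-free; there is no data-dependent grid offset.
- Per bin: cell count, MSI (mean z), and with a z threshold: z⁺ count,
  MSI⁺ (mean z over z⁺ cells), z⁺ frequency. Ties sit on the positive
  side: `z ≥ threshold` is positive, `x ≥ x_threshold` is "high".
- All events are retained in the stored grid. The five-cell rule
  (`min_cells_per_bin = 5`) is a display/feature-eligibility flag, not a
  filter: `displayed` for n ≥ 5, `displayed_pos` for n_z⁺ ≥ 5 (MSI⁺ plots
  draw displayed bins below that in gray).
- Non-finite coordinates are excluded from binning with a warning and a
  count, never silently.
- Quadrants: one threshold per axis, four regions. The default naming is
  Q1 = low/low, Q2 = low-x/high-y, Q3 = high/high, Q4 = high-x/low-y;
  published figures do not always share one convention, so the mapping is
  configuration (`BinConfig.quadrant_layout`). Black numbers are percent
  of all events; red numbers percent of z⁺ cells *within* the quadrant;
  empty quadrants report missing, not zero.
- Co-expression: within each quadrant, cells are split into the four joint
  categories of two z markers' positivity; fractions per quadrant sum to 1.

## Features

Feature names encode their configuration
(`CD90_CD44_CD86__max_bin_msi`, `CD90_CD44__pct_Q2`,
`CD90_CD44_CD86__pct_zpos_Q3`). Two families:

- *Threshold-independent*: max bin-MSI, min bin-MSI and their span over
  displayed bins — exactly the endpoints of the dynamic color legend. They
  are computed over the displayed set (legend semantics) and are provably
  independent of any z threshold; raising `min_cells_per_bin` can only
  shrink the displayed set, so max bin-MSI is non-increasing in it.
- *Threshold-dependent*: the black and red quadrant percentages, which
  require user-set axis and z thresholds. Thresholds are scientific
  inputs, not fitted quantities; the package never chooses them.

Missing features (marker absent, no displayed bin, empty quadrant) are
missing values, never zeros.

## Group comparison

Two-sided Mann-Whitney U. With no ties and total n ≤ 20 the exact null
distribution is used (the suite verifies it against full enumeration of
all C(n_a+n_b, n_a) labelings); otherwise a normal approximation with
midrank tie correction and continuity correction. An all-tied feature is
reported as U = n_a·n_b/2, p = 1. Star coding: `*` ≤ 0.05, `**` ≤ 0.01,
`***` ≤ 0.001, `****` ≤ 0.0001, else `ns`. P-values are reported
unadjusted — the convention for small exploratory cytometry cohorts, where
each feature is judged on its own — with a Benjamini-Hochberg column
(`p_adj_bh`) added as a labelled extension for users who want family-wise
control.

## Quality control

Samples are summarized by exact per-marker medians of the transformed
intensities (midpoint of central order statistics for even n). Classical
(Torgerson) MDS — double-centering of the squared Euclidean distance
matrix and eigendecomposition — gives the 2-D overview map; it is exact
when profiles lie in a plane, and the implementation is the textbook one
because the common SMACOF-style MDS solvers are iterative and need not
reproduce it. Ward clustering runs on the same profiles. The
non-redundancy score of marker m is `Σ_k λ_k |loading_{m,k}|` over the
top 3 principal components of the cell × marker matrix (components
configurable); it is not scale-invariant by design, so inputs must be
transformed first. QC flags — cell count below a threshold (default
1000), or MDS position farther from the group centroid than 3× the median
within-group centroid distance — are advisory; exclusion happens only when
`qc.exclude_flagged` is set, and then with a loud log message.

## Synthetic cohorts

The generator emulates gated CD4⁺ T-cell samples as Gaussian mixtures in
asinh space with diagonal covariance: four populations (naive CD44⁻,
memory CD44⁺, a CD90-high/CD44⁺ Tbet⁺Ki67⁺ effector subset, Foxp3⁺
regulatory cells) over a 9-marker panel, per-marker sd 0.35 asinh,
proportions 0.45/0.30/0.15/0.10. The default design is a two-arm study,
6 samples per arm, 50,000 events per sample; the "effective" arm shifts
the effector population by +0.8 asinh in CD86 and +0.5 in Ki67, leaving
CD27, KLRG1 and PDL1 as negative controls. A per-sample jitter (sd 0.05
asinh added to every population mean of a sample) emulates biological
replicate variability. The true population index of each cell rides along
in an extra channel, so any downstream statistic can be checked against
ground truth. Draws are fully deterministic given (seed, group, sample
index) via independent seed sequences, and cohorts can be written to FCS
on the raw scale (`sinh(v)/cofactor`) so the standard pipeline applies
unmodified.

What the generator does *not* emulate: marker correlations within a
population (diagonal covariance; full covariance would slot in without
interface changes), instrument artifacts (spillover, bead drift,
doublets), zero-inflation of mass-cytometry counts, and non-Gaussian
tails. Passing tests therefore demonstrate correctness of the computation
and sensitivity to planted mean shifts under clean mixtures — not
robustness to every property of real CyTOF data.

## Numerical choices

- Bin statistics use vectorized grouped means; the suite bounds any
  summation-order discrepancy against a per-event loop at 1e-9 relative
  (observed ~1e-15).
- Color scales: piecewise-linear blue → yellow → red with 50 quantization
  levels; values clamped to the scale; a degenerate scale
  (v_min = v_max) maps to the palette midpoint. Dynamic scales use one
  grid's displayed min/max, common scales the pooled min/max of a panel.
- Quadrant percentages are printed to 1 decimal, rounding half away from
  zero; stored values stay unrounded.
- SVG output is rendered with a fixed hash salt and no timestamp metadata,
  so identical inputs give byte-identical vector files.
- FCS writing uses FCS 3.1, list mode, little-endian float32 — the
  dominant modern dialect; reading accepts FCS 3.0/3.1 with float32/
  float64/integer list-mode data. Round-trips are exact at float32
  precision.
- Gates are axis-aligned rectangles (sufficient for the standard
  live/singlet → bead-exclusion → CD45⁺ → CD3⁺CD19⁻ → CD4⁺CD8⁻ chain,
  shipped as a template with placeholder thresholds); polygon gates are
  out of scope. Rectangular chains are order-independent, which is tested
  as a property.

## Problem sizes in the validation suite

The replicate simulation study uses 20 cohorts of the full default design
(12 × 50,000 events); oracle-agreement checks run on 100 random tables of
up to 10⁴ events; the enumeration check covers every tie-free group-size
split with total n ≤ 12; the end-to-end determinism check uses a
3 + 3 × 3,000-event cohort. These sizes make the whole suite complete in
well under a minute while exercising the statistics at realistic scale.

## Known limitations

- Quadrant layout and manual thresholds must be aligned with the
  conventions of any external figures before numerical comparison.
- The exact Mann-Whitney path requires tie-free data; heavily discretized
  features fall back to the approximation.
- NRS ranks markers within the analyzed (already gated) population;
  rankings are not comparable across different gates.
- Binning is limited to two axes; higher-order combinatorics are expressed
  through side-by-side z panels and pairwise co-expression, not
  higher-dimensional grids.
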