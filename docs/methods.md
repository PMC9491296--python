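# Methods

This note records the statistical model behind `nlfnc`, the estimator
and generator choices that were genuinely open, and what the synthetic
validation does and does not establish.

## The dependence model

For time courses `x, y ∈ R^T` the package separates dependence into a
linear part and an explicitly nonlinear remainder:

- **Linear part**: the OLS fit `ŷ = αx + β`. Its residual
  `z = y − ŷ` is exactly uncorrelated with `x` (normal equations), so
  the decomposition is clean at the level of second moments.
- **Nonlinear remainder**: `NMI(x, z)`, mutual information normalized
  into `[0, 1]`, estimated by plug-in entropies on equal-width
  histograms. Because regression is directional, the final statistic
  symmetrizes by averaging the two directions:
  `eNMI(x,y) = ½[NMI(x, z_{y|x}) + NMI(y, z_{x|y})]`, each direction
  with its own histogram.
- **Boosted metric**: `ρ + sign(ρ)·eNMI`. It preserves the sign of the
  linear relationship (direction is not well defined for the nonlinear
  part) and never has smaller magnitude than `ρ`; `sign(0)` is taken as
  0 so the value degenerates to `ρ` at exactly zero correlation.

Residualization removes only the *linear* component; eNMI is therefore
a lower bound on "all dependence minus linear dependence" as seen
through the histogram estimator, not a decomposition of information.

## Entropy estimator

Open choices, fixed as follows:

- **Estimator**: plug-in (maximum likelihood) on a `B×B` joint grid
  spanning each variable's observed min–max range. Marginals are the
  joint grid's row/column sums, which guarantees `MI ≥ 0` and makes
  `NMI(x,x) = 1` exact. Plug-in MI is biased upward at small `T`
  (≈ `(B−1)²/(2T ln 2)` bits); all group comparisons are therefore
  *contrasts* of eNMI between conditions sharing `T` and `B`, where the
  bias cancels to first order. Absolute eNMI values should not be read
  as calibrated information measures.
- **Bin count**: Rice rule `B = ⌈2·T^(1/3)⌉` (20 at `T=1000`, 11 at
  `T=159`), overridable (`--bins/--bin-rule`). Data-adaptive and
  standard; at `n=1000` it reproduces the canonical three-case NMI
  magnitudes.
- **Normalization**: the default divides MI by the **joint entropy**
  `Hxy`; `1 − MI/Hxy` is a proper metric (the normalized information
  distance of Kraskov et al.), so NMI retains a similarity-metric
  interpretation. Dividing by `max(Hx, Hy)` (Horibe's metric form) is
  available as `normalization="max"`. The joint form is the default
  because it is the configuration under which the package reproduces
  the established three-case reference values (e.g. quadratic-case
  NMI ≈ 0.255 before and after linear removal at `n=1000`, `B=20`);
  the max form runs ≈ 0.39 on the same data. Both normalizations share
  every qualitative property the package relies on (range, affine
  invariance, invariance of eNMI conclusions).
- **Binning convention**: values exactly on an internal edge go to the
  higher bin; the maximum goes in the top (right-closed) bin. Fixed so
  tests can be bit-exact.
- **Degenerate inputs**: a constant series has zero entropy; NMI with a
  constant series is defined as 0 (nothing measurable), which also
  makes the eNMI diagonal naturally 0 — the residual of a series on
  itself is the zero vector. Residuals whose range is below `1e-10`
  of the parent series' range are treated as that zero vector, so an
  exactly affine pair has eNMI 0 rather than an artifact of binning
  rounding noise.
- **Affine invariance**: min–max equal-width binning maps affinely
  transformed data to identical bin assignments (positive scale), so
  NMI is invariant to per-series standardization; whether inputs are
  z-scored is immaterial.

## The three-case validation

`simulate_three_cases` draws `x ~ U[0,1]` and builds `y1 = 2x+ε`
(linear), `y2 = 5(x−½)²+ε` (purely quadratic: `Cov(x, (x−½)²) = 0`),
`y3 = y2-type + 2x + ε` (mixed), with `ε ~ N(0, σ²)` drawn
independently per case. `σ = 0.1` by default, back-solved from the
linear case's reference correlation (`√((1/3)/(1/3+σ²)) ≈ 0.985`).
Expected behaviors, all asserted in the acceptance suite:
correlations ≈ 0.985 / ≈ 0 / ≈ 0.831; post-removal correlations are
numerically zero; quadratic-case NMI is invariant under linear removal
(mean |Δ| < 0.02 over 50 draws); eNMI of the linear case is the
smallest of the three in ≥ 48/50 replicates.

## Cohort generator

`simulate_cohort` emulates ICA component time courses at study scale
(default `T = 159`, `C = 10`, 50 subjects/group). Each component is a
variance-normalized mixture

    component_i = sqrt(1 − Σ w²) · white noise + Σ w · factor

- A **linear coupling** of weight `λ` adds the same latent factor to
  both components of a pair, giving population correlation `λ²`
  (default `λ = 0.4` on within-domain pairs → ρ = 0.16, the magnitude
  typical of mean FNC matrices).
- A **nonlinear coupling** of weight `γ` adds a latent factor `u` to
  one component and the standardized centered `u²` to the other;
  `Cov(u, u²) = 0` for symmetric `u`, so the pair is uncorrelated but
  dependent — the cohort analogue of the quadratic case.
- Latent factors are AR(1)-smoothed (coefficient 0.3) **before** the
  quadratic transform, then components are z-scored. Smoothing the
  mixed signal instead would partially destroy the quadratic relation
  between the observed components; placing the autocorrelation in the
  latent network signals preserves it and is the more faithful reading
  of where temporal structure lives.
- **Group effects**: group B adds `group_delta` to `γ` on designated
  pairs (default 0.8, i.e. a 64 % signal-variance share — a strong,
  unambiguous nonlinear effect). The generator validates that every
  component's total squared coupling weight stays ≤ 1, so the variance
  normalization leaves all *linear* correlations identical across
  groups: the injected difference is purely nonlinear by construction.
- All randomness flows from a single seed through spawned per-subject
  substreams; outputs are bit-reproducible. The latent factor of a
  zero-weight coupling is still drawn, keeping the two groups'
  RNG streams aligned.

What the generator does **not** emulate: hemodynamic response
convolution, band-limited fMRI spectra beyond AR(1) smoothing,
physiological noise, motion artifacts, inter-subject variability in
coupling strength, or non-quadratic nonlinearities. Passing tests show
the estimator and pipeline recover the kinds of dependence they were
designed for at realistic `T` and group sizes — not that real fMRI
contains such dependence.

## Group statistics

- **Per-subject matrices**: all `C(C−1)/2` pairs per metric; the eNMI
  diagonal is 0, correlation-based diagonals 1. A constant component's
  cells get the metric's degenerate value with a logged warning.
- **Two-sample comparison**: Student's pooled-variance t-test per cell
  (A − B orientation; Welch behind `equal_var=False`), BH step-up FDR
  across the unique off-diagonal cells, each metric corrected
  separately. Signed maps are `−log10(p)·sign(t)`. No Fisher
  z-transform is applied to correlations by default (kept simple and
  metric-uniform).
- **Min-cell test**: the cell with minimum mean is the reference; each
  other cell is tested one-sided ("greater") with a paired t-test
  across subjects (a fixed-constant reference variant is available).
  Zero-variance cells and the reference itself are untestable and left
  unmasked.
- **Block modularity**: observed statistic = mean within-domain minus
  mean between-domain cell value; null from permuting the
  component-to-domain assignment; `p = (1 + #{null ≥ obs})/(1 + n_perm)`.
  This is a transparent substitute for random-matrix modularity
  analyses; it tests the same claim type (block structure beyond
  chance) with an explicit permutation null.
- **Joint-distribution differences**: per-subject `G×G` densities
  (default `G = 20`) on edges pooled across *all* subjects of both
  groups, so the group-mean difference is comparable cell-by-cell and
  sums to 0 by construction.
- **Spectra**: one-sided FFT amplitudes scaled so non-DC amplitude
  squares sum to the signal variance (Parseval), with frequencies in
  Hz from the sampling interval (default 2 s).

## Problem sizes in the validation suite

The acceptance checks run the three-case analyses at `n = 1000` with 50
seeds; calibration uses 8-component cohorts (20/group for 200 label
shuffles, 12/group for 100 global-null replicates); recovery uses the
default 10-component, 50-subjects-per-group cohort over 20 replicates.
These sizes give stable rates (binomial SE ≈ 3–4 % on the recovery
rate) while keeping the full suite around a minute of compute.

## Known limitations

- Plug-in NMI bias grows with `B²/T`; at `T = 159`, `B = 11` the
  independent-pair floor is ≈ 0.06–0.08 (joint normalization). Only
  contrasts across matched conditions are interpretable.
- eNMI removes the *global* linear fit; piecewise-linear or lagged
  linear structure appears as "nonlinear".
- The boosted metric mixes units (correlation + NMI); it is a
  sensitivity device, not a decomposition, and its two addends cannot
  be recovered from the sum.
- Time-lagged, windowed/dynamic, and k-NN/Kraskov estimator variants
  are out of scope.
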