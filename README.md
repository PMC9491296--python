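# nlfnc — explicitly nonlinear functional network connectivity

Functional network connectivity (FNC) studies almost always quantify the
dependence between component time courses — e.g. the ICA-derived
intrinsic connectivity networks of resting-state fMRI — with the Pearson
correlation, which sees only the *linear* part of the relationship. Two
networks can be strongly coupled through a purely nonlinear relationship
(a quadratic one has exactly zero correlation) and be invisible to the
standard analysis.

`nlfnc` measures the **explicitly nonlinear** part of pairwise
dependence and carries it through a full group-analysis pipeline. For a
pair of time courses `x`, `y` of length `T`:

1. **Remove the linear relationship.** Fit `ŷ = αx + β` by ordinary
   least squares and keep the residual `z = y − ŷ`; by the normal
   equations, `corr(x, z) = 0` to machine precision, so anything left
   is nonlinear.
2. **Measure what remains with normalized mutual information.**
   Entropies are plug-in estimates on equal-width histograms
   (`B = ⌈2·T^(1/3)⌉` bins by default, the Rice rule), with marginals
   taken from the joint grid so that `MI = Hx + Hy − Hxy ≥ 0`, and

       NMI(x, y) = (Hx + Hy − Hxy) / Hxy        (default)
       NMI(x, y) = (Hx + Hy − Hxy) / max(Hx, Hy) (option)

   both in `[0, 1]` (0 = independent on the grid, 1 = identical).
3. **Symmetrize.** `eNMI(x, y) = ½·[NMI(x, z_yx) + NMI(y, z_xy)]`,
   averaging the two regression directions.
4. **Optionally "boost".** `boosted(x, y) = ρ + sign(ρ)·eNMI`: the
   familiar signed linear correlation, with its magnitude augmented by
   the residual nonlinear dependence.

Around the metric sit a per-subject `C×C` matrix builder (a
scikit-learn–style transformer), a synthetic cohort generator with
controllable linear/quadratic couplings and group effects, matrix-wise
two-sample comparison with Benjamini–Hochberg FDR control, a min-cell
variation test, a permutation block-modularity test, joint-distribution
difference maps, and a CLI.

## Worked example

The three canonical bivariate cases (with `x ~ U[0,1]`,
`ε ~ N(0, 0.1²)`): a linear pair `y1 = 2x + ε`, a purely quadratic pair
`y2 = 5(x−½)² + ε`, and a mixed pair `y3 = 5(x−½)² + 2x + ε`:

```bash
nlfnc simulate-cases --n 1000 --seed 7 --out demo
cat demo/table.csv
```

```
case,corr_before,corr_after,nmi_before,nmi_after
I,0.9846405230434571,-9.68226699909286e-18,0.37704477329566133,0.03682893666681033
II,-0.018362604687708412,-1.6143944679137206e-17,0.255887747640835,0.25598125118359444
III,0.8258921548044835,2.2833054443893215e-16,0.34236956655969925,0.25494667723243436
```

Reading the table: removing the linear fit annihilates the correlation
in every case (`corr_after ≈ 0`). For the purely linear pair the NMI
collapses too (0.377 → 0.037), but for the quadratic pair it is
untouched (0.2559 → 0.2560): the dependence was never linear to begin
with, and correlation at `−0.018` missed nearly all of it. The mixed
case lands in between — its NMI drops only by the linear share.

The same pair through the library API:

```python
>>> from nlfnc import dependence, simulate_three_cases
>>> c = simulate_three_cases(n=1000, noise_sd=0.1, seed=7)
>>> r = dependence(c.x, c.y2)
>>> print(f"rho={r.rho:.4f} enmi={r.enmi:.4f} boosted={r.boosted:.4f}")
rho=-0.0184 enmi=0.2560 boosted=-0.2743
```

Cohort-level use mirrors nilearn's connectivity API:

```python
from nlfnc import ConnectivityMeasure, default_cohort_spec, simulate_cohort
records = simulate_cohort(default_cohort_spec(n_subjects_per_group=50, seed=0))
mats = ConnectivityMeasure(metric="enmi").fit_transform(records)  # (100, 10, 10)
```

and end-to-end from a shell, via a manifest of per-subject time-course
files:

```bash
nlfnc simulate-cohort --out cohort
nlfnc fnc     --manifest cohort/manifest.csv --metric all --out fnc
nlfnc compare --manifest cohort/manifest.csv --metric enmi \
              --domains cohort/domains.csv --out cmp
nlfnc modularity --matrix fnc/mean_enmi.csv \
                 --domains cohort/domains.csv --nperm 5000 --seed 1 --out mod
```

`compare` writes t/p/q/signed-log-p matrices and a significant-edge
list; every command writes a `summary.json` recording the estimator
configuration (including the resolved bin count), so any number in the
outputs is reproducible from the log alone.

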