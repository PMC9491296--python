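"""Group-level statistics on connectivity matrices.

Covers the matrix-wise comparisons used downstream of the dependence
metrics: the min-cell variation test, two-sample group comparison with
Benjamini-Hochberg FDR control, signed -log10(p) maps, a permutation
block-modularity test, joint-distribution difference grids for selected
pairs, and amplitude spectra of single time courses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .connectivity import FncMatrix
from .simulate import SubjectRecord

__all__ = [
    "GroupComparison",
    "ModularityResult",
    "JointDistDifference",
    "bh_fdr",
    "two_sample_compare",
    "min_cell_test",
    "block_modularity_test",
    "select_top_pairs",
    "joint_distribution_difference",
    "spectrum",
]

_TINY_P = 1e-300  # guard for log10 of underflowed p-values


@dataclass(frozen=True)
class GroupComparison:
    """Cell-wise test results over a C x C connectivity matrix.

    All maps are symmetric; the diagonal (and any untested cell) holds
    NaN in ``t_map``/``p_map``/``q_map``, 0 in ``signed_logp``, and
    False in ``mask``.
    """

    t_map: np.ndarray
    p_map: np.ndarray
    q_map: np.ndarray
    signed_logp: np.ndarray
    mask: np.ndarray
    alpha: float
    labels: tuple[str, ...] = ()


@dataclass(frozen=True)
class ModularityResult:
    """Permutation block-modularity test outcome."""

    observed_statistic: float
    null_distribution: np.ndarray
    p_value: float


@dataclass(frozen=True)
class JointDistDifference:
    """Difference of mean group joint densities for one component pair."""

    pair: tuple[int, int]
    grid: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, rejection mask at ``alpha``).  The
    adjusted value of the i-th test is min over j >= rank(i) of
    m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted, reject


def _upper_pairs(c: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(c, k=1)


def _stack(matrices: list[FncMatrix]) -> np.ndarray:
    if not matrices:
        raise ValueError("no matrices")
    metric, c = matrices[0].metric, matrices[0].n_components
    if any(m.metric != metric or m.n_components != c for m in matrices):
        raise ValueError("matrices must share metric and size")
    return np.stack([m.values for m in matrices])


def _assemble(c, iu, ju, t, p, q, mask, alpha, labels) -> GroupComparison:
    t_map = np.full((c, c), np.nan)
    p_map = np.full((c, c), np.nan)
    q_map = np.full((c, c), np.nan)
    s_map = np.zeros((c, c))
    m_map = np.zeros((c, c), dtype=bool)
    signed = -np.log10(np.maximum(p, _TINY_P)) * np.sign(t)
    signed = np.where(np.isfinite(signed), signed, 0.0)
    for arr, vals in ((t_map, t), (p_map, p), (q_map, q), (s_map, signed), (m_map, mask)):
        arr[iu, ju] = vals
        arr[ju, iu] = vals
    return GroupComparison(t_map=t_map, p_map=p_map, q_map=q_map,
                           signed_logp=s_map, mask=m_map, alpha=alpha,
                           labels=tuple(labels))


def two_sample_compare(
    group_a: list[FncMatrix],
    group_b: list[FncMatrix],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> GroupComparison:
    """Cell-wise two-sample t-test (A - B) with BH FDR over unique cells.

    Student's pooled-variance t-test by default (``equal_var=False``
    switches to Welch).  The BH correction runs across the C(C-1)/2
    unique off-diagonal cells.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    a = _stack(group_a)
    b = _stack(group_b)
    if a.shape[1:] != b.shape[1:] or group_a[0].metric != group_b[0].metric:
        raise ValueError("group matrices must share metric and size")
    c = a.shape[1]
    iu, ju = _upper_pairs(c)
    t, p = sps.ttest_ind(a[:, iu, ju], b[:, iu, ju], axis=0, equal_var=equal_var)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    q, mask = bh_fdr(p, alpha)
    return _assemble(c, iu, ju, t, p, q, mask, alpha, group_a[0].labels)


def min_cell_test(
    matrices: list[FncMatrix],
    alpha: float = 0.05,
    reference: str = "paired",
) -> GroupComparison:
    """Test every cell against the cell with the minimum group mean.

    Identifies the off-diagonal cell whose mean over subjects is
    smallest, then tests each other cell's subject-wise values against
    it with a one-sided alternative ("greater").  ``reference="paired"``
    runs a paired t-test against the minimum cell's subject values;
    ``reference="constant"`` a one-sample t-test against its scalar
    mean.  BH adjustment runs over the tested cells; the minimum cell
    itself is excluded (NaN/unmasked), as are zero-variance cells.
    """
    if len(matrices) < 3:
        raise ValueError("need at least 3 subjects")
    if reference not in ("paired", "constant"):
        raise ValueError("reference must be 'paired' or 'constant'")
    stackv = _stack(matrices)
    c = stackv.shape[1]
    iu, ju = _upper_pairs(c)
    cells = stackv[:, iu, ju]  # (n_subjects, n_cells)
    means = cells.mean(axis=0)
    k_min = int(np.argmin(means))

    n_cells = cells.shape[1]
    t = np.zeros(n_cells)
    p = np.ones(n_cells)
    testable = np.ones(n_cells, dtype=bool)
    testable[k_min] = False
    diffs = cells - (cells[:, [k_min]] if reference == "paired" else means[k_min])
    sd = diffs.std(axis=0, ddof=1)
    testable &= sd > 0
    if np.any(testable):
        res = sps.ttest_1samp(diffs[:, testable], 0.0, alternative="greater")
        t[testable] = res.statistic
        p[testable] = res.pvalue
    q = np.full(n_cells, np.nan)
    mask = np.zeros(n_cells, dtype=bool)
    if np.any(testable):
        q[testable], mask[testable] = bh_fdr(p[testable], alpha)
    t = np.where(testable, t, np.nan)
    p = np.where(testable, p, np.nan)
    return _assemble(c, iu, ju, t, p, q, mask, alpha, matrices[0].labels)


def block_modularity_test(
    mean_matrix: FncMatrix,
    domains,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> ModularityResult:
    """Permutation test of block (domain) modularity.

    Statistic: mean within-domain cell value minus mean between-domain
    cell value over off-diagonal cells.  The null permutes the
    component-to-domain labels; p = (1 + #{null >= observed}) /
    (1 + n_perm).
    """
    labels = np.asarray(list(domains))
    v = mean_matrix.values
    c = v.shape[0]
    if labels.size != c:
        raise ValueError("domain labels must match matrix size")
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 domains")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    iu, ju = _upper_pairs(c)
    cells = v[iu, ju]

    def stat(lab: np.ndarray) -> float:
        within = lab[iu] == lab[ju]
        if within.all() or not within.any():
            return 0.0
        return float(cells[within].mean() - cells[~within].mean())

    observed = stat(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = np.array([stat(rng.permutation(labels)) for _ in range(n_perm)])
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return ModularityResult(observed_statistic=observed, null_distribution=null, p_value=p)


def select_top_pairs(comparison: GroupComparison, k: int) -> list[tuple[int, int]]:
    """The k off-diagonal pairs with smallest raw p.

    Ties break by larger |t|, then by (i, j) lexicographic order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    c = comparison.p_map.shape[0]
    iu, ju = _upper_pairs(c)
    p = comparison.p_map[iu, ju]
    t = comparison.t_map[iu, ju]
    valid = np.isfinite(p)
    if k > int(valid.sum()):
        raise ValueError(f"k={k} exceeds the {int(valid.sum())} tested cells")
    order = sorted(
        (i for i in range(p.size) if valid[i]),
        key=lambda i: (p[i], -abs(t[i]), int(iu[i]), int(ju[i])),
    )
    return [(int(iu[i]), int(ju[i])) for i in order[:k]]


def joint_distribution_difference(
    pair: tuple[int, int],
    group_a: list[SubjectRecord],
    group_b: list[SubjectRecord],
    grid_size: int = 20,
) -> JointDistDifference:
    """Mean group-A joint density minus mean group-B density for a pair.

    Each subject's two time courses are histogrammed on shared edges
    (pooled min-max over all subjects in both groups) and normalized to
    a density summing to 1; group means are differenced, so the grid
    sums to ~0.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    i, j = pair
    all_records = list(group_a) + list(group_b)
    for r in all_records:
        if max(i, j) >= r.timecourses.shape[1]:
            raise ValueError(f"pair {pair} out of range for subject {r.subject_id}")
    xs = np.concatenate([r.timecourses[:, i] for r in all_records])
    ys = np.concatenate([r.timecourses[:, j] for r in all_records])
    x_edges = np.linspace(xs.min(), xs.max(), grid_size + 1)
    y_edges = np.linspace(ys.min(), ys.max(), grid_size + 1)

    def mean_density(records: list[SubjectRecord]) -> np.ndarray:
        acc = np.zeros((grid_size, grid_size))
        for r in records:
            h, _, _ = np.histogram2d(
                r.timecourses[:, i], r.timecourses[:, j], bins=[x_edges, y_edges]
            )
            acc += h / h.sum()
        return acc / len(records)

    grid = mean_density(list(group_a)) - mean_density(list(group_b))
    return JointDistDifference(pair=(i, j), grid=grid, x_edges=x_edges, y_edges=y_edges)


def spectrum(x, sampling_interval: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT amplitude spectrum of a time course.

    Returns (frequencies in Hz, amplitudes).  Amplitudes are scaled so
    that the sum of squared non-DC amplitudes equals the signal's
    (population) variance — Parseval's identity — with the DC term
    holding |mean|.  ``sampling_interval`` is the repetition time in
    seconds (2 s for typical resting-state acquisitions).
    """
    v = np.asarray(x, dtype=float).ravel()
    if v.size < 4:
        raise ValueError("need at least 4 samples")
    n = v.size
    amp = np.abs(np.fft.rfft(v)) / n
    amp[1:] *= np.sqrt(2.0)
    if n % 2 == 0:
        amp[-1] /= np.sqrt(2.0)  # Nyquist bin is not doubled
    freqs = np.fft.rfftfreq(n, d=sampling_interval)
    return freqs, amp
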