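"""Per-subject connectivity matrices and the scikit-learn estimator.

`ConnectivityMeasure` follows the transformer convention: ``transform``
maps a sequence of (T x C) subject time-course arrays to a stack of
(C x C) symmetric connectivity matrices for the configured metric.
The lower-level functional surface (`subject_fnc`, `group_mean_fnc`)
operates on `FncMatrix` objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .metrics import (
    HistogramConfig,
    explicit_nonlinear_nmi,
    normalized_mutual_information,
    pearson_correlation,
    remove_linear,
)
from .simulate import SubjectRecord

__all__ = ["FncMatrix", "ConnectivityMeasure", "subject_fnc", "group_mean_fnc", "METRICS"]

logger = logging.getLogger(__name__)

METRICS = ("pearson", "enmi", "boosted")

# value placed on the diagonal (self-connectivity) per metric
_DIAGONAL = {"pearson": 1.0, "enmi": 0.0, "boosted": 1.0}


@dataclass(frozen=True)
class FncMatrix:
    """A C x C symmetric connectivity matrix for one metric.

    The diagonal holds the metric's self-connectivity: 1 for pearson
    and boosted, 0 for enmi (the residual of a series on itself is the
    zero vector, which carries no dependence).
    """

    metric: str
    values: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("values must be symmetric")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        object.__setattr__(self, "values", v)
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"C{i + 1}" for i in range(v.shape[0]))
            )

    @property
    def n_components(self) -> int:
        return self.values.shape[0]


def _pairwise_matrix(tc: np.ndarray, metric: str, cfg: HistogramConfig) -> np.ndarray:
    t, c = tc.shape
    out = np.full((c, c), _DIAGONAL[metric])
    constant = np.ptp(tc, axis=0) == 0
    if np.any(constant):
        logger.warning(
            "constant component(s) %s: filling with degenerate value",
            np.flatnonzero(constant).tolist(),
        )

    if metric == "pearson" and not np.any(constant):
        r = np.corrcoef(tc, rowvar=False)
        np.fill_diagonal(r, 1.0)
        return np.clip(r, -1.0, 1.0)

    b = cfg.n_bins(t)
    pair_cfg = HistogramConfig(bins=b, bin_rule="fixed", normalization=cfg.normalization)
    for i in range(c):
        if constant[i]:
            out[i, :] = out[:, i] = 0.0 if metric == "enmi" else np.nan
            out[i, i] = _DIAGONAL[metric]
            continue
        x = tc[:, i]
        for j in range(i + 1, c):
            if constant[j]:
                continue
            y = tc[:, j]
            if metric == "pearson":
                val = pearson_correlation(x, y)
            else:
                zyx = remove_linear(x, y).residual
                zxy = remove_linear(y, x).residual
                enmi = 0.5 * (
                    normalized_mutual_information(x, zyx, pair_cfg).nmi
                    + normalized_mutual_information(y, zxy, pair_cfg).nmi
                )
                if metric == "enmi":
                    val = enmi
                else:  # boosted
                    rho = pearson_correlation(x, y)
                    val = rho + np.copysign(enmi, rho) if rho != 0.0 else rho
            out[i, j] = out[j, i] = val
    return out


def subject_fnc(
    record: SubjectRecord | np.ndarray,
    metric: str = "enmi",
    cfg: HistogramConfig | None = None,
) -> FncMatrix:
    """Connectivity matrix of one subject for one metric.

    Accepts a `SubjectRecord` or a bare (T x C) array.  A constant
    component gets the metric's degenerate value in its row/column
    (0 for enmi, NaN for correlation-based metrics) with a logged
    warning.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    cfg = cfg or HistogramConfig()
    if isinstance(record, SubjectRecord):
        tc, labels = record.timecourses, record.component_labels
    else:
        tc = np.asarray(record, dtype=float)
        labels = ()
    if tc.ndim != 2:
        raise ValueError("timecourses must be 2-D (T x C)")
    if tc.shape[0] < 10:
        raise ValueError("need at least 10 timepoints")
    return FncMatrix(metric=metric, values=_pairwise_matrix(tc, metric, cfg), labels=tuple(labels))


def group_mean_fnc(matrices: list[FncMatrix]) -> FncMatrix:
    """Element-wise mean of same-metric, same-size connectivity matrices."""
    if not matrices:
        raise ValueError("no matrices")
    metric = matrices[0].metric
    c = matrices[0].n_components
    if any(m.metric != metric for m in matrices):
        raise ValueError("mixed metrics")
    if any(m.n_components != c for m in matrices):
        raise ValueError("mixed matrix sizes")
    mean = np.mean([m.values for m in matrices], axis=0)
    return FncMatrix(metric=metric, values=mean, labels=matrices[0].labels)


class ConnectivityMeasure(TransformerMixin, BaseEstimator):
    """Transform subject time courses into connectivity matrices.

    Parameters
    ----------
    metric : {"pearson", "enmi", "boosted"}
        ``"pearson"`` is the conventional linear FNC; ``"enmi"`` is the
        explicitly nonlinear NMI (linear dependence regressed out,
        symmetrized); ``"boosted"`` is rho + sign(rho) * eNMI.
    bins : int or None
        Histogram bins per axis; ``None`` selects the Rice rule
        ceil(2 T^(1/3)) from the series length.
    normalization : {"joint", "max"}
        NMI denominator (joint entropy or max marginal entropy).

    Examples
    --------
    >>> cm = ConnectivityMeasure(metric="enmi")
    >>> mats = cm.fit_transform([tc1, tc2])   # each tc: (T, C) array
    >>> mats.shape
    (2, C, C)
    """

    def __init__(self, metric: str = "enmi", bins: int | None = None,
                 normalization: str = "joint"):
        self.metric = metric
        self.bins = bins
        self.normalization = normalization

    def _config(self) -> HistogramConfig:
        if self.bins is None:
            return HistogramConfig(bin_rule="rice", normalization=self.normalization)
        return HistogramConfig(bins=self.bins, bin_rule="fixed",
                               normalization=self.normalization)

    def fit(self, X, y=None):
        """Validate inputs and record dimensions; stateless otherwise."""
        tcs = self._coerce(X)
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        self._config()  # validates bins/normalization
        self.n_components_ = tcs[0].shape[1]
        self.n_timepoints_ = tcs[0].shape[0]
        return self

    def transform(self, X) -> np.ndarray:
        """Return a (n_subjects, C, C) stack of connectivity matrices."""
        if not hasattr(self, "n_components_"):
            self.fit(X)
        tcs = self._coerce(X)
        cfg = self._config()
        return np.stack([subject_fnc(tc, self.metric, cfg).values for tc in tcs])

    @staticmethod
    def _coerce(X) -> list[np.ndarray]:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            tcs = [X[i] for i in range(X.shape[0])]
        else:
            tcs = [
                r.timecourses if isinstance(r, SubjectRecord) else np.asarray(r, dtype=float)
                for r in X
            ]
        if not tcs:
            raise ValueError("empty input")
        shape = tcs[0].shape
        for tc in tcs:
            if tc.ndim != 2 or tc.shape != shape:
                raise ValueError("all subjects must share the same (T, C) shape")
        return tcs
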