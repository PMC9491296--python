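"""Synthetic data generators.

Two generators:

* :func:`simulate_three_cases` - the three bivariate validation cases
  (purely linear, purely quadratic with zero linear correlation, and
  mixed), used to demonstrate that residualized NMI isolates nonlinear
  dependence.
* :func:`simulate_cohort` - multi-subject cohorts of ICA-like component
  time courses with modular linear couplings, quadratic (explicitly
  nonlinear) couplings, and optional group differences in the nonlinear
  coupling strength.  This emulates the structure of resting-state fMRI
  component time courses at study scale (default T=159 timepoints).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "ThreeCases",
    "CohortSpec",
    "SubjectRecord",
    "simulate_three_cases",
    "simulate_cohort",
    "default_cohort_spec",
]


@dataclass(frozen=True)
class ThreeCases:
    """The shared driver x and the three response vectors.

    y1 = 2x + eps          (purely linear)
    y2 = 5(x-1/2)^2 + eps  (purely quadratic; zero linear correlation)
    y3 = 5(x-1/2)^2 + 2x + eps  (linear + quadratic)

    with x ~ Uniform[0, 1] and eps ~ N(0, noise_sd^2), drawn
    independently per case.
    """

    x: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    y3: np.ndarray


def simulate_three_cases(
    n: int = 1000,
    noise_sd: float = 0.1,
    seed: int | np.random.Generator | None = None,
) -> ThreeCases:
    """Draw the three bivariate validation cases.

    The default noise level sigma = 0.1 makes the population
    correlation of the linear case sqrt((1/3)/(1/3 + sigma^2)) ~ 0.985.
    Deterministic given ``seed``; the noise is drawn independently per
    case.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = rng.uniform(0.0, 1.0, n)
    q = 5.0 * (x - 0.5) ** 2
    y1 = 2.0 * x + rng.normal(0.0, noise_sd, n)
    y2 = q + rng.normal(0.0, noise_sd, n)
    y3 = q + 2.0 * x + rng.normal(0.0, noise_sd, n)
    return ThreeCases(x=x, y1=y1, y2=y2, y3=y3)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: id, group label, and a T x C time-course matrix."""

    subject_id: str
    group: str
    timecourses: np.ndarray
    component_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        tc = np.asarray(self.timecourses, dtype=float)
        if tc.ndim != 2:
            raise ValueError("timecourses must be a 2-D (T x C) array")
        if not np.all(np.isfinite(tc)):
            raise ValueError("timecourses contain non-finite values")
        object.__setattr__(self, "timecourses", tc)
        if not self.component_labels:
            object.__setattr__(
                self,
                "component_labels",
                tuple(f"C{i + 1}" for i in range(tc.shape[1])),
            )


Pair = tuple[int, int]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a two-group synthetic cohort.

    Each component is a variance-normalized mixture of its own white
    noise and shared latent factors:

    * a *linear* coupling of weight ``lam`` on pair (i, j) adds the same
      smoothed standard-normal factor f to both components, so their
      population correlation is lam^2;
    * a *nonlinear* coupling of weight ``gamma`` on pair (i, j) adds the
      factor u to component i and the standardized centered square of u
      to component j.  Since Cov(u, u^2) = 0 for symmetric u the pair is
      (population-)uncorrelated but strongly dependent - the cohort
      analogue of the quadratic validation case.

    Latent factors are AR(1)-smoothed *before* the quadratic transform
    (autocorrelation is a property of the underlying network signals),
    and every component is z-scored at the end.  Group "B" uses
    gamma + group_delta on the designated pairs.
    """

    n_subjects_per_group: int = 50
    n_components: int = 10
    n_timepoints: int = 159
    domain_assignment: tuple[str, ...] | None = None
    linear_coupling: dict[Pair, float] = field(default_factory=dict)
    nonlinear_coupling: dict[Pair, float] = field(default_factory=dict)
    group_delta: dict[Pair, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    ar_coefficient: float = 0.3
    seed: int | None = None
    group_labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if not 0 <= abs(self.ar_coefficient) < 1:
            raise ValueError("|ar_coefficient| must be < 1")
        c = self.n_components
        for name in ("linear_coupling", "nonlinear_coupling", "group_delta"):
            for (i, j) in getattr(self, name):
                if not (0 <= i < c and 0 <= j < c) or i == j:
                    raise ValueError(f"{name} pair ({i}, {j}) out of range for C={c}")
        if self.domain_assignment is not None and len(self.domain_assignment) != c:
            raise ValueError("domain_assignment length must equal n_components")
        for group_b in (False, True):
            load = self._variance_load(group_b)
            if np.any(load > 1.0 + 1e-9):
                k = int(np.argmax(load))
                raise ValueError(
                    f"coupling weights overload component {k}: "
                    f"sum of squared weights {load[k]:.3f} > 1"
                )

    def _variance_load(self, group_b: bool) -> np.ndarray:
        load = np.zeros(self.n_components)
        for (i, j), lam in self.linear_coupling.items():
            load[i] += lam * lam
            load[j] += lam * lam
        deltas = self.group_delta if group_b else {}
        for pair in set(self.nonlinear_coupling) | set(deltas):
            g = self.nonlinear_coupling.get(pair, 0.0) + deltas.get(pair, 0.0)
            i, j = pair
            load[i] += g * g
            load[j] += g * g
        return load


def _smooth_factor(rng: np.random.Generator, t: int, ar: float) -> np.ndarray:
    v = rng.standard_normal(t)
    if ar:
        v = lfilter([1.0], [1.0, -ar], v)
    v -= v.mean()
    sd = v.std()
    return v / sd if sd > 0 else v


def _simulate_subject(rng: np.random.Generator, spec: CohortSpec, group_b: bool) -> np.ndarray:
    t, c = spec.n_timepoints, spec.n_components
    noise = spec.noise_sd * rng.standard_normal((t, c))
    signal = np.zeros((t, c))
    weight2 = np.zeros(c)  # accumulated squared mixing weight per component

    for (i, j), lam in sorted(spec.linear_coupling.items()):
        f = _smooth_factor(rng, t, spec.ar_coefficient)
        signal[:, i] += lam * f
        signal[:, j] += lam * f
        weight2[i] += lam * lam
        weight2[j] += lam * lam

    deltas = spec.group_delta if group_b else {}
    nl_pairs = sorted(set(spec.nonlinear_coupling) | set(deltas))
    for pair in nl_pairs:
        gamma = spec.nonlinear_coupling.get(pair, 0.0) + deltas.get(pair, 0.0)
        u = _smooth_factor(rng, t, spec.ar_coefficient)  # drawn even if gamma=0: keeps
        if gamma == 0.0:                                 # the RNG stream group-invariant
            continue
        q = u * u
        q = (q - q.mean()) / q.std()
        i, j = pair
        signal[:, i] += gamma * u
        signal[:, j] += gamma * q
        weight2[i] += gamma * gamma
        weight2[j] += gamma * gamma

    own = np.sqrt(np.clip(1.0 - weight2, 0.0, 1.0))
    x = own * noise + signal
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate the full two-group cohort, deterministically per seed.

    Subjects are generated from per-subject substreams spawned from the
    top-level seed, so the cohort is reproducible bit-for-bit and
    subjects are mutually independent.
    """
    root = np.random.SeedSequence(spec.seed)
    n = spec.n_subjects_per_group
    children = root.spawn(2 * n)
    records: list[SubjectRecord] = []
    for g, label in enumerate(spec.group_labels):
        for s in range(n):
            rng = np.random.default_rng(children[g * n + s])
            tc = _simulate_subject(rng, spec, group_b=(g == 1))
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{label}{s + 1:03d}",
                    group=label,
                    timecourses=tc,
                )
            )
    return records


def default_cohort_spec(
    n_subjects_per_group: int = 50,
    seed: int | None = None,
    group_delta: float = 0.8,
    n_nonlinear_pairs: int = 3,
) -> CohortSpec:
    """A 10-component, two-domain cohort with modular linear structure.

    Components 0-4 form one domain and 5-9 the other; within-domain
    pairs carry moderate linear couplings (lambda = 0.4, population
    correlation lambda^2 = 0.16, the scale seen in mean FNC matrices).
    ``n_nonlinear_pairs`` cross-domain pairs carry a purely nonlinear
    group difference of weight ``group_delta`` in group B only; the
    default pairs keep every component's total squared coupling weight
    at or below 1, so the variance normalization leaves the linear
    correlations identical across groups.
    """
    domains = tuple(["D1"] * 5 + ["D2"] * 5)
    linear = {
        (0, 1): 0.4, (1, 2): 0.4, (2, 3): 0.4, (0, 4): 0.4,
        (5, 6): 0.4, (6, 7): 0.4, (7, 8): 0.4, (5, 9): 0.4,
    }
    nl_pairs = [(3, 8), (4, 9), (2, 7), (1, 6), (0, 5)][:n_nonlinear_pairs]
    return CohortSpec(
        n_subjects_per_group=n_subjects_per_group,
        domain_assignment=domains,
        linear_coupling=linear,
        nonlinear_coupling={},
        group_delta={p: group_delta for p in nl_pairs},
        seed=seed,
    )
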