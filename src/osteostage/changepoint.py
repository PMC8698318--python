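"""Multivariate change-point detection by divisive energy statistics.

Metabolic phases of a differentiation time course are defined by change
points in the multivariate series of daily metabolite uptake/secretion
rates. Change points are estimated hierarchically: within each current
segment the split maximizing the scaled energy divergence between the two
halves is located, its significance is assessed by a within-segment
permutation test, and accepted splits are recursed into. This is the
E-Divisive strategy of Matteson & James applied to daily rate vectors.

The divergence between samples ``A = {x_1..x_m}`` and ``B = {y_1..y_n}``
for a moment index ``alpha`` in (0, 2) is::

    E(A, B) = 2/(mn) * sum_ij |x_i - y_j|^alpha
              - C(m,2)^-1 * sum_{i<j} |x_i - x_j|^alpha
              - C(n,2)^-1 * sum_{i<j} |y_i - y_j|^alpha

with within-segment terms taken as 0 for singleton segments, and the
scaled test statistic ``Q = mn/(m+n) * E``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted


@dataclass
class ChangePointConfig:
    """Parameters of the divisive energy-statistic search.

    alpha_moment : moment index of the energy distance, in (0, 2).
    sig_level    : permutation significance threshold for accepting a split.
    n_permutations : permutations per significance test.
    min_segment  : minimum observations per segment on either side of a split.
    seed         : seed for the permutation RNG.
    """

    alpha_moment: float = 1.0
    sig_level: float = 0.05
    n_permutations: int = 199
    min_segment: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_moment < 2.0:
            raise ValueError("alpha_moment must lie in (0, 2)")
        if self.min_segment < 2:
            raise ValueError("min_segment must be >= 2")


@dataclass
class ChangePointResult:
    """Accepted change points and the metabolic phases they delimit.

    ``change_days`` holds the first day of each new phase; ``phases`` is a
    list of ``(phase_index, start_day, end_day)`` with inclusive bounds that
    partition the analyzed day range.
    """

    change_days: list = field(default_factory=list)
    p_values: list = field(default_factory=list)
    phases: list = field(default_factory=list)


def _alpha_distance_matrix(X: np.ndarray, alpha: float) -> np.ndarray:
    if X.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(X, metric="euclidean") ** alpha)


def energy_divergence(segment_a, segment_b, alpha_moment: float = 1.0):
    """Energy divergence between two multivariate samples.

    Returns ``(e_hat, q)``: the divergence estimate and the scaled
    statistic ``Q = mn/(m+n) * e_hat`` used in the split search.
    """
    a = np.atleast_2d(np.asarray(segment_a, dtype=float))
    b = np.atleast_2d(np.asarray(segment_b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("segments must be non-empty")
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"dimension mismatch: {a.shape[1]} vs {b.shape[1]}"
        )
    m, n = a.shape[0], b.shape[0]
    cross = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1) ** alpha_moment
    e_hat = 2.0 * cross.sum() / (m * n)
    for seg, size in ((a, m), (b, n)):
        if size > 1:
            within = pdist(seg, metric="euclidean") ** alpha_moment
            e_hat -= within.sum() / (size * (size - 1) / 2.0)
    q = m * n / (m + n) * e_hat
    return e_hat, q


def _best_split(D: np.ndarray, min_segment: int):
    """Best within-segment split of a distance-power matrix.

    Returns ``(tau, q)`` where ``tau`` is the size of the left part.  Ties
    break toward the earliest split.  Requires ``len(D) >= 2 * min_segment``.
    """
    T = D.shape[0]
    # prefix-sum trick: sum of D[:a, :b] = C[a-1, b-1]
    C = D.cumsum(axis=0).cumsum(axis=1)
    total = C[-1, -1]
    taus = np.arange(min_segment, T - min_segment + 1)
    within_a = C[taus - 1, taus - 1]
    between = C[taus - 1, T - 1] - within_a
    within_b = total - within_a - 2.0 * between
    m = taus.astype(float)
    n = T - m
    e_hat = (
        2.0 * between / (m * n)
        - within_a / (m * (m - 1))
        - within_b / (n * (n - 1))
    )
    q = m * n / (m + n) * e_hat
    best = int(np.argmax(q))  # argmax returns the first maximum: earliest tie
    return int(taus[best]), float(q[best])


class EnergyDivisive(BaseEstimator):
    """Divisive hierarchical change-point estimator for multivariate series.

    Parameters follow :class:`ChangePointConfig`. ``fit`` expects an
    ``(n_observations, n_features)`` array ordered in time; estimated
    breakpoints are stored as row indices marking the first row of each new
    segment.

    Attributes
    ----------
    breakpoints_ : list of int
        Sorted indices ``b`` such that rows ``[.., b-1]`` and ``[b, ..]``
        fall in different segments.
    p_values_ : list of float
        Permutation p-value of each accepted breakpoint, aligned with
        ``breakpoints_``.
    labels_ : ndarray of int
        Segment label per row, 0-based and increasing in time.
    """

    def __init__(
        self,
        alpha_moment: float = 1.0,
        sig_level: float = 0.05,
        n_permutations: int = 199,
        min_segment: int = 3,
        random_state: int = 0,
    ):
        self.alpha_moment = alpha_moment
        self.sig_level = sig_level
        self.n_permutations = n_permutations
        self.min_segment = min_segment
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        if not 0.0 < self.alpha_moment < 2.0:
            raise ValueError("alpha_moment must lie in (0, 2)")
        if self.min_segment < 2:
            raise ValueError("min_segment must be >= 2")
        T = X.shape[0]
        if T < 2 * self.min_segment:
            raise ValueError(
                f"need at least {2 * self.min_segment} observations, got {T}"
            )
        D = _alpha_distance_matrix(X, self.alpha_moment)
        rng = np.random.default_rng(self.random_state)
        accepted: list[tuple[int, float]] = []
        # depth-first divisive search; each segment is tested independently
        stack = [(0, T)]
        while stack:
            start, end = stack.pop()
            length = end - start
            if length < 2 * self.min_segment:
                continue
            sub = D[start:end, start:end]
            tau, q_obs = _best_split(sub, self.min_segment)
            if q_obs <= 0:
                # identical rows: no divergence anywhere in this segment
                continue
            exceed = 0
            for _ in range(self.n_permutations):
                idx = rng.permutation(length)
                q_perm = _best_split(sub[np.ix_(idx, idx)], self.min_segment)[1]
                if q_perm >= q_obs:
                    exceed += 1
            p = (1.0 + exceed) / (self.n_permutations + 1.0)
            if p <= self.sig_level:
                accepted.append((start + tau, p))
                stack.append((start, start + tau))
                stack.append((start + tau, end))
        accepted.sort()
        self.breakpoints_ = [b for b, _ in accepted]
        self.p_values_ = [p for _, p in accepted]
        bounds = [0] + self.breakpoints_ + [T]
        labels = np.empty(T, dtype=int)
        for i, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
            labels[lo:hi] = i
        self.labels_ = labels
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def predict(self, X=None):
        check_is_fitted(self, "labels_")
        return self.labels_


def edivisive(panel, config: ChangePointConfig | None = None) -> ChangePointResult:
    """Detect metabolic phases in a :class:`~osteostage.phases.RatePanel`.

    Metabolite rate series are standardized to unit variance before the
    energy-distance computation (unless the panel is already standardized)
    so that high-concentration metabolites do not dominate the Euclidean
    geometry.
    """
    config = config or ChangePointConfig()
    X = np.asarray(panel.rates, dtype=float)
    if not panel.standardized:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    est = EnergyDivisive(
        alpha_moment=config.alpha_moment,
        sig_level=config.sig_level,
        n_permutations=config.n_permutations,
        min_segment=config.min_segment,
        random_state=config.seed,
    ).fit(X)
    days = np.asarray(panel.days)
    change_days = [int(days[b]) for b in est.breakpoints_]
    bounds = [0] + est.breakpoints_ + [len(days)]
    phases = [
        (i, int(days[lo]), int(days[hi - 1]))
        for i, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:]))
    ]
    return ChangePointResult(
        change_days=change_days, p_values=est.p_values_, phases=phases
    )
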