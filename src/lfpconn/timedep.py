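"""Time-domain dependence measures and the trial-label permutation test.

Cross-covariance uses the biased 1/T normalization, which keeps the lag-0
estimate positive semidefinite.  Partial correlation is read off the
precision matrix (the inverse of the lag-0 covariance):
``rho_pq|v = -Theta_pq / sqrt(Theta_pp Theta_qq)``.

The two-sample permutation test compares per-trial statistics (typically
lag-0 correlations of one channel pair) between two trial groups with the
Welch-type statistic ``(mean1 - mean2) / sqrt(v1/n1 + v2/n2)``.  When the
number of distinct relabelings is small the null is enumerated exhaustively;
otherwise random relabelings are drawn and the add-one convention
``p = (1 + #{|t*| >= |t_obs|}) / (1 + n_perm)`` is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .exceptions import DegenerateInputError, SingularityError

__all__ = [
    "LagCovariance",
    "CorrelationMatrix",
    "PartialCorrelationMatrix",
    "PermTestResult",
    "cross_covariance",
    "correlation_matrix",
    "partial_correlation_matrix",
    "trialwise_corr_test",
    "benjamini_hochberg",
]

_COND_LIMIT = 1e10  # near-singularity cutoff for the precision matrix


@dataclass
class LagCovariance:
    lags: list[int]
    matrices: list[np.ndarray]
    normalization: str = "biased_1_over_T"

    def at(self, lag: int) -> np.ndarray:
        return self.matrices[self.lags.index(lag)]


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    lag: int = 0


@dataclass
class PartialCorrelationMatrix:
    values: np.ndarray


def cross_covariance(trial: np.ndarray, lags: list[int] | np.ndarray) -> LagCovariance:
    """Lag-k cross-covariance matrices of a demeaned (P, T) trial.

    ``sigma_pq(k) = (1/T) sum_t x_{p,t} x_{q,t+k}`` over valid t; the
    identity ``Sigma(-k) = Sigma(k)^T`` holds exactly.
    """
    x = np.atleast_2d(np.asarray(trial, dtype=np.float64))
    _, t = x.shape
    lags = [int(k) for k in lags]
    if any(abs(k) >= t for k in lags):
        raise ValueError(f"all |lags| must be < T={t}")
    x = x - x.mean(axis=1, keepdims=True)
    cache: dict[int, np.ndarray] = {}

    def pos(k: int) -> np.ndarray:
        if k not in cache:
            cache[k] = x[:, : t - k] @ x[:, k:].T / t
        return cache[k]

    mats = [pos(k) if k >= 0 else pos(-k).T for k in lags]
    return LagCovariance(lags=lags, matrices=mats)


def correlation_matrix(trial: np.ndarray, lag: int = 0) -> CorrelationMatrix:
    """Lag-k correlation rho_pq(k) = sigma_pq(k) / sqrt(sigma_pp(0) sigma_qq(0))."""
    x = np.atleast_2d(np.asarray(trial, dtype=np.float64))
    cov = cross_covariance(x, [0, lag] if lag != 0 else [0])
    var = np.diag(cov.at(0)).copy()
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        raise DegenerateInputError(f"zero-variance channel at index {bad[0]}")
    rho = cov.at(lag) / np.sqrt(np.outer(var, var))
    rho = np.clip(rho, -1.0, 1.0)
    if lag == 0:
        np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(values=rho, lag=lag)


def partial_correlation_matrix(trial: np.ndarray) -> PartialCorrelationMatrix:
    """Partial correlations from the precision matrix of the lag-0 covariance."""
    x = np.atleast_2d(np.asarray(trial, dtype=np.float64))
    sigma = cross_covariance(x, [0]).at(0)
    cond = np.linalg.cond(sigma)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise SingularityError(
            f"lag-0 covariance is singular or near-singular (condition number {cond:.3g}); "
            "perfectly collinear channels cannot be de-confounded"
        )
    theta = np.linalg.inv(sigma)
    d = np.sqrt(np.diag(theta))
    rho = -theta / np.outer(d, d)
    rho = np.clip(0.5 * (rho + rho.T), -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return PartialCorrelationMatrix(values=rho)


@dataclass
class PermTestResult:
    t_obs: float
    p_value: float
    n_perm: int
    exact: bool
    group_means: tuple[float, float]
    group_vars: tuple[float, float]


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    n1, n2 = len(a), len(b)
    d = a.mean() - b.mean()
    se2 = a.var(ddof=1) / n1 + b.var(ddof=1) / n2
    if se2 <= 0:
        return 0.0 if d == 0 else np.sign(d) * np.inf
    return float(d / np.sqrt(se2))


def trialwise_corr_test(
    values_group1,
    values_group2,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermTestResult:
    """Two-sample permutation test on per-trial statistics.

    Relabels the pooled values between the two groups.  All ``C(n1+n2, n1)``
    relabelings are enumerated when their count does not exceed ``n_perm``
    (exact test, p = count / total); otherwise ``n_perm`` random relabelings
    with the add-one convention.
    """
    a = np.asarray(values_group1, dtype=np.float64)
    b = np.asarray(values_group2, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    t_obs = _welch_t(a, b)
    pooled = np.concatenate([a, b])
    n1, n = len(a), len(pooled)
    total = comb(n, n1)
    tol = 1e-12 * max(1.0, abs(t_obs))

    if total <= n_perm:
        count = 0
        for idx in combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            t_star = _welch_t(pooled[mask], pooled[~mask])
            if abs(t_star) >= abs(t_obs) - tol:
                count += 1
        p = count / total
        return PermTestResult(
            t_obs, p, total, True,
            (a.mean(), b.mean()), (a.var(ddof=1), b.var(ddof=1)),
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        t_star = _welch_t(pooled[perm[:n1]], pooled[perm[n1:]])
        if abs(t_star) >= abs(t_obs) - tol:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermTestResult(
        t_obs, p, n_perm, False,
        (a.mean(), b.mean()), (a.var(ddof=1), b.var(ddof=1)),
    )


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    p = np.asarray(pvals, dtype=np.float64)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out
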