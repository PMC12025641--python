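"""Robust canonical band coherence (KenCoh) and the direction-difference test.

Canonical band coherence (CBC) is the maximal squared correlation between
lagged linear combinations ``u' X_{t-h}`` and ``v' Y_t`` of two channel
groups' band-filtered signals:

    phi(Omega) = max_{u,v,h} |u' Sigma_XY(h) v|^2
                 s.t. u' Sigma_XX(0) u = v' Sigma_YY(0) v = 1.

The maximizer is obtained from the eigendecomposition of

    Theta1 = A^{-1/2} B C^{-1} B' A^{-1/2},   A = Sigma_XX(0),
    Theta2 = C^{-1/2} B' A^{-1} B C^{-1/2},   C = Sigma_YY(0), B = Sigma_XY(h):

phi is the leading eigenvalue of Theta1; the canonical directions are the
leading eigenvectors of Theta1 / Theta2 mapped back through A^{-1/2} /
C^{-1/2}.

KenCoh replaces the sample covariance by a Kendall-tau scale matrix: under
elliptical symmetry the population correlation satisfies
``lambda = sin(pi tau / 2)`` (the arcsine law), so the elementwise sine
transform of the lagged rank-correlation matrix is a consistent, outlier-
robust scale estimate.  Kendall's tau here is the signed-pair statistic
normalized by the number of pairs T(T-1)/2, which has range [-1, 1] and
makes the sine transform recover the Gaussian correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import TrialSet
from .exceptions import DegenerateInputError, SingularityError
from .spectral import FilterSpec, FrequencyBand, SpectralMatrix, bandpass_filter
from .timedep import benjamini_hochberg

__all__ = [
    "ScaleMatrixEstimate",
    "CBCResult",
    "DirectionSummary",
    "DirectionTestResult",
    "kendall_lag_tau",
    "robust_scale_matrix",
    "cbc_solve",
    "canonical_coherence_at_frequency",
    "trial_directions_summary",
    "direction_difference_test",
    "KenCoh",
    "smote_augment",
]

_EIG_FLOOR = 1e-10  # relative eigenvalue floor for symmetric inverse square roots


# ---------------------------------------------------------------------------
# Kendall-tau scale matrices
# ---------------------------------------------------------------------------

def kendall_lag_tau(Z: np.ndarray, h: int = 0, method: str = "fast") -> np.ndarray:
    """Lagged Kendall-tau matrix tau_jk(h) between Z_{j,t-h} and Z_{k,t}.

    ``method='fast'`` uses an O(T log T) inversion-counting path;
    ``method='brute'`` enumerates all 1 <= t < s <= T signed pairs.  Both
    normalize by the pair count T(T-1)/2 and agree exactly on tie-free data
    (ties contribute sign 0 in the brute path).
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    d, t = Z.shape
    if h < 0 or h >= t:
        raise ValueError(f"lag h must satisfy 0 <= h < T, got {h}")
    if t - h < 4:
        raise ValueError("need at least 4 aligned samples")
    A = Z[:, : t - h]  # Z_{., t-h}
    B = Z[:, h:]       # Z_{., t}
    const = [j for j in range(d) if np.ptp(A[j]) == 0 or np.ptp(B[j]) == 0]
    if const:
        warnings.warn(
            f"constant channel(s) {const}: all signed pairs are 0, tau set to 0",
            RuntimeWarning,
        )
    tau = np.zeros((d, d))
    for j in range(d):
        for k in range(d):
            if j in const or k in const:
                continue
            tau[j, k] = _tau_pair(A[j], B[k], method)
    return tau


def _tau_pair(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "brute":
        n = len(x)
        sx = np.sign(x[:, None] - x[None, :])
        sy = np.sign(y[:, None] - y[None, :])
        iu = np.triu_indices(n, k=1)
        return float((sx[iu] * sy[iu]).sum() / (n * (n - 1) / 2))
    if method == "fast":
        # scipy's tau-b equals the signed-pair statistic / pair count when tie-free
        res = stats.kendalltau(x, y).statistic
        return float(0.0 if np.isnan(res) else res)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class ScaleMatrixEstimate:
    lag: int
    values: np.ndarray
    estimator: str


def robust_scale_matrix(Z: np.ndarray, h: int = 0, estimator: str = "kendall_sine") -> ScaleMatrixEstimate:
    """Lag-h scale matrix: sine-transformed Kendall tau, or sample correlation.

    ``kendall_sine`` applies ``lambda = sin(pi tau / 2)`` elementwise;
    ``sample_covariance`` returns the lag-h cross-covariance rescaled to
    correlation by the lag-0 standard deviations.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    if estimator == "kendall_sine":
        lam = np.sin(np.pi / 2.0 * kendall_lag_tau(Z, h))
        if h == 0:
            np.fill_diagonal(lam, 1.0)
    elif estimator == "sample_covariance":
        x = Z - Z.mean(axis=1, keepdims=True)
        t = x.shape[1]
        cov = x[:, : t - h] @ x[:, h:].T / t
        sd = np.sqrt(np.einsum("pt,pt->p", x, x) / t)
        if np.any(sd <= 0):
            raise DegenerateInputError("zero-variance channel")
        lam = cov / np.outer(sd, sd)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return ScaleMatrixEstimate(lag=h, values=lam, estimator=estimator)


# ---------------------------------------------------------------------------
# CBC eigenproblem
# ---------------------------------------------------------------------------

def _inv_sqrt(m: np.ndarray, what: str) -> np.ndarray:
    """Symmetric inverse square root with a relative eigenvalue floor."""
    w, v = np.linalg.eigh(0.5 * (m + m.T))
    floor = _EIG_FLOOR * np.trace(m)
    if w.min() <= floor:
        raise SingularityError(
            f"{what} block is not positive definite (min eigenvalue {w.min():.3g}); "
            "consider regularizing the scale matrix (off by default)"
        )
    return (v / np.sqrt(w)) @ v.T


def _fix_sign(vec: np.ndarray) -> np.ndarray:
    i = int(np.argmax(np.abs(vec)))
    return vec if vec[i] >= 0 else -vec


@dataclass
class CBCResult:
    """Canonical band coherence for one trial and band."""

    phi: float
    u: np.ndarray
    v: np.ndarray
    h: int
    band: FrequencyBand | None = None
    estimator: str = "kendall_sine"


def cbc_solve(
    scale_by_lag: dict[int, np.ndarray],
    P: int,
    Q: int,
    band: FrequencyBand | None = None,
    estimator: str = "kendall_sine",
) -> CBCResult:
    """Solve the CBC eigenproblem over candidate lags.

    ``scale_by_lag[h]`` is the d x d lag-h scale (or covariance) matrix of the
    stacked series Z = [X; Y] with d = P + Q; lag 0 must be present.  For each
    candidate lag the Theta1/Theta2 matrices are formed with symmetric inverse
    square roots; the lag with the largest leading eigenvalue wins.  Direction
    signs are fixed by making the largest-magnitude coordinate positive.
    """
    if 0 not in scale_by_lag:
        raise ValueError("scale_by_lag must include lag 0")
    S0 = scale_by_lag[0]
    if S0.shape != (P + Q, P + Q):
        raise ValueError(f"expected ({P + Q}, {P + Q}) matrices, got {S0.shape}")
    A = 0.5 * (S0[:P, :P] + S0[:P, :P].T)
    C = 0.5 * (S0[P:, P:] + S0[P:, P:].T)
    Ai = _inv_sqrt(A, "X (lag-0)")
    Ci = _inv_sqrt(C, "Y (lag-0)")

    best: CBCResult | None = None
    for h in sorted(scale_by_lag):
        B = scale_by_lag[h][:P, P:]  # Cov(X_{t-h}, Y_t)
        K = Ai @ B @ Ci  # Theta1 = K K', Theta2 = K' K
        uw, svals, vwt = np.linalg.svd(K)
        phi = float(min(svals[0] ** 2, 1.0))
        if best is None or phi > best.phi:
            u = _fix_sign(Ai @ uw[:, 0])
            v = _fix_sign(Ci @ vwt[0, :])
            best = CBCResult(phi=phi, u=u, v=v, h=h, band=band, estimator=estimator)
    assert best is not None
    return best


def cbc_from_trial(
    Z: np.ndarray,
    P: int,
    Q: int,
    h_max: int = 5,
    estimator: str = "kendall_sine",
    band: FrequencyBand | None = None,
) -> CBCResult:
    """CBC of one band-filtered (P+Q, T) trial, searching lags 0..h_max."""
    scales = {h: robust_scale_matrix(Z, h, estimator).values for h in range(h_max + 1)}
    return cbc_solve(scales, P, Q, band=band, estimator=estimator)


def canonical_coherence_at_frequency(
    S: SpectralMatrix, omega: float, P: int, Q: int
) -> tuple[float, np.ndarray, np.ndarray]:
    """Canonical coherence at a single frequency (Hz) from a spectral matrix.

    Returns the largest eigenvalue of
    ``Sxx^{-1/2} Sxy Syy^{-1} Syx Sxx^{-1/2}`` and the directions a, b with
    ``a^H Sxx a = b^H Syy b = 1``.
    """
    fi = int(np.argmin(np.abs(S.freqs - omega)))
    M = S.matrices[fi]
    Sxx, Syy, Sxy = M[:P, :P], M[P:, P:], M[:P, P:]

    def _cinv_sqrt(m, what):
        w, v = np.linalg.eigh(0.5 * (m + m.conj().T))
        if w.min() <= _EIG_FLOOR * np.abs(np.trace(m)):
            raise SingularityError(f"{what} spectral block is singular at {S.freqs[fi]:g} Hz")
        return (v / np.sqrt(w)) @ v.conj().T

    Ai = _cinv_sqrt(Sxx, "X")
    Ci = _cinv_sqrt(Syy, "Y")
    K = Ai @ Sxy @ Ci
    uw, svals, vwh = np.linalg.svd(K)
    phi = float(min(svals[0] ** 2, 1.0))
    a = Ai @ uw[:, 0]
    b = Ci @ vwh[0, :].conj()
    return phi, a, b


# ---------------------------------------------------------------------------
# Direction summaries and the permutation test
# ---------------------------------------------------------------------------

@dataclass
class DirectionSummary:
    values: np.ndarray
    n_trials: int


def trial_directions_summary(directions: np.ndarray) -> DirectionSummary:
    """Spatial-median summary of per-trial canonical directions.

    The coordinatewise-separable L1 objective
    ``argmin_{mu >= 0} sum_r ||u(r) - mu||_L1`` is minimized by the
    coordinatewise median of the absolute per-trial directions (signs are
    ambiguous and fixed upstream, magnitudes are what the summary compares).
    """
    dirs = np.atleast_2d(np.asarray(directions, dtype=np.float64))
    if dirs.shape[0] < 1:
        raise ValueError("need at least one trial direction")
    med = np.median(np.abs(dirs), axis=0)
    return DirectionSummary(values=np.maximum(med, 0.0), n_trials=dirs.shape[0])


@dataclass
class DirectionTestResult:
    statistic: float
    p_raw: float
    p_adjusted: float | None
    pair: tuple[str, str] | None = None
    condition: str | None = None
    n_perm: int = 0


def _direction_stat(u_g, v_g, u_k, v_k) -> float:
    P = u_g.shape[1]
    Q = v_g.shape[1]
    du = np.linalg.norm(trial_directions_summary(u_g).values - trial_directions_summary(u_k).values)
    dv = np.linalg.norm(trial_directions_summary(v_g).values - trial_directions_summary(v_k).values)
    return float(du / P + dv / Q)


def smote_augment(X: np.ndarray, n_new: int, k: int = 5, rng=None) -> np.ndarray:
    """Synthetic minority oversampling: uniform interpolation to k-NN neighbors."""
    from sklearn.neighbors import NearestNeighbors

    rng = np.random.default_rng(rng)
    n = X.shape[0]
    if n < 2 or n_new <= 0:
        return X
    kk = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=kk + 1).fit(X)
    _, idx = nn.kneighbors(X)
    base = rng.integers(0, n, size=n_new)
    nbr = idx[base, rng.integers(1, kk + 1, size=n_new)]
    gap = rng.uniform(size=(n_new, 1))
    return np.vstack([X, X[base] + gap * (X[nbr] - X[base])])


def direction_difference_test(
    dirs_g: tuple[np.ndarray, np.ndarray],
    dirs_k: tuple[np.ndarray, np.ndarray],
    n_perm: int = 1000,
    seed: int | None = None,
    balance: str = "none",
) -> DirectionTestResult:
    """Permutation test for equality of canonical-direction configurations.

    ``dirs_g`` and ``dirs_k`` are (u, v) pairs of per-trial direction arrays
    for two odors: u of shape (R, P), v of shape (R, Q).  The statistic is

        T = ||U(g) - U(k)||_L2 / P + ||V(g) - V(k)||_L2 / Q

    with U, V the spatial-median summaries.  The null distribution relabels
    trials between the two odors.  With ``balance='smote'`` and a size ratio
    above 2, the minority group's stacked (u, v) vectors are augmented by
    SMOTE (k=5, uniform interpolation) before the medians are taken -- once
    per (re)labeling.
    """
    if balance not in ("none", "smote"):
        raise ValueError("balance must be 'none' or 'smote'")
    u_g, v_g = (np.atleast_2d(np.asarray(a, float)) for a in dirs_g)
    u_k, v_k = (np.atleast_2d(np.asarray(a, float)) for a in dirs_k)
    if u_g.shape[0] < 2 or u_k.shape[0] < 2:
        raise ValueError("each odor needs at least 2 trials")
    P, Q = u_g.shape[1], v_g.shape[1]
    rng = np.random.default_rng(seed)

    def stat(ug, vg, uk, vk, prng) -> float:
        if balance == "smote":
            ng, nk = ug.shape[0], uk.shape[0]
            if ng > 2 * nk:
                aug = smote_augment(np.hstack([np.abs(uk), np.abs(vk)]), ng - nk, rng=prng)
                uk, vk = aug[:, :P], aug[:, P:]
            elif nk > 2 * ng:
                aug = smote_augment(np.hstack([np.abs(ug), np.abs(vg)]), nk - ng, rng=prng)
                ug, vg = aug[:, :P], aug[:, P:]
        return _direction_stat(ug, vg, uk, vk)

    t_obs = stat(u_g, v_g, u_k, v_k, rng)
    u_all = np.vstack([u_g, u_k])
    v_all = np.vstack([v_g, v_k])
    n_g, n = u_g.shape[0], u_all.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        t_star = stat(
            u_all[perm[:n_g]], v_all[perm[:n_g]],
            u_all[perm[n_g:]], v_all[perm[n_g:]], rng,
        )
        if t_star >= t_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return DirectionTestResult(statistic=t_obs, p_raw=p, p_adjusted=None, n_perm=n_perm)


def pairwise_direction_tests(
    dirs_by_group: dict[str, tuple[np.ndarray, np.ndarray]],
    n_perm: int = 1000,
    seed: int | None = None,
    balance: str = "none",
    condition: str | None = None,
) -> list[DirectionTestResult]:
    """All pairwise direction tests with BH adjustment across the family."""
    keys = sorted(dirs_by_group)
    rng = np.random.default_rng(seed)
    results = []
    for i, g in enumerate(keys):
        for k in keys[i + 1:]:
            res = direction_difference_test(
                dirs_by_group[g], dirs_by_group[k], n_perm=n_perm,
                seed=int(rng.integers(2**31)), balance=balance,
            )
            res.pair = (g, k)
            res.condition = condition
            results.append(res)
    adj = benjamini_hochberg([r.p_raw for r in results])
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
    return results


# ---------------------------------------------------------------------------
# High-level estimator
# ---------------------------------------------------------------------------

class KenCoh:
    """Robust canonical band coherence over the trials of a TrialSet.

    Parameters
    ----------
    band : FrequencyBand
        Analysis band; trials are zero-phase Butterworth filtered to it.
    h_max : int
        Canonical lag search range 0..h_max (samples of the filtered series).
    estimator : {'kendall_sine', 'sample_covariance'}
        Scale-matrix estimator; the Kendall-sine path is outlier robust.
    filter_order : int
        Butterworth order.

    After :meth:`fit`, per-trial results live in ``results_`` and the arrays
    ``phi_`` (R,), ``u_`` (R, P), ``v_`` (R, Q), ``h_`` (R,).
    """

    def __init__(self, band: FrequencyBand, h_max: int = 5,
                 estimator: str = "kendall_sine", filter_order: int = 4):
        self.band = band
        self.h_max = h_max
        self.estimator = estimator
        self.filter_order = filter_order

    def fit(self, ts: TrialSet) -> "KenCoh":
        prox = ts.region_indices("proximal")
        dist = ts.region_indices("distal")
        if not prox or not dist:
            raise ValueError("TrialSet must contain both proximal and distal channels")
        spec = FilterSpec(band=self.band, order=self.filter_order)
        results = []
        for r in range(ts.n_trials):
            z = bandpass_filter(ts.data[r][prox + dist], spec, ts.fs)
            results.append(
                cbc_from_trial(z, len(prox), len(dist), h_max=self.h_max,
                               estimator=self.estimator, band=self.band)
            )
        self.proximal_idx_ = prox
        self.distal_idx_ = dist
        self.results_ = results
        self.phi_ = np.array([r.phi for r in results])
        self.u_ = np.array([r.u for r in results])
        self.v_ = np.array([r.v for r in results])
        self.h_ = np.array([r.h for r in results])
        return self
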