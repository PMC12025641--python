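"""Frequency-domain dynamic PCA isolation + pairwise Granger causality.

The goal is to test directed influence between two nodes of interest that
are embedded in a high-dimensional background network.  The pipeline is:

1. estimate the background cross-spectrum by a lag-window (Bartlett) smoother
   of the empirical lag covariances,
2. solve the per-frequency eigenproblem ``S(w) phi_j(w) = lambda_j(w)
   phi_j(w)`` and inverse-Fourier transform the eigenvectors into real
   time-domain filters of half-length L (frequency-domain dynamic PCA),
3. convolve the background with the filters to obtain a few dynamic
   principal component scores summarizing the background's activity,
4. regress each node of interest on the scores (optionally plus pairwise
   score interactions) and keep the residuals,
5. run the standard restricted-vs-unrestricted Granger F-test on the
   residual pair, per trial,
6. vote: a directed edge is "consistently present" when it is significant
   on at least 99% of trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "BackgroundSpectrum",
    "DPCFilterBank",
    "DPCScores",
    "GCTestResult",
    "EdgeVoteSummary",
    "estimate_background_spectrum",
    "dpc_filters",
    "dpc_scores",
    "partial_out",
    "gc_pair_test",
    "vote_edges",
    "choose_n_components",
    "SpectralDPCA",
]


@dataclass
class BackgroundSpectrum:
    """Hermitian cross-spectral matrices of the background on a full-circle grid."""

    freqs: np.ndarray  # cycles/sample in [0, 1)
    matrices: np.ndarray  # (F, P-2, P-2), Hermitian
    window: str
    M: int


def estimate_background_spectrum(
    zeta: np.ndarray,
    M: int | None = None,
    window: str = "bartlett",
    nfreq: int | None = None,
) -> BackgroundSpectrum:
    """Lag-window estimate S(w) = sum_{|h|<=M} w(|h|/M) Sigma(h) e^{-2 pi i h w}.

    ``zeta`` is (P-2, T); channels are demeaned internally; Sigma(-h) =
    Sigma(h)^T ensures Hermitian symmetry by construction.  M defaults to
    floor(sqrt(T)); the grid is the full circle [0, 1) so that the inverse
    transform of eigenvectors yields real filters.
    """
    z = np.atleast_2d(np.asarray(zeta, dtype=np.float64))
    p, t = z.shape
    if M is None:
        M = int(np.sqrt(t))
    if M >= t:
        raise ValueError(f"window size M={M} must be < T={t}")
    if window != "bartlett":
        raise ValueError("only the bartlett window is implemented")
    z = z - z.mean(axis=1, keepdims=True)
    nf = nfreq or t
    freqs = np.arange(nf) / nf
    lags = np.arange(-M, M + 1)
    w = 1.0 - np.abs(lags) / max(M, 1)
    covs = np.empty((len(lags), p, p))
    for i, h in enumerate(lags):
        hh = abs(h)
        c = z[:, hh:] @ z[:, : t - hh].T / t  # Cov(z_{t+h}, z_t), h >= 0
        covs[i] = c if h >= 0 else c.T
    phase = np.exp(-2j * np.pi * np.outer(freqs, lags))
    S = np.einsum("fh,hpq->fpq", phase * w, covs)
    S = 0.5 * (S + np.conj(np.transpose(S, (0, 2, 1))))
    return BackgroundSpectrum(freqs=freqs, matrices=S, window=window, M=M)


@dataclass
class DPCFilterBank:
    """Real time-domain filters of the leading dynamic principal components."""

    filters: np.ndarray  # (sc, 2L+1, P-2); filters[j, L+m] = rho_m^(j)
    eigenvalues: np.ndarray  # (F, P-2) descending per frequency
    L: int
    sc: int


def dpc_filters(S: BackgroundSpectrum, sc: int, L: int = 30) -> DPCFilterBank:
    """Per-frequency eigendecomposition -> inverse-Fourier time filters.

    Eigenvector phases are rotated so the largest-magnitude coordinate is
    real nonnegative, and conjugate symmetry ``phi_j(-w) = conj(phi_j(w))``
    is enforced by computing on [0, 1/2] and mirroring, so the filters are
    real.  Components are matched across frequencies by descending
    eigenvalue (no tracking through crossings).
    """
    F, p, _ = S.matrices.shape
    if sc > p:
        raise ValueError(f"sc={sc} exceeds background dimension {p}")
    lam = np.empty((F, p))
    vecs = np.empty((F, p, p), dtype=complex)
    half = F // 2
    for fi in range(half + 1):
        w, v = np.linalg.eigh(S.matrices[fi])
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for j in range(p):
            i = int(np.argmax(np.abs(v[:, j])))
            ph = v[i, j]
            if np.abs(ph) > 0:
                v[:, j] = v[:, j] * (np.conj(ph) / np.abs(ph))
        lam[fi], vecs[fi] = np.maximum(w, 0.0), v
    for fi in range(half + 1, F):
        lam[fi] = lam[F - fi]
        vecs[fi] = np.conj(vecs[F - fi])

    m = np.arange(-L, L + 1)
    # rho_m^(j) = (1/F) sum_f phi_j(w_f) e^{i 2 pi w_f m}
    phase = np.exp(2j * np.pi * np.outer(S.freqs, m))  # (F, 2L+1)
    filters = np.einsum("fpj,fm->jmp", vecs[:, :, :sc], phase).real / F
    return DPCFilterBank(filters=filters, eigenvalues=lam, L=L, sc=sc)


@dataclass
class DPCScores:
    scores: np.ndarray  # (sc, T') with T' = T - 2L
    L: int


def dpc_scores(zeta: np.ndarray, bank: DPCFilterBank) -> DPCScores:
    """dpc_{j,t} = sum_m rho_m^(j)' zeta_{t-m}, edges of length L trimmed."""
    z = np.atleast_2d(np.asarray(zeta, dtype=np.float64))
    p, t = z.shape
    L = bank.L
    if t <= 2 * L:
        raise ValueError(f"series length {t} must exceed 2L = {2 * L}")
    z = z - z.mean(axis=1, keepdims=True)
    tp = t - 2 * L
    out = np.zeros((bank.sc, tp))
    for j in range(bank.sc):
        acc = np.zeros(tp)
        for mi, m in enumerate(range(-L, L + 1)):
            # zeta_{t-m} for t in [L, T-L)
            acc += bank.filters[j, mi] @ z[:, L - m: L - m + tp]
        out[j] = acc
    order = np.argsort(out.var(axis=1))[::-1]
    return DPCScores(scores=out[order], L=L)


def choose_n_components(eigenvalues: np.ndarray, mass: float = 0.9) -> int:
    """Smallest component count whose summed eigenvalue mass reaches ``mass``."""
    tot = eigenvalues.sum(axis=0)  # per component, summed over frequencies
    frac = np.cumsum(tot) / tot.sum()
    return int(np.searchsorted(frac, mass) + 1)


def partial_out(
    x: np.ndarray, scores: DPCScores | np.ndarray, interactions: bool = False
) -> np.ndarray:
    """Residual of x after least squares on the score regressors.

    If ``x`` is longer than the scores by 2L (untrimmed), its edges are
    trimmed to align.  With ``interactions=True`` the pairwise score
    products are included.  Residuals are exactly orthogonal to the design.
    """
    if isinstance(scores, DPCScores):
        sc = scores.scores
        L = scores.L
    else:
        sc = np.atleast_2d(np.asarray(scores, dtype=np.float64))
        L = 0
    x = np.asarray(x, dtype=np.float64).ravel()
    tp = sc.shape[1]
    if len(x) == tp + 2 * L and L > 0:
        x = x[L:-L]
    if len(x) != tp:
        raise ValueError(f"x has length {len(x)}, scores have {tp}")
    cols = [np.ones(tp)] + [s for s in sc]
    if interactions:
        k = sc.shape[0]
        cols += [sc[i] * sc[j] for i in range(k) for j in range(i, k)]
    design = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


@dataclass
class GCTestResult:
    source: str
    target: str
    F: float
    p: float
    d_p: int
    d_q: int
    n: int


def _lag_matrix(x: np.ndarray, d: int, start: int) -> np.ndarray:
    return np.column_stack([x[start - i: len(x) - i] for i in range(1, d + 1)])


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _criterion(rss: float, n: int, k: int, which: str) -> float:
    if which == "bic":
        return n * np.log(rss / n) + k * np.log(n)
    if which == "aic":
        return n * np.log(rss / n) + 2 * k
    raise ValueError("criterion must be 'bic' or 'aic'")


def gc_pair_test(
    x_target: np.ndarray,
    x_source: np.ndarray,
    d_max: int = 10,
    criterion: str = "bic",
    alpha: float = 0.05,
    d_p: int | None = None,
    d_q: int | None = None,
    source: str = "source",
    target: str = "target",
) -> GCTestResult:
    """Granger F-test of source -> target on a pair of (residual) series.

    Restricted model: target on its own past (d_p lags).  Unrestricted:
    plus d_q lags of the source.  Lag orders are selected by the information
    criterion up to d_max unless given.  F = ((RSS_r - RSS_u)/d_q) /
    (RSS_u/(n - d_p - d_q - 1)) with p from the F(d_q, n - d_p - d_q - 1)
    reference distribution.
    """
    y = np.asarray(x_target, dtype=np.float64).ravel()
    x = np.asarray(x_source, dtype=np.float64).ravel()
    if len(y) != len(x):
        raise ValueError("series must have equal length")
    t = len(y)
    dm = max(d_max, d_p or 1, d_q or 1)
    if t <= 3 * dm + 5:
        raise ValueError(f"series too short (T={t}) for d_max={dm}")

    if d_p is None:
        best = None
        for d in range(1, d_max + 1):
            start = d_max  # common sample across candidate orders
            yy = y[start:]
            X = np.column_stack([np.ones(t - start), _lag_matrix(y, d, start)])
            c = _criterion(_ols_rss(yy, X), len(yy), d + 1, criterion)
            if best is None or c < best[0]:
                best = (c, d)
        d_p = best[1]
    if d_q is None:
        best = None
        for d in range(1, d_max + 1):
            start = d_max
            yy = y[start:]
            X = np.column_stack(
                [np.ones(t - start), _lag_matrix(y, d_p, start), _lag_matrix(x, d, start)]
            )
            c = _criterion(_ols_rss(yy, X), len(yy), d_p + d + 1, criterion)
            if best is None or c < best[0]:
                best = (c, d)
        d_q = best[1]

    start = max(d_p, d_q)
    yy = y[start:]
    n = len(yy)
    Xr = np.column_stack([np.ones(n), _lag_matrix(y, d_p, start)])
    Xu = np.column_stack([Xr, _lag_matrix(x, d_q, start)])
    rss_r = _ols_rss(yy, Xr)
    rss_u = _ols_rss(yy, Xu)
    dof = n - d_p - d_q - 1
    F = ((rss_r - rss_u) / d_q) / (rss_u / dof)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, d_q, dof))
    return GCTestResult(source=source, target=target, F=float(F), p=p,
                        d_p=d_p, d_q=d_q, n=n)


@dataclass
class EdgeVoteSummary:
    fractions: dict
    consistent: dict
    threshold: float
    alpha: float


def vote_edges(
    per_trial_results: dict,
    threshold: float = 0.99,
    alpha: float = 0.05,
) -> EdgeVoteSummary:
    """Aggregate per-trial GC results: an edge is consistent when significant
    on at least ``threshold`` (fraction) of trials.
    """
    fractions, consistent = {}, {}
    for pair, results in per_trial_results.items():
        if not results:
            raise ValueError(f"empty result list for pair {pair}")
        sig = [r.p < alpha if isinstance(r, GCTestResult) else bool(r) for r in results]
        frac = float(np.mean(sig))
        fractions[pair] = frac
        consistent[pair] = frac >= threshold - 1e-12
    return EdgeVoteSummary(fractions=fractions, consistent=consistent,
                           threshold=threshold, alpha=alpha)


class SpectralDPCA:
    """Convenience wrapper: background spectrum -> filters -> scores.

    ``sc=None`` picks the smallest component count capturing 90% of the
    summed eigenvalue mass.
    """

    def __init__(self, sc: int | None = None, L: int = 30, M: int | None = None,
                 window: str = "bartlett", mass: float = 0.9):
        self.sc = sc
        self.L = L
        self.M = M
        self.window = window
        self.mass = mass

    def fit(self, zeta: np.ndarray) -> "SpectralDPCA":
        self.spectrum_ = estimate_background_spectrum(zeta, M=self.M, window=self.window)
        if self.sc is None:
            full = dpc_filters(self.spectrum_, sc=self.spectrum_.matrices.shape[1], L=self.L)
            sc = choose_n_components(full.eigenvalues, self.mass)
            self.bank_ = DPCFilterBank(filters=full.filters[:sc], eigenvalues=full.eigenvalues,
                                       L=self.L, sc=sc)
        else:
            self.bank_ = dpc_filters(self.spectrum_, sc=self.sc, L=self.L)
        self.scores_ = dpc_scores(zeta, self.bank_)
        return self

    def transform(self, zeta: np.ndarray) -> DPCScores:
        return dpc_scores(zeta, self.bank_)
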