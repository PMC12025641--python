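"""Non-decimated wavelet decomposition and localized cross-scale coherence.

Signals are decomposed with the maximal-overlap (non-decimated) discrete
wavelet transform into length-preserving scale subprocesses X_j(t); the
localized coherence between the scale-j subprocess of channel p and the
scale-j' subprocess of channel q is the squared magnitude of a rolling-
window correlation

    rho_{jj'}^{(p,q)}(t/T) = | Cov(X_j^p(t), X_j'^q(t))
                              / sqrt(Var(X_j^p(t)) Var(X_j'^q(t))) |^2,

estimated with centered boxcar windows of W samples.  Values lie in [0, 1];
when j = j' the cross-scale quantity reduces exactly to the single-scale
coherence.  Group differences (e.g. correct vs incorrect trials) are tested
by permuting trial labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "ScaleSubprocess",
    "LocalCoherence",
    "GroupCoherenceTest",
    "modwt_details",
    "local_cross_scale_coherence",
    "coherence_group_test",
]

DEFAULT_WAVELET = "sym8"  # Daubechies least-asymmetric, 8 vanishing moments


@dataclass
class ScaleSubprocess:
    """Per-channel scale subprocesses: details (P, J, T) plus the smooth."""

    details: np.ndarray
    smooth: np.ndarray
    wavelet_family: str
    J: int

    def detail(self, channel: int, scale: int) -> np.ndarray:
        """Scale-j subprocess (1-based scale, 1 = finest) of one channel."""
        if not 1 <= scale <= self.J:
            raise ValueError(f"scale must be in 1..{self.J}")
        return self.details[channel, scale - 1]


def modwt_details(
    trial: np.ndarray, family: str = DEFAULT_WAVELET, J: int | None = None
) -> ScaleSubprocess:
    """Maximal-overlap wavelet details at scales 1..J of a (P, T) trial.

    Length is preserved per scale and the energy identity
    ``sum_j ||D_j||^2 + ||smooth_J||^2 = ||X||^2`` holds (normalized
    transform).  T must be divisible by 2^J; the default J is
    floor(log2(T)) - 2 to keep boundary effects modest.
    """
    x = np.atleast_2d(np.asarray(trial, dtype=np.float64))
    p, t = x.shape
    if J is None:
        J = max(int(np.log2(t)) - 2, 1)
    if t < 2**J or t % (2**J) != 0:
        raise ValueError(f"T={t} must be a multiple of 2^J = {2**J}")
    details = np.empty((p, J, t))
    smooth = np.empty((p, t))
    for ch in range(p):
        coeffs = pywt.swt(x[ch], family, level=J, trim_approx=True, norm=True)
        smooth[ch] = coeffs[0]
        for j in range(1, J + 1):  # coeffs[1] = cD_J, ..., coeffs[J] = cD_1
            details[ch, j - 1] = coeffs[J - j + 1]
    return ScaleSubprocess(details=details, smooth=smooth, wavelet_family=family, J=J)


@dataclass
class LocalCoherence:
    """Squared local correlation trajectory in [0, 1]; NaN where undefined."""

    values: np.ndarray
    window: int
    scales: tuple[int, int]
    channels: tuple[int, int] | None = None


def local_cross_scale_coherence(
    sub_p: np.ndarray, sub_q: np.ndarray, W: int = 128
) -> LocalCoherence:
    """Rolling-window squared correlation between two scale subprocesses.

    Uses a centered boxcar window of W samples; time points whose window is
    incomplete (edges) or has zero local variance are NaN.
    """
    a = np.asarray(sub_p, dtype=np.float64).ravel()
    b = np.asarray(sub_q, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("series must be aligned")
    if W < 8:
        raise ValueError("window length W must be >= 8")
    t = len(a)
    if t < W:
        raise ValueError(f"series length {t} shorter than window {W}")
    win = np.lib.stride_tricks.sliding_window_view
    aw, bw = win(a, W), win(b, W)
    ma, mb = aw.mean(axis=1), bw.mean(axis=1)
    cov = (aw * bw).mean(axis=1) - ma * mb
    va = (aw**2).mean(axis=1) - ma**2
    vb = (bw**2).mean(axis=1) - mb**2
    out = np.full(t, np.nan)
    denom = va * vb
    valid = denom > 0
    vals = np.full(t - W + 1, np.nan)
    vals[valid] = np.clip(cov[valid] ** 2 / denom[valid], 0.0, 1.0)
    out[W // 2: W // 2 + t - W + 1] = vals
    return LocalCoherence(values=out, window=W, scales=(0, 0))


@dataclass
class GroupCoherenceTest:
    statistic: float
    p_value: float
    n_perm: int
    mean_group1: np.ndarray
    mean_group2: np.ndarray


def _trial_trajectories(ts, scale_pair, channel_pair, W, family=DEFAULT_WAVELET, J=None):
    j, jp = scale_pair
    p, q = channel_pair
    trajs = []
    for r in range(ts.n_trials):
        sub = modwt_details(ts.data[r][[p, q]], family=family,
                            J=J or max(j, jp))
        lc = local_cross_scale_coherence(sub.detail(0, j), sub.detail(1, jp), W)
        trajs.append(lc.values)
    trajs = np.array(trajs)
    # drop the incomplete-window edge columns (all-missing by construction)
    keep = ~np.all(np.isnan(trajs), axis=0)
    return trajs[:, keep]


def coherence_group_test(
    ts_group1,
    ts_group2,
    scale_pair: tuple[int, int],
    channel_pair: tuple[int, int],
    W: int = 128,
    n_perm: int = 1000,
    seed: int | None = None,
    family: str = DEFAULT_WAVELET,
    J: int | None = None,
) -> GroupCoherenceTest:
    """Permutation test for group differences in mean coherence trajectories.

    The statistic is the time-averaged absolute difference of the two group
    mean trajectories; the null permutes trial labels between the groups;
    the p-value uses the add-one convention.
    """
    if ts_group1.n_trials < 2 or ts_group2.n_trials < 2:
        raise ValueError("each group needs at least 2 trials")
    t1 = _trial_trajectories(ts_group1, scale_pair, channel_pair, W, family, J)
    t2 = _trial_trajectories(ts_group2, scale_pair, channel_pair, W, family, J)
    n1 = len(t1)
    allt = np.vstack([t1, t2])

    def stat(g1, g2):
        m1 = np.nanmean(g1, axis=0)
        m2 = np.nanmean(g2, axis=0)
        return float(np.nanmean(np.abs(m1 - m2)))

    obs = stat(t1, t2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(allt))
        if stat(allt[perm[:n1]], allt[perm[n1:]]) >= obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return GroupCoherenceTest(statistic=obs, p_value=p, n_perm=n_perm,
                              mean_group1=np.nanmean(t1, axis=0),
                              mean_group2=np.nanmean(t2, axis=0))
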