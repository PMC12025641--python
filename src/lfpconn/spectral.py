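"""Frequency bands, band-pass filtering, spectral matrices and coherence.

The five canonical EEG/LFP rhythms are used throughout: delta (0.5-4 Hz),
theta (4-8 Hz), alpha (8-12 Hz), beta (12-30 Hz) and gamma (30-50 Hz).  A
generic band (omega_L, omega_H) in cycles/sample maps to Hz by multiplying
with the sampling rate.

Spectral matrices follow the convention ``S(w) = sum_k Sigma(k) exp(-i 2 pi
w k)`` with ``w`` in cycles/sample, so white noise with covariance Sigma has
a flat spectrum equal to Sigma.  Coherence is the magnitude-squared quantity
``|S_pq|^2 / (S_pp S_qq)`` in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core_io import TrialSet
from .exceptions import DegenerateInputError

__all__ = [
    "FrequencyBand",
    "FilterSpec",
    "SpectralMatrix",
    "CoherenceMatrix",
    "BANDS",
    "band_to_hz",
    "bandpass_filter",
    "spectral_matrix",
    "coherence_matrix",
]


@dataclass(frozen=True)
class FrequencyBand:
    """A frequency band [lo, hi] in Hz (or cycles/sample when fs = 1)."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"need 0 < lo < hi, got ({self.lo}, {self.hi})")


#: The standard EEG/LFP rhythm bands in Hz.
BANDS = {
    "delta": FrequencyBand("delta", 0.5, 4.0),
    "theta": FrequencyBand("theta", 4.0, 8.0),
    "alpha": FrequencyBand("alpha", 8.0, 12.0),
    "beta": FrequencyBand("beta", 12.0, 30.0),
    "gamma": FrequencyBand("gamma", 30.0, 50.0),
}


def band_to_hz(generic: tuple[float, float], fs: float, name: str = "") -> FrequencyBand:
    """Map a generic band (wL, wH) in cycles/sample, 0 < wL < wH < 0.5, to Hz."""
    lo, hi = generic
    if not (0 < lo < hi < 0.5):
        raise ValueError(f"generic band must satisfy 0 < lo < hi < 0.5, got {generic}")
    return FrequencyBand(name or f"{fs * lo:g}-{fs * hi:g}Hz", fs * lo, fs * hi)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter specification: Butterworth, zero-phase by default."""

    band: FrequencyBand
    family: str = "butterworth"
    order: int = 4
    phase: str = "zero_phase"

    def __post_init__(self) -> None:
        if self.family != "butterworth":
            raise ValueError("only the butterworth family is supported")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


def bandpass_filter(x: np.ndarray, spec: FilterSpec | FrequencyBand, fs: float) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass of a (P, T) trial.

    Accepts a 1-D series or a (P, T) array; filtering is along the last axis.
    """
    if isinstance(spec, FrequencyBand):
        spec = FilterSpec(band=spec)
    band = spec.band
    nyq = fs / 2.0
    if band.hi >= nyq:
        raise ValueError(f"band edge {band.hi} Hz must lie below the Nyquist rate {nyq} Hz")
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] <= 3 * spec.order:
        raise ValueError("series too short for the requested filter order")
    sos = sps.butter(spec.order, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


@dataclass
class SpectralMatrix:
    """Hermitian P x P cross-spectral matrices on a frequency grid.

    ``freqs`` are in Hz; ``matrices`` has shape (F, P, P).  ``n_segments``
    records how many trials/segments were averaged.
    """

    freqs: np.ndarray
    matrices: np.ndarray
    fs: float
    n_segments: int
    method: str
    channel_ids: list[str] = field(default_factory=list)

    def band_slice(self, band: FrequencyBand) -> np.ndarray:
        mask = (self.freqs >= band.lo) & (self.freqs <= band.hi)
        if not mask.any():
            raise ValueError(
                f"band ({band.lo}, {band.hi}) Hz contains no grid frequencies"
            )
        return self.matrices[mask]


def spectral_matrix(
    ts: TrialSet,
    channels: list[int] | None = None,
    method: str = "trial_averaged_periodogram",
    M: int | None = None,
) -> SpectralMatrix:
    """Estimate the cross-spectral matrix of a TrialSet.

    ``trial_averaged_periodogram`` averages per-trial cross-periodograms over
    trials (requires K >= 2 trials of equal length).  ``lag_window`` smooths
    the pooled lag-covariance sequence with a Bartlett window of bandwidth
    ``M`` (default floor(sqrt(T))).
    """
    if ts.n_trials < 1:
        raise ValueError("need at least one trial")
    idx = list(range(ts.n_channels)) if channels is None else list(channels)
    data = ts.data[:, idx, :]  # (R, P, T)
    r, p, t = data.shape
    data = data - data.mean(axis=2, keepdims=True)
    nfreq = t // 2 + 1
    freqs_cs = np.arange(nfreq) / t  # cycles/sample, [0, 0.5]

    if method == "trial_averaged_periodogram":
        if r == 1:
            raise ValueError(
                "K=1 trial gives an inconsistent raw periodogram; use method='lag_window' "
                "or provide multiple trials"
            )
        d = np.fft.rfft(data, axis=2)  # (R, P, F)
        S = np.einsum("rpf,rqf->fpq", d, d.conj()) / (t * r)
    elif method == "lag_window":
        if M is None:
            M = int(np.sqrt(t))
        S = np.zeros((nfreq, p, p), dtype=complex)
        for rr in range(r):
            S += _lag_window_spectrum(data[rr], M, freqs_cs)
        S /= r
    else:
        raise ValueError(f"unknown method {method!r}")

    S = 0.5 * (S + np.conj(np.transpose(S, (0, 2, 1))))  # enforce Hermitian
    cids = [ts.channels[i].channel_id for i in idx] if ts.channels else []
    return SpectralMatrix(
        freqs=freqs_cs * ts.fs, matrices=S, fs=ts.fs, n_segments=r, method=method,
        channel_ids=cids,
    )


def _lag_window_spectrum(x: np.ndarray, M: int, freqs_cs: np.ndarray) -> np.ndarray:
    """Bartlett lag-window spectral estimate of one demeaned (P, T) trial."""
    p, t = x.shape
    if M >= t:
        raise ValueError(f"window size M={M} must be < T={t}")
    lags = np.arange(-M, M + 1)
    w = 1.0 - np.abs(lags) / max(M, 1)  # Bartlett; M=0 -> single weight 1
    covs = np.empty((len(lags), p, p))
    for i, h in enumerate(lags):
        hh = abs(h)
        c = x[:, hh:] @ x[:, : t - hh].T / t  # Cov(x_{t+h}, x_t) for h >= 0
        covs[i] = c if h >= 0 else c.T
    phase = np.exp(-2j * np.pi * np.outer(freqs_cs, lags))  # (F, H)
    return np.einsum("fh,hpq->fpq", phase * w, covs)


@dataclass
class CoherenceMatrix:
    """Symmetric P x P coherence values in [0, 1] with a band annotation."""

    values: np.ndarray
    band: FrequencyBand | None = None
    channel_ids: list[str] = field(default_factory=list)


def coherence_matrix(S: SpectralMatrix, band: FrequencyBand | None = None) -> CoherenceMatrix:
    """Band-averaged coherence |S_pq|^2 / (S_pp S_qq) from a spectral matrix.

    Per-frequency coherences are averaged with equal weight over the grid
    frequencies inside the band (the full grid when no band is given); the
    diagonal is exactly 1.
    """
    mats = S.band_slice(band) if band is not None else S.matrices
    auto = np.real(np.einsum("fpp->fp", mats))
    # frequencies with (numerically) zero auto-spectrum carry no information;
    # demeaning zeroes the DC bin, so exclude such bins from the average
    tol = 1e-12 * max(auto.max(), np.finfo(float).tiny)
    valid = (auto > tol).all(axis=1)
    if not valid.any():
        raise DegenerateInputError("zero auto-spectrum throughout the requested band")
    mats, auto = mats[valid], auto[valid]
    denom = auto[:, :, None] * auto[:, None, :]
    coh = (np.abs(mats) ** 2 / denom).mean(axis=0)
    coh = np.clip(0.5 * (coh + coh.T), 0.0, 1.0)
    np.fill_diagonal(coh, 1.0)
    return CoherenceMatrix(values=coh, band=band, channel_ids=list(S.channel_ids))
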