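"""Synthetic LFP-like trial generators with known ground truth.

The real recordings emulated here are not public, so every estimator in the
toolkit is exercised against simulated TrialSets whose generating mechanism
is fully known:

* :func:`simulate_var_trials` -- stationary vector autoregressions (Gaussian
  or standardized Student-t innovations) for correlation, coherence, and
  Granger-causality ground truth.
* :func:`simulate_am_pair` -- a driver/receiver pair of band-limited carriers
  multiplied by strictly positive amplitude envelopes; the receiver's
  envelope depends on the driver's envelope lagged by a whole number of
  blocks, which is exactly the coupling the block-maxima transfer-entropy
  pathway is designed to detect.
* :func:`simulate_lsw_trials` -- locally stationary wavelet processes
  ``X(t) = sum_j sum_k V_j(k/T) psi_{j,t-k} z_{j,k}`` with optional
  cross-scale innovation correlation, for the wavelet-coherence pathway.
* :func:`contaminate` -- point or block outlier contamination for
  robustness benchmarks.

All generators are pure functions of (spec, seed): identical calls return
bit-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .core_io import ODORS, ChannelInfo, TrialInfo, TrialSet
from .spectral import FilterSpec, FrequencyBand, bandpass_filter

__all__ = [
    "VARSpec",
    "AMSpec",
    "LSWSpec",
    "ContaminationSpec",
    "simulate_var_trials",
    "simulate_am_pair",
    "simulate_lsw_trials",
    "contaminate",
    "default_channels",
    "default_trials",
]


def default_channels(p: int, n_proximal: int | None = None) -> list[ChannelInfo]:
    """T1..TP channel metadata; the first half (or n_proximal) proximal."""
    npx = (p + 1) // 2 if n_proximal is None else n_proximal
    return [
        ChannelInfo(f"T{i + 1}", "proximal" if i < npx else "distal")
        for i in range(p)
    ]


def default_trials(r: int, template: TrialInfo | None = None) -> list[TrialInfo]:
    """Trial metadata: template labels, or odors cycled A-E, in/correct."""
    if template is None:
        return [TrialInfo(f"trial{i:04d}", ODORS[i % 5], "in", "correct") for i in range(r)]
    return [
        TrialInfo(f"trial{i:04d}", template.odor, template.sequence, template.response)
        for i in range(r)
    ]


# ---------------------------------------------------------------------------
# VAR
# ---------------------------------------------------------------------------

@dataclass
class VARSpec:
    """A stationary VAR(p) specification."""

    P: int
    order: int
    coeffs: list[np.ndarray]
    innov_cov: np.ndarray
    innov_family: str = "gaussian"
    df: float = 5.0  # only for student_t

    def __post_init__(self) -> None:
        self.coeffs = [np.asarray(a, dtype=np.float64) for a in self.coeffs]
        self.innov_cov = np.asarray(self.innov_cov, dtype=np.float64)
        if len(self.coeffs) != self.order:
            raise ValueError("need one coefficient matrix per lag")
        for a in self.coeffs:
            if a.shape != (self.P, self.P):
                raise ValueError(f"coefficient matrices must be {self.P}x{self.P}")
        if self.innov_cov.shape != (self.P, self.P):
            raise ValueError("innov_cov shape mismatch")
        w = np.linalg.eigvalsh(0.5 * (self.innov_cov + self.innov_cov.T))
        if w.min() <= 0:
            raise ValueError("innov_cov must be symmetric positive definite")
        if self.innov_family not in ("gaussian", "student_t"):
            raise ValueError("innov_family must be 'gaussian' or 'student_t'")
        if self.innov_family == "student_t" and self.df <= 2:
            raise ValueError("student_t needs df > 2 for finite variance")

    def spectral_radius(self) -> float:
        p, k = self.P, self.order
        if k == 0:
            return 0.0
        comp = np.zeros((p * k, p * k))
        comp[:p, :] = np.hstack(self.coeffs)
        if k > 1:
            comp[p:, : p * (k - 1)] = np.eye(p * (k - 1))
        return float(np.abs(np.linalg.eigvals(comp)).max())


def _draw_innovations(spec: VARSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    L = np.linalg.cholesky(spec.innov_cov)
    z = rng.standard_normal((n, spec.P))
    if spec.innov_family == "student_t":
        # standardized to unit variance so robustness comparisons hold variance fixed
        g = rng.chisquare(spec.df, size=(n, 1))
        z = z * np.sqrt(spec.df / g) * np.sqrt((spec.df - 2) / spec.df)
    return z @ L.T


def simulate_var_trials(
    spec: VARSpec,
    R: int,
    T: int,
    fs: float = 1000.0,
    labels: TrialInfo | None = None,
    seed: int | None = None,
) -> TrialSet:
    """Simulate R independent trials of a stationary VAR process.

    A burn-in of 10x the VAR order is discarded to remove initialization
    transients.
    """
    rho = spec.spectral_radius()
    if rho >= 1.0:
        raise ValueError(f"VAR is not stationary: companion spectral radius {rho:.4f} >= 1")
    rng = np.random.default_rng(seed)
    burn = 10 * spec.order
    data = np.empty((R, spec.P, T))
    for r in range(R):
        eps = _draw_innovations(spec, T + burn, rng)
        x = np.zeros((T + burn, spec.P))
        for t in range(T + burn):
            acc = eps[t].copy()
            for i, a in enumerate(spec.coeffs, start=1):
                if t - i >= 0:
                    acc += a @ x[t - i]
            x[t] = acc
        data[r] = x[burn:].T
    return TrialSet(data=data, fs=fs, channels=default_channels(spec.P),
                    trials=default_trials(R, labels))


# ---------------------------------------------------------------------------
# Amplitude-modulated pair
# ---------------------------------------------------------------------------

@dataclass
class AMSpec:
    """Driver/receiver pair: band carrier x positive envelope, envelope-coupled.

    The receiver's log-envelope at block b equals ``coupling_gain`` times the
    driver's log-envelope at block ``b - coupling_delay`` plus independent
    AR(1) noise; carriers are independent band-limited noise.  Envelopes are
    piecewise constant over blocks of ``block_size`` samples and strictly
    positive by construction (exponential of a Gaussian AR(1)).
    """

    carrier_freq: float
    band: FrequencyBand
    modulator_ar: float = 0.7
    coupling_gain: float = 0.8
    coupling_delay: int = 1
    block_size: int = 100

    def __post_init__(self) -> None:
        if not (self.band.lo <= self.carrier_freq <= self.band.hi):
            raise ValueError(
                f"carrier {self.carrier_freq} Hz outside band "
                f"({self.band.lo}, {self.band.hi}) Hz"
            )
        if not (-1 < self.modulator_ar < 1):
            raise ValueError("modulator_ar must lie in (-1, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.coupling_delay < 1:
            raise ValueError("coupling_delay must be >= 1 block")


def _ar1(n: int, a: float, rng: np.random.Generator) -> np.ndarray:
    e = rng.standard_normal(n) * np.sqrt(1 - a**2)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    for i in range(1, n):
        x[i] = a * x[i - 1] + e[i]
    return x


def _band_carrier(
    T: int, band: FrequencyBand, fs: float, carrier_freq: float, rng: np.random.Generator
) -> np.ndarray:
    """Narrowband noise centered at the carrier frequency, inside the band."""
    half = min(1.0, 0.2 * (band.hi - band.lo))
    lo = max(band.lo, carrier_freq - half)
    hi = min(band.hi, carrier_freq + half)
    w = rng.standard_normal(T + 400)
    c = bandpass_filter(w, FilterSpec(band=FrequencyBand("carrier", lo, hi)), fs)[200:-200]
    return c / c.std()


def simulate_am_pair(
    spec: AMSpec,
    R: int,
    T: int,
    fs: float = 1000.0,
    seed: int | None = None,
) -> TrialSet:
    """Simulate R trials of the 2-channel driver -> receiver AM pair."""
    rng = np.random.default_rng(seed)
    m = spec.block_size
    if T < m * (spec.coupling_delay + 2):
        raise ValueError("T too short for the requested block structure")
    nb = T // m + spec.coupling_delay + 1
    data = np.empty((R, 2, T))
    for r in range(R):
        log_ad = _ar1(nb, spec.modulator_ar, rng)
        noise = _ar1(nb, spec.modulator_ar, rng)
        log_ar_ = np.zeros(nb)
        d = spec.coupling_delay
        log_ar_[d:] = spec.coupling_gain * log_ad[:-d]
        log_ar_ += np.sqrt(max(1 - spec.coupling_gain**2, 0.05)) * noise
        env_d = np.repeat(np.exp(log_ad), m)[-T:]
        env_r = np.repeat(np.exp(log_ar_), m)[-T:]
        data[r, 0] = env_d * _band_carrier(T, spec.band, fs, spec.carrier_freq, rng)
        data[r, 1] = env_r * _band_carrier(T, spec.band, fs, spec.carrier_freq, rng)
    channels = [ChannelInfo("driver", "distal"), ChannelInfo("receiver", "proximal")]
    return TrialSet(data=data, fs=fs, channels=channels, trials=default_trials(R))


# ---------------------------------------------------------------------------
# Locally stationary wavelet processes
# ---------------------------------------------------------------------------

@dataclass
class LSWSpec:
    """Locally stationary wavelet process specification.

    ``transfer`` holds the time-varying transfer values V_j(u) on a rescaled-
    time grid u in [0, 1): shape (J, G) applies one transfer per scale to all
    channels, shape (J, P, G) is per channel.  ``cross_scale`` is either a
    constant (J, J, P, P) array of innovation correlations Q_{jj'} between
    channel components at scales j and j', or a callable u -> (J, J, P, P)
    for time-varying cross-scale dependence; the stacked (J*P) innovation
    covariance must be positive semidefinite at every u.
    """

    J: int
    P: int
    transfer: np.ndarray
    cross_scale: object = None  # None -> identity
    wavelet_family: str = "sym8"

    def __post_init__(self) -> None:
        self.transfer = np.asarray(self.transfer, dtype=np.float64)
        if self.transfer.ndim == 2:
            if self.transfer.shape[0] != self.J:
                raise ValueError("transfer must have J rows")
            self.transfer = np.broadcast_to(
                self.transfer[:, None, :], (self.J, self.P, self.transfer.shape[1])
            ).copy()
        if self.transfer.shape[:2] != (self.J, self.P):
            raise ValueError("transfer must have shape (J, G) or (J, P, G)")
        if not np.all(np.isfinite(self.transfer)):
            raise ValueError("transfer values must be finite")

    def q_matrix(self, u: float) -> np.ndarray:
        """Stacked (J*P, J*P) innovation covariance at rescaled time u."""
        if self.cross_scale is None:
            return np.eye(self.J * self.P)
        q = self.cross_scale(u) if callable(self.cross_scale) else self.cross_scale
        q = np.asarray(q, dtype=np.float64)
        if q.shape != (self.J, self.J, self.P, self.P):
            raise ValueError("cross_scale blocks must have shape (J, J, P, P)")
        full = q.transpose(0, 2, 1, 3).reshape(self.J * self.P, self.J * self.P)
        return 0.5 * (full + full.T)


def _synthesis_wavelets(family: str, J: int, T: int) -> np.ndarray:
    """Impulse responses psi_j (J, T) of the non-decimated detail synthesis.

    psi_j is obtained by inverting a coefficient set that is a unit impulse
    at detail level j, so synthesis is exactly adjoint to the analysis
    transform used by the coherence estimators (circular boundary).
    """
    psi = np.empty((J, T))
    for j in range(1, J + 1):
        coeffs = [np.zeros(T)]  # smooth at level J
        for lev in range(J, 0, -1):
            d = np.zeros(T)
            if lev == j:
                d[0] = 1.0
            coeffs.append(d)
        psi[j - 1] = pywt.iswt(coeffs, family, norm=True)
    return psi


def simulate_lsw_trials(
    spec: LSWSpec,
    R: int,
    T: int,
    fs: float = 1000.0,
    seed: int | None = None,
) -> TrialSet:
    """Simulate R trials of a P-variate locally stationary wavelet process.

    T must be a power of two.  For each shift k, the stacked innovation
    vector over scales and channels is drawn with covariance Q(k/T); the
    signal is the superposition of circular convolutions of the modulated
    innovations with the non-decimated synthesis wavelets.
    """
    if T < 2 or (T & (T - 1)) != 0:
        raise ValueError(f"T must be a power of two, got {T}")
    if T < 2**spec.J:
        raise ValueError("need T >= 2^J")
    rng = np.random.default_rng(seed)
    J, P = spec.J, spec.P
    psi = _synthesis_wavelets(spec.wavelet_family, J, T)
    psi_f = np.fft.rfft(psi, axis=1)  # (J, F)
    g = spec.transfer.shape[2]
    grid_idx = np.minimum((np.arange(T) / T * g).astype(int), g - 1)
    V = spec.transfer[:, :, grid_idx]  # (J, P, T)

    # Cholesky factors of Q on the transfer grid (step-constant in u)
    chols = []
    for gi in range(g):
        q = spec.q_matrix(gi / g)
        w, vv = np.linalg.eigh(q)
        if w.min() < -1e-8:
            raise ValueError("cross_scale covariance is not positive semidefinite")
        chols.append(vv @ np.diag(np.sqrt(np.maximum(w, 0.0))))
    chols = np.array(chols)  # (G, J*P, J*P)

    data = np.empty((R, P, T))
    for r in range(R):
        zraw = rng.standard_normal((T, J * P))
        z = np.einsum("tij,tj->ti", chols[grid_idx], zraw)  # (T, J*P)
        z = z.reshape(T, J, P).transpose(1, 2, 0)  # (J, P, T)
        a = V * z  # modulated innovations per (scale, channel, shift)
        af = np.fft.rfft(a, axis=2)
        x = np.fft.irfft(af * psi_f[:, None, :], n=T, axis=2)  # circular conv
        data[r] = x.sum(axis=0)
    return TrialSet(data=data, fs=fs, channels=default_channels(P),
                    trials=default_trials(R))


# ---------------------------------------------------------------------------
# Contamination
# ---------------------------------------------------------------------------

@dataclass
class ContaminationSpec:
    """Outlier contamination: point (independent samples) or block (runs)."""

    rate: float
    magnitude: float
    mode: str = "point"
    block_len: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.rate <= 1):
            raise ValueError("rate must lie in [0, 1]")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.mode not in ("point", "block"):
            raise ValueError("mode must be 'point' or 'block'")


def contaminate(
    ts: TrialSet, spec: ContaminationSpec, seed: int | None = None
) -> tuple[TrialSet, np.ndarray]:
    """Replace samples with outliers; returns (contaminated set, boolean mask).

    Point mode replaces each sample independently with probability ``rate``
    by ``value +/- magnitude * sigma_channel`` (random sign); block mode
    starts runs of ``block_len`` samples at rate ``rate / block_len`` so the
    expected contaminated fraction matches point mode.
    """
    rng = np.random.default_rng(seed)
    data = ts.data.copy()
    r, p, t = data.shape
    if spec.mode == "point":
        mask = rng.random((r, p, t)) < spec.rate
    else:
        starts = rng.random((r, p, t)) < spec.rate / max(spec.block_len, 1)
        mask = np.zeros((r, p, t), dtype=bool)
        for off in range(spec.block_len):
            mask[:, :, off:] |= starts[:, :, : t - off] if off else starts
    if mask.any() and spec.magnitude > 0:
        sd = data.std(axis=2, keepdims=True)
        signs = rng.choice([-1.0, 1.0], size=(r, p, t))
        data = np.where(mask, data + signs * spec.magnitude * sd, data)
    out = TrialSet(data=data, fs=ts.fs, channels=list(ts.channels), trials=list(ts.trials))
    return out, mask
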