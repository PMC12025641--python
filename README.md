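# lfpconn

Connectivity analysis for multi-trial local field potential (LFP) recordings.

`lfpconn` is a toolkit for neuroscientists and statisticians studying how
brain regions interact, built around trial-structured multichannel
electrophysiology: R trials x P channels (tetrodes) x T samples, with
per-trial labels (odor A–E, in/out-of-sequence presentation,
correct/incorrect response) and per-channel anatomical labels (proximal or
distal CA1). Because such recordings are rarely public, the package ships a
first-class synthetic-data generator with known ground truth for every
estimator.

## Methods

**Time-domain dependence** (`lfpconn.timedep`): cross-covariance
σ̂_pq(k) = (1/T) Σ_t x_{p,t} x_{q,t+k}, correlation
ρ_pq(k) = σ_pq(k)/√(σ_pp(0)σ_qq(0)), and partial correlation via the
precision matrix Θ = Σ(0)⁻¹, ρ_pq|v = −Θ_pq/√(Θ_pp Θ_qq); a two-sample
trial-label permutation test with the Welch-type statistic
(ρ̄₁ − ρ̄₂)/√(ν̂₁/n₁ + ν̂₂/n₂), exhaustive when feasible, with
Benjamini–Hochberg correction across channel pairs.

**Spectral dependence** (`lfpconn.spectral`): the five EEG/LFP rhythm bands
(delta 0.5–4, theta 4–8, alpha 8–12, beta 12–30, gamma 30–50 Hz), zero-phase
Butterworth band-pass filtering, trial-averaged periodogram or Bartlett
lag-window spectral matrices S(ω), and band-averaged coherence
C_pq = |S_pq|²/(S_pp S_qq) ∈ [0, 1].

**Robust canonical band coherence — KenCoh** (`lfpconn.kencoh`): the
canonical band coherence (CBC)

φ(Ω) = max_{u,v,h} |u′ Σ_XY^Ω(h) v|²  s.t.  u′ Σ_XX^Ω(0) u = v′ Σ_YY^Ω(0) v = 1

between the band-filtered proximal group X and distal group Y, solved by the
eigendecomposition of Θ₁ = A^{−1/2} B C⁻¹ B′ A^{−1/2} (and Θ₂ for v). KenCoh
estimates the scale matrices from lagged Kendall-τ rank correlations through
the arcsine law λ̂ = sin(πτ̂/2), which is consistent under elliptical
symmetry and robust to heavy tails and outliers. Per-trial canonical
directions are summarized by coordinatewise medians of their magnitudes and
compared across odors with the permutation statistic
T = ‖Û(g) − Û(k)‖₂/P + ‖V̂(g) − V̂(k)‖₂/Q, with SMOTE balancing of
imbalanced odor groups and BH adjustment.

**sDPCA-isolated Granger causality** (`lfpconn.sdpca_gc`): frequency-domain
dynamic PCA summarizes a high-dimensional background network — per-frequency
eigenvectors of the lag-window cross-spectrum are inverse-Fourier
transformed into real time-domain filters whose outputs (dynamic principal
component scores) are regressed out of the two nodes of interest; the
residual pair is tested with the standard restricted-vs-unrestricted Granger
F-test, and per-trial results are voted: an edge is "consistently present"
when significant on at least 99% of trials.

**Spectral transfer entropy** (`lfpconn.ste`): band-filter, take block
maxima of the absolute signal over non-overlapping windows of m samples
(m = 100 at 1000 Hz ⇒ 0.1 s resolution), and estimate the transfer entropy
TE(q→p; k, ℓ) = I(Y_{p,b}; Y_{q,b−1..b−k} | Y_{p,b−1..b−ℓ}) on the pooled
block-maxima tuples — avoiding the temporal-dependence distortion that
filtering induces in causality measures applied to smooth oscillations.
Estimators: Gaussian-copula (rank → normal scores → closed-form Gaussian
CMI; invariant to monotone marginal transforms) and Frenzel–Pompe k-NN.
Significance by permuting whole source trial segments.

**Wavelet coherence** (`lfpconn.wavecoh`): maximal-overlap (non-decimated)
wavelet details per scale and the localized cross-scale coherence
ρ_{jj'}^{(p,q)}(t/T) = |Cov(X_j^p, X_{j'}^q)/√(Var·Var)|² over centered
rolling windows, with a trial-label permutation test for group differences.
The matching generative model (locally stationary wavelet processes with
time-varying transfer functions and cross-scale innovation correlation)
lives in `lfpconn.simulate`.

**Persistent homology** (`lfpconn.tda`): connectivity matrices map to
dissimilarities (1 − C for coherence, 1 − |ρ| for partial correlation);
Vietoris–Rips persistence in dimensions 0 (components, via the minimum
spanning tree) and 1 (loops, via GF(2) boundary reduction); diagrams
compared with the exact order-2 Wasserstein distance under the sup-norm
ground metric and summarized per odor group.

## Worked example

```python
import numpy as np
from lfpconn import simulate, spectral, kencoh, ste

# 6 trials of a 4-channel VAR with a directed proximal->distal coupling
spec = simulate.VARSpec(
    P=4, order=1,
    coeffs=[np.array([[0.3, 0, 0, 0], [0, 0.3, 0, 0],
                      [0.5, 0, 0.2, 0], [0, 0, 0, 0.2]])],
    innov_cov=np.eye(4))
ts = simulate.simulate_var_trials(spec, R=6, T=1000, fs=1000.0, seed=42)

# robust canonical band coherence, proximal (T1,T2) vs distal (T3,T4)
est = kencoh.KenCoh(band=spectral.BANDS["beta"], h_max=3).fit(ts)
print("per-trial CBC phi:", np.round(est.phi_, 3))
print("median |u|:", np.round(kencoh.trial_directions_summary(est.u_).values, 3))

# spectral transfer entropy on an envelope-coupled driver/receiver pair
am = simulate.AMSpec(carrier_freq=20.0, band=spectral.BANDS["beta"],
                     modulator_ar=0.8, coupling_gain=0.8, coupling_delay=1,
                     block_size=100)
pair = simulate.simulate_am_pair(am, R=10, T=1200, fs=1000.0, seed=7)
fwd = ste.spectral_transfer_entropy(pair, "driver", "receiver",
                                    spectral.BANDS["beta"], m=100,
                                    n_perm=199, seed=1)
rev = ste.spectral_transfer_entropy(pair, "receiver", "driver",
                                    spectral.BANDS["beta"], m=100,
                                    n_perm=199, seed=1)
print(f"STE driver->receiver: {fwd.value:.4f} (p = {fwd.p_value:.3f})")
print(f"STE receiver->driver: {rev.value:.4f} (p = {rev.p_value:.3f})")
```

Output:

```
per-trial CBC phi: [0.262 0.526 0.179 0.38  0.232 0.347]
median |u|: [0.97  0.275]
STE driver->receiver: 0.1477 (p = 0.005)
STE receiver->driver: 0.0043 (p = 0.315)
```

The CBC values show moderate beta-band association between the groups, and
the direction summary |u| identifies channel T1 — the channel that actually
drives T3 in the simulation — as the dominant proximal contributor. The STE
contrast recovers the planted envelope coupling: information flows from the
driver to the receiver (p = 0.005, the minimum attainable with 199
permutations) and not in reverse.

## Command line

```sh
lfpconn <simulate|corrtest|coherence|kencoh|gc|ste|wavecoh|tda> \
        --config cfg.yaml --seed 1 --out results/
```

Each subcommand reads a YAML config (see the docstrings in `lfpconn.cli`
for keys), writes CSV tables, and records a run manifest with the seed,
config hash, and library versions.

## Layout

```
src/lfpconn/      core_io, simulate, timedep, spectral, kencoh,
                  sdpca_gc, ste, wavecoh, tda, cli
tests/            pytest suite (unit, property, and end-to-end checks)
docs/methods.md   modelling assumptions, defaults, numerical choices
scripts/          acceptance.py
```
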