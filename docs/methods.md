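# Methods notes

This note records the models behind each estimator, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical decisions taken where the methodology leaves choices open.

## Data model

A `TrialSet` holds an (R, P, T) float64 array — R trials of P channels by T
samples — with a sampling rate in Hz, per-channel region labels
(proximal/distal CA1), and per-trial labels (odor A–E, in/out-of-sequence,
correct/incorrect). Samples are nominally microvolts; no estimator depends
on the absolute scale except where explicitly noted. Per-trial mean removal
is deliberately *not* performed at load time: estimators that assume
zero-mean weakly stationary series demean internally, so the stored data
remain exactly what was recorded or simulated. Time indices are 0-based;
the long CSV format carries an explicit `sample_index` column so the
convention is unambiguous on disk.

The bundled per-subject trial table (tetrode counts and
in/out-of-sequence × correct/incorrect trial counts for five subjects) is a
published summary used for bookkeeping checks and fixture construction; the
underlying recordings are not distributed, which is why every estimator is
validated against simulations instead.

## Synthetic generators

All generators are pure functions of (spec, seed) — bit-identical reruns —
and are the package's substitute for the non-public recordings. They
emulate: band-limited oscillations in the standard rhythm bands, clustered
within-region dependence, directed lagged couplings, amplitude-modulated
carriers, locally stationary (time-varying) spectra, heavy tails, and
outlier contamination. They do **not** emulate biophysics (no conductance
models, no spikes), electrode drift, line noise, or volume conduction;
passing tests demonstrate statistical correctness of the estimators under
the stated models, not robustness to every artifact of real tissue.

* **VAR trials** — stationarity is enforced by requiring the companion
  matrix's spectral radius to be below 1; a burn-in of 10× the order is
  discarded to remove initialization transients. Student-t innovations are
  standardized to unit variance so that robustness comparisons hold the
  variance fixed and differ only in tail weight.
* **Amplitude-modulated pair** — each channel is a narrowband carrier
  (band-pass filtered noise centered on the carrier frequency) multiplied
  by a strictly positive envelope, the exponential of a Gaussian AR(1) held
  constant within blocks of `block_size` samples. The modulating signal's
  family is not prescribed by the methodology; the log-AR(1) envelope was
  chosen because an amplitude must be positive and the exponential of a
  stationary Gaussian is the simplest such process. The receiver's
  log-envelope is the driver's log-envelope lagged by a whole number of
  blocks times `coupling_gain`, plus independent AR(1) noise — exactly the
  structure the block-maxima transfer-entropy pathway targets.
* **Locally stationary wavelet trials** — X(t) = Σ_j Σ_k V_j(k/T) ψ_{j,t−k}
  z_{j,k} with non-decimated synthesis wavelets obtained as impulse
  responses of the inverse stationary wavelet transform, so synthesis and
  analysis use the same (circularly extended) system. Innovations are drawn
  per shift with the stacked scale×channel covariance Q(k/T), allowing
  time-varying cross-scale dependence. Note that lattice-aligned wavelets
  at different scales are orthogonal, so same-shift cross-scale innovation
  correlation expresses itself in the *analysis coefficients* (which is
  what the empirical coherence measures) rather than in raw instantaneous
  products; the Haar family shows the effect most strongly and is used in
  the power studies.
* **Contamination** — point mode replaces each sample independently with
  probability `rate` by value ± `magnitude`·σ(channel); block mode starts
  runs of `block_len` samples at rate/`block_len` so the expected
  contaminated fraction matches. The mask is returned so tests can verify
  exactly which samples were altered.

## Time-domain measures and the permutation test

Cross-covariance uses the biased 1/T normalization: it guarantees a
positive semidefinite lag-0 estimate, which the precision-matrix inversion
requires. Near-singularity is declared at condition number 10¹⁰ — the
methodology only warns about exact collinearity, and a numeric cutoff is
needed in practice.

The two-sample test uses the Welch-type statistic with sample variances
(ddof = 1). When the number of distinct relabelings C(n₁+n₂, n₁) does not
exceed `n_perm`, the null is enumerated exhaustively and
p = #{|t*| ≥ |t_obs|}/total (the observed labeling is one of the
enumeration); otherwise `n_perm` random relabelings are drawn and the
add-one convention p = (1 + #{|t*| ≥ |t_obs|})/(1 + n_perm) avoids p = 0.
Default n_perm = 1000. Comparisons use a relative tolerance of 10⁻¹² so
exact ties in the permuted statistic are counted.

## Spectral measures

Convention: S(ω) = Σ_k Σ(k) e^{−i2πωk} with ω in cycles/sample, reported
in Hz as ω·fs. Band-pass filtering is Butterworth order 4, zero-phase
(forward–backward); order and phase are implementation choices since only
the filter family is named by the methodology. The five rhythm bands map
from generic (ω_L, ω_H) ⊂ (0, 0.5) to Hz by multiplication with fs. The
decomposition weights of the band expansion are treated as 1 throughout —
the filter bank defines the components and no estimator uses the weights.

Two spectral-matrix estimators: the trial-averaged periodogram (refusing
K = 1, where the raw periodogram is inconsistent) and the Bartlett
lag-window smoother with bandwidth M = ⌊√T⌋ by default (window family and
bandwidth are open choices; Bartlett guarantees a positive semidefinite
estimate). Demeaning annihilates the DC bin, so coherence averages skip
grid frequencies whose auto-spectra are numerically zero. Band coherence is
the unweighted mean of per-frequency coherences over grid points in the
band — no weighting is prescribed, and the unweighted mean keeps band
values invariant to grid refinement.

## KenCoh

The lagged Kendall statistic is the signed-pair sum over 1 ≤ t < s ≤ T
normalized by the number of pairs T(T−1)/2, giving range [−1, 1]; ties
contribute sign 0. Under elliptical symmetry, λ = sin(πτ/2) recovers the
correlation-scale entry (arcsine law), so the sine-transformed τ̂ matrix is
a consistent robust scale estimate; the density generator never needs to be
evaluated because the Θ₁/Θ₂ eigenproblem is invariant to the overall scale
proportionality. The fast path is O(T log T) inversion counting; the O(T²)
signed-pair enumeration is kept as the contract and the two agree exactly
on tie-free data (with ties, the fast path normalizes by tie-corrected pair
counts — continuous LFP data are tie-free almost surely).

Numerical choices: symmetric inverse square roots via eigendecomposition
with a relative eigenvalue floor of 10⁻¹⁰·trace (singular blocks raise an
error; no silent regularization); canonical-lag search h ∈ {0,…,5} by
default since the maximization over h states no range; eigenvector signs
fixed by making the largest-magnitude coordinate positive, because
directions are sign-ambiguous and downstream summaries use magnitudes. The
direction summary minimizes the coordinatewise-separable L1 objective over
the nonnegative orthant, whose minimizer is the coordinatewise median of
the absolute per-trial directions. The odor-difference statistic divides
the L2 norms by P and Q (not √P, √Q), exactly as defined. SMOTE (k = 5
neighbors, uniform interpolation) triggers at a group-size ratio above 2:1
— "highly imbalanced" is not quantified anywhere, so the trigger is a
package choice — and is applied once per (re)labeling inside the
permutation loop, so the null distribution sees the same balancing
procedure as the observed statistic.

## sDPCA + Granger causality

The background spectrum is the Bartlett lag-window estimate on the full
frequency circle; eigenvectors are phase-rotated so the largest-magnitude
coordinate is real nonnegative and mirrored conjugate-symmetrically so the
inverse-transform filters are exactly real. Filter half-length L = 30 by
default; components are matched across frequencies by descending eigenvalue
without tracking crossings (a documented limitation — eigenvalue crossings
can mix components between frequencies). The number of components, when not
given, is the smallest count whose eigenvalue mass across frequencies
reaches 90%. Scores trim L samples at each edge (incomplete convolution
support). Partialling out is ordinary least squares on the scores (plus
optional pairwise score interactions, off by default); residual
orthogonality to the design is exact by construction.

The Granger F-test compares nested autoregressions on a common estimation
sample; lag orders are selected by BIC (default) up to `d_max` — first the
target's own order on the restricted model, then the source order on the
unrestricted model. Per-trial significance is α = 0.05, and the voting rule
labels a directed edge consistent when significant on at least 99% of
trials, applied literally to the trial fraction (small trial counts make
the threshold coarse; that is inherent to fraction voting). Null
calibration studies use fixed unit lags: with data-driven lag selection the
pretest inflates the size of the subsequent F-test by a percentage point or
two, which users should keep in mind when interpreting borderline edges.
First differencing for stationarity is offered at the CLI level, not inside
the test.

## Spectral transfer entropy

Defaults m = 100 samples per block (0.1 s at 1000 Hz), k = ℓ = 1 block,
matching the first-order embedding of the definition. Embedded tuples never
straddle trial boundaries and are pooled across trials. The
Gaussian-copula estimator rank-transforms each coordinate to normal scores
(ranks/(n+1) through the normal quantile) and applies the closed-form
Gaussian CMI ½ log(det Σ_XZ det Σ_YZ / (det Σ_Z det Σ_XYZ)); estimates are
clipped below at 0. It is exactly invariant to strictly monotone marginal
transforms up to rank ties. The k-NN path is the Frenzel–Pompe estimator
with Chebyshev metric (k = 5 default). Significance permutes whole source
trial segments across trials — preserving within-trial autocorrelation
under the null — with the add-one convention; n_perm < 19 is rejected
because α = 0.05 cannot be resolved. Inference here is a permutation
surrogate: the copula-model-based inference machinery of the original STE
proposal is intentionally out of scope.

## Wavelet coherence

`modwt_details` returns the maximal-overlap transform coefficients
(PyWavelets' stationary wavelet transform with the energy-preserving
normalization), which are length-preserving per scale and satisfy the
energy identity Σ_j‖D_j‖² + ‖smooth‖² = ‖X‖². Default family is the
least-asymmetric Daubechies with 8 vanishing moments ('sym8'); none is
prescribed. Default J = ⌊log₂T⌋ − 2 keeps boundary effects modest; T must
be a multiple of 2^J.

The localized coherence uses centered boxcar windows of W = 128 samples by
default — the localization of the covariance/variance in the empirical
definition is not specified, and a plain rolling window is the most
transparent choice. Edges with incomplete windows and windows with zero
variance are reported missing (NaN), never zero. The quantity is a squared
magnitude and lies in [0, 1]; the model-side coherence that ranges over
[−1, 1] (unsquared) is a different object and not part of the empirical
contract. At j = j′ the cross-scale formula reduces identically to the
single-scale coherence. The group test statistic is the time-averaged
absolute difference of group-mean trajectories with trial-label
permutation (1000 replicates by default).

## Persistent homology

The connectivity-to-dissimilarity maps are 1 − C for coherence and 1 − |ρ|
for partial correlation; both connectivity measures are bounded by 1, so
the images lie in [0, 1] with zero diagonal. No map is prescribed by the
methodology — this choice is flagged prominently because different monotone
maps reparametrize the filtration scale (though they preserve the ordering
of births and deaths).

Dimension-0 persistence comes from the minimum spanning tree (births 0,
deaths at MST edge weights, one essential class); dimension-1 from standard
boundary-matrix reduction over GF(2) on edges and triangles, simplices
ordered by filtration value with dimension then lexicographic tie-breaks;
zero-persistence pairs are dropped. Directed (asymmetric) inputs are
rejected. Essential classes are excluded from Wasserstein comparisons
(finite costs are required); the distance is order 2 with the sup-norm
ground metric, solved exactly as an assignment problem on the
diagonal-augmented cost matrix. Group summaries average pairwise distances;
a single-trial group's within-group mean is undefined and reported missing,
not zero.

## Problem sizes in the test suite

Monte-Carlo studies in the suite use the smallest sizes that cleanly decide
each property: e.g. 100 seeds at T = 400 for the contamination-robustness
ordering, 500 replicates at T = 300 for Granger size, 100 replicates at
T = 1000 for Granger power, 100 simulations of 8 trials × 1200 samples for
transfer-entropy directionality, and 20 trials per group at T = 1024 for
the wavelet-coherence power study. The acceptance script
(`scripts/acceptance.py`) re-runs the same computations from scratch under
a caller-supplied seed.

## Known limitations

* Stationarity is assumed by everything except the wavelet pathway; the
  toolkit does not test for it.
* Eigenvalue crossings in sDPCA are not tracked across frequencies.
* The fraction-based ≥99% edge vote is coarse for small trial counts.
* The Kendall fast path differs from the signed-pair formula in the
  presence of ties (tie-corrected normalization); use the brute path for
  heavily discretized data.
* Spatial channel coordinates are carried as metadata only; no estimator
  uses them.
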