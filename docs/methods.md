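# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the synthetic benchmark does and does not show.

## Pipeline and preprocessing

The stage order is fixed: CCA-based EOG reduction on the raw recording,
polyphase resampling to 200 Hz, zero-phase 0–45 Hz Butterworth filtering
(order 3, applied forward–backward, so 6th-order magnitude), then contiguous
non-overlapping 3-s windows with the trailing partial window discarded.

**CCA artifact reduction.** Canonical variate pairs are computed between the
centered EEG block and the centered EOG block of the whole session (long
blocks are needed for a stable estimate; per-segment CCA would be badly
conditioned).  The implementation whitens each block via the ridge-
regularized covariance (`C + εI`, ε = 1e−10·trace/d plus an absolute floor)
and takes the SVD of the cross-covariance in whitened coordinates, which
yields a *complete* EEG-side basis: canonical directions beyond the EOG rank
carry zero canonical correlation and are always kept.  EEG components with
canonical correlation ≥ threshold (default 0.5, inclusive boundary with a
1e−9 tolerance absorbing the ridge perturbation) are zeroed and the EEG
reconstructed; at most as many components as there are EOG channels can be
removed.  The correlation-threshold rule (rather than removing a fixed
number of components) is this package's choice and is exposed in the
configuration.  Removal is idempotent up to numerical noise.  Zero-phase
filtering was chosen to avoid phase distortion of the Poincaré and ordinal-
pattern features; non-overlapping windows keep clustering samples
approximately independent.

## Features

All features are computed per 3-s, 600-sample segment at 200 Hz.

**Welch PSD** uses 1-s Hamming windows with 50% overlap (five sub-windows
per segment, 1 Hz resolution).  These parameters are configurable; the
1-s/50% choice balances variance reduction against the short segment.
Relative power uses inclusive band edges on the discrete grid (θ = 4–8 Hz,
β = 12–30 Hz, total band 0–45 Hz, matching the filter passband).  SEF95
returns the first grid frequency at which the cumulative power reaches 95%
of the 0–45 Hz total, without interpolation, normalized by 45 Hz.  Window
leakage can push a pure tone's edge one bin above the tone frequency; tests
account for this.

**Poincaré ratio.** SD1 = (√2/2)·SD(xₙ − xₙ₊τ),
SD2 = √(2·SD(xₙ)² − ½·SD(xₙ − xₙ₊τ)²), τ = 1 sample, sample (n−1) standard
deviations over the n−τ paired points.  A negative SD2 radicand (possible
numerically) is clamped to 0 and flagged; SD2 = 0 raises a degenerate-signal
error.  For an AR(1) process the ratio has the closed form
√((1−φ)/(1+φ)), which the test suite verifies by simulation.  Note the
estimator has an O(10⁻³) positive finite-sample bias at n = 10⁵, well below
its single-run sampling SE.

**Lempel–Ziv complexity.** The segment is binarized by thresholding the
analytic-signal envelope (|Hilbert transform|) at its mean — a scale-
invariant rule — and parsed by the exhaustive-history LZ76 scheme
(Kaspar–Schuster scan).  The normalization is the classic c·log₂(n)/n, which
approaches 1 for i.i.d. fair-coin sequences.  Published clinical values of
"normalized LZC" vary by binarization and normalization convention and are
not directly comparable across toolboxes; the proxy threshold of 0.4 should
be interpreted in this package's convention.

**Imaginary coherency.** Welch cross- and auto-spectra with the same window
scheme; the feature is the mean of |Im C_xy(f)| over θ-band bins.  The
magnitude (rather than the signed imaginary part) is used because the sign
depends on the arbitrary channel ordering; this makes the null distribution
for independent channels positive (≈0.05–0.1 at the default averaging),
which the connectivity tests quantify.

**wSMI.** Each channel is mapped to ordinal patterns of k = 3 samples with
spacing τ; τ is tied to the highest frequency to resolve through
f_max = f_s/(k·τ), giving τ = round(200/(3·8)) = 8 samples (40 ms) for the
θ band.  Ties rank by order of occurrence.  The mutual information over the
joint pattern histogram uses natural logs, normalized by 1/ln(3!) = 1/ln 6,
with weight 0 on identical and on sign-opposed pattern pairs and weight 1
otherwise — the standard convention in the wSMI literature, adopted here
because the weighting function is rarely spelled out in applications.  The
statistic can be slightly negative on finite samples.  Connectivity features
enter the feature matrix as the mean of the strict lower triangle of the
channel-pair matrix.

## Clustering and the NCL

Features are z-scored per session before clustering (FCM is distance-based
and the raw features span different scales); `--no-scale` disables this.
Constant columns are dropped with a warning.

**FCM** is implemented directly: seeded random row-normalized membership
initialization, alternating center/membership updates, stop when the
objective improves by < 1e−5 or after 1000 iterations (m = 2, N = 2).  The
returned centers are recomputed from the final memberships so they satisfy
the center equation exactly.  A point coincident with a center receives
membership 1 there.  **GMM** uses scikit-learn's full-covariance
`GaussianMixture` (tol 1e−5, max 1000 iterations, reg_covar 1e−6, 5
initializations, seeded); posteriors serve as memberships, and the
log-likelihood trace is exposed by re-running EM one step at a time from the
fitted solution.

**Conscious-cluster labeling** is a majority vote over all seven features,
each voting for the cluster with the larger centroid in original units
(centroids are mapped back through the stored scaling).  With seven voting
features a tie requires exact centroid equality and is broken by the larger
SEF95.  The SEF95 premise ("above the α band") is implemented as a plain
greater-than comparison between centroids.  The two methods are labeled
independently; no cross-method cluster matching is attempted.  The per-
segment NCL is the literal product of the two conscious memberships, not
renormalized (an optional flag renormalizes by the sum of the
conscious·conscious and unconscious·unconscious products for sensitivity
analysis).  Clustering is fit independently per session.

**Cluster-count check.** `choose_k_chi` hardens memberships by arg-max and
scans the Calinski–Harabasz index over k = 2…6 for both methods.

## Evaluation

PC ∈ [1/c, 1] and PE ∈ [0, 1]; PE uses the base-c logarithm by default
because only that base makes the [0, 1] range exact (a natural-log option is
retained).  Proxy scoring applies strict `>` to five thresholds
(RP_θ 0.07, SEF95 8/45 on the normalized scale, LZC 0.4, iCOH 0.14,
wSMI 0.088); RP_β and ERR have no published reference values and are
excluded.  Spearman correlations are tie-corrected; p-values use the
t-approximation for n > 10 and exact full-enumeration permutation for
n ≤ 10.

## Synthetic data

The generator is the package's test bed, not a head model.  State A
("conscious-like") is weakly autocorrelated AR(1) noise (φ = 0.3, innovation
SD 10 µV) plus a narrowband ~20 Hz source (8 µV RMS, 4 Hz bandwidth)
propagated across EEG channels with a 6-sample lag; state B
("unconscious-like") is a strong ~3.5 Hz oscillation (30 µV RMS) on heavily
smoothed AR(1) noise (φ = 0.95, SD 4 µV), independent across channels.
These defaults were chosen so that the state contrast moves β power,
spectral edge, complexity and the Poincaré ratio in the expected directions
at realistic resting-EEG amplitudes; they are deliberately strong enough
that the two states are separable — the benchmark tests the pipeline's
correctness, not its sensitivity limit.  Sessions default to eight
alternating 30-s blocks (80 segments) at 500 Hz with 6 EEG + 2 EOG channels.
Blinks are a Poisson train (6/min) of raised-cosine bumps (0.3–1.0 s,
~80 µV) added to the EOG channels and leaked into the EEG through a
per-channel mixing vector.

What passing tests therefore show: every stage implements its definition
correctly and the ensemble recovers a planted, well-separated two-state
structure.  What they do not show: performance on real patient EEG, where
state contrasts are weaker and drift, artifacts are not purely ocular, and
the two-state assumption itself is an approximation.  Note that in state B
the slow oscillation raises θ-band relative power above state A's, so the
θ-power premise votes against the planted conscious state here; the majority
vote is robust to this, which is exactly why a single-feature rule is not
used.

## Numerical conventions and limitations

* Determinism: every stochastic step (generator, blink train, FCM/GMM
  initialization) is driven by explicit seeds; identical configuration gives
  byte-identical outputs.
* Degenerate inputs raise typed errors (constant signals, zero total power,
  identical centroids, all-identical points) rather than returning NaNs;
  segments with any failed feature are dropped from the feature matrix with
  a log entry.
* EDF output is 16-bit with per-channel physical scaling over the observed
  range (quantization ≤ range/65535); records are 1 s, trailing partial
  seconds are dropped.  Reading goes through MNE.
* The pipeline assumes two latent states; more states, streaming operation
  and directed connectivity measures are out of scope.
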