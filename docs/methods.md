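# Methods

## Signal model of the synthetic generator

Each EMG channel is generated as

    x(t) = g_c · e(terrain, muscle, φ(t)) · n_band(t)
           + a_0 · n_band'(t) + powerline(t) + artifact(t)

where φ(t) ∈ [0, 1) is the phase fraction of the current gait cycle
(0 at heel strike), `e` is a sum of Gaussian bumps in phase coordinates
(periodic by wrapped distance), `n_band` is unit-variance Gaussian noise
band-passed to 20–150 Hz, `g_c` is a per-cycle lognormal-like gain
jitter (CV 10%), `a_0` the additive baseline-noise amplitude, the
powerline term a 50 Hz sinusoid with geometrically decaying harmonics,
and the artifact a random walk low-passed below 10 Hz. This is the
standard amplitude-modulated-carrier abstraction of surface EMG: it
reproduces what the downstream pipeline actually consumes (per-window
band-limited amplitude structure that differs by muscle, phase and
terrain) without modeling motor-unit physiology, electrode crosstalk or
conduction-velocity effects.

Default study conditions: three terrains × five muscles with distinct
envelope placements (TA at heel strike and swing clearance, MG at
push-off, RF/VL in loading response and strongly on stairs, ES biphasic
at the support transitions); cycle duration 1.1 s with 5% CV; stance
fraction 0.60 / 0.62 / 0.58 for level ground / stair ascent / stair
descent; EMG at 1926 Hz; pressure at 148 Hz; baseline noise 0.05,
powerline 0.10, artifact 0.20 in units where envelope peaks are ≈ 1.
Values the protocol did not pin down (stance fractions, cadence, bump
geometry, interference levels) were chosen once from typical adult-gait
and sEMG-quality figures and are not tuned thereafter.

Foot-pressure traces load the heel from HS to heel-off and the toe from
toe-strike to TO, with 10-ms smoothstep transitions; the heel onset
begins exactly at HS and the toe unloading ends exactly at TO, so
threshold-crossing detection has a known sub-sample bias (≈2 ms, well
inside one native 148 Hz sample).

A cohort of "virtual subjects" shares envelope geometry but differs in
per-muscle gain (±15% lognormal) and in all noise seeds — enough
between-subject variability to make across-subject robustness (STN)
statistics nondegenerate. The default cohort is three subjects with 40
cycles per terrain (~468 windows each), a deliberate desk-scale size:
a full `scripts/acceptance.py` run finishes in well under a minute on
one core.

All outputs are pure functions of the configuration seed; substreams
(per terrain, per channel, interference, tie-breaking, folds) are drawn
from `numpy` Generators seeded from it.

## Preprocessing choices

* Resampling: polyphase (rational-ratio) anti-aliased resampling to
  500 Hz; output length is round(n·ratio), equal-rate input passes
  through untouched.
* Band-pass: 4th-order Butterworth, 10–150 Hz, applied
  forward-backward (zero phase) so event-anchored windows stay aligned;
  notches: IIR, Q = 30, at 50/100/150 Hz (the in-band powerline
  harmonics).
* Wavelet denoising: db4, 4 levels, periodized (orthonormal) transform.
  Two actions: the level-4 approximation (≈ 0–15.6 Hz) is subtracted as
  the motion-artifact estimate, and detail coefficients are
  soft-thresholded at the universal threshold σ√(2 ln n), σ from the
  median absolute deviation of the finest detail / 0.6745. Soft
  thresholding alone cannot remove a step-like artifact (a step lives in
  large approximation coefficients that thresholding keeps), which is
  why the approximation is dropped; orthonormality makes the
  energy-non-increase guarantee exact. On broadband noise-like input the
  universal threshold is aggressive, but it is shrinkage by a constant:
  relative amplitude structure across windows — what the classifier
  uses — survives.
* Event detection: hysteresis thresholds at 10%/20% of per-channel peak
  pressure; HS = validated upward crossing of the low threshold on the
  heel channel, TO = downward crossing on the toe channel after loading.
  Alternation is enforced by keeping the last TO inside each HS–HS
  interval.
* Windows: half-open [start, start + 0.2 s), sample index floor(t·500);
  Post_TO and Pre_HC may overlap in short swings and both are kept,
  drawn from the continuous recording; windows that would leave the
  recording are dropped with a log entry.

## Feature conventions

* WAMP threshold: 5% of the per-channel RMS pooled over the feature
  matrix's windows (amplitude-robust); ZC/SSC thresholds 0; all three
  configurable.
* AR1–AR4: Yule-Walker on biased autocovariances, prediction convention
  x_t = Σ a_k x_{t−k} + e_t; constant windows return zeros.
* Spectra: Hann-tapered periodogram of the 100-sample window (5 Hz
  bins); MDF is the first bin where cumulative power reaches half the
  total; PR splits at 75 Hz (passband midpoint); degenerate all-zero
  windows return zeros by convention. LogVAR uses ε = 1e−12.
* DWT: symmetric extension, 3 levels (db7 supports 2 clean levels on
  100 samples; cD1/cD2, the only featurized bands, are identical either
  way); cA3/cD3 are computed but never featurized.

## Selection conventions

Indices are computed on the 5-channel value vector of each feature
(Euclidean geometry in muscle space), per subject, with L = 12 classes.
Davies-Bouldin dispersion D_ii is the mean distance of class members to
their centroid; the scattering index weights class covariances by class
size; RES runs over ordered pairs (matching its 1/(L(L−1))
normalizer) with the scalar class spread δ_ii = √(mean per-channel
variance). Degenerate geometry (coincident centroids with spread, zero
between-class trace) yields +inf sentinels rather than exceptions.
Ranking is by mean invRES ascending with STN as tie-breaker; DB and J
are reported but not used for ranking. The pinned six-feature reference
set (MAV, WL, RMS, Db1-cD2-MAV, Db1-cD1-WL, Db1-cD2-WL) is available as
an alternative to the data-driven ranking; on synthetic data the
ranking itself tends to favor WAMP-family features, a reminder that the
generator's amplitude statistics are not real sEMG.

## Classification and evaluation

Base classifiers: LDA (least-squares solver, automatic shrinkage) and
RBF-SVM (C = 1, γ = 1/(d·var)); hyperparameters deliberately ordinary,
configurable. Voting ties are broken uniformly at random from the tied
set using a seeded generator. Weighted voting's W entries are held-out
per-class recalls from a 5-fold stratified cross-training inside the
training partition; with uniform W the weighted rule reduces exactly to
plurality voting. LightGBM: 200 trees, 31 leaves, learning rate 0.1,
single-threaded deterministic mode.

Evaluation pools the held-out predictions of a stratified 5-fold split
into one confusion matrix; "overall" accuracy is its trace over its
total (identical to pooled-prediction accuracy by construction).
Macro-F1 is the harmonic mean of macro-averaged precision and recall —
not the mean of per-class F1 scores; classes never predicted contribute
precision 0, classes with no true members are excluded with L adjusted.
Wall-clock train/predict times are reported for completeness but are
hardware-dependent and not treated as results.

## What passing tests do and do not show

The synthetic benchmark demonstrates that the pipeline is *correct*:
features match independent brute-force oracles, indices match textbook
formulas, the weight estimator is exact against realized recalls, the
end-to-end system separates classes that are separable by construction
(LightGBM ≥ 0.90 accuracy on the default cohort, ≈ 0.98 in practice)
and collapses to chance (1/12) when labels carry no information. It
does not show that real sEMG would reach these accuracies: the
generator has no crosstalk, no electrode lift, no fatigue drift, no
inter-session variability, and its class structure is exactly the
amplitude structure the features measure. With additive noise removed,
accuracy is still bounded slightly below 1 by the stochastic carrier's
own amplitude variance (≈ 0.98–0.99 at 24 cycles/terrain) — the
noiseless regression test asserts ≥ 0.95. Published per-subject
accuracies from the four-participant study are stored as reference
data for arithmetic cross-checks only; they are not reproducible
because the recordings were never deposited.

## Degenerate inputs and numerical conventions

Constant windows: LogVAR = ln ε, AR = 0, count features 0. All-zero
spectra: spectral features 0, PR = 0. Empty or single-HS event series:
no cycles, no exception. All-zero pressure: empty event series with a
warning. Cycles without a unique interior TO are dropped and counted.
Oracle-equivalence tolerances are 1e−9 relative (features) and 1e−12
relative (indices, macro-F1); these reflect floating-point accumulation
order only.
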