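# Methods

`lfplocal` asks one question of a multichannel extracellular recording: is a
band-limited LFP oscillation (the running example throughout is theta,
6–10 Hz, around a nominal 8 Hz peak) generated by the tissue around the
electrodes, or is it a distant generator's field reaching the probe by
passive volume conduction? Because conduction through tissue is effectively
instantaneous at these frequencies, the two hypotheses leave different
fingerprints, and the package quantifies three of them plus a
spiking-entrainment side channel.

## Signal model

The synthetic generator (`lfplocal.simgen`) formalizes the recording model
the analyses are designed against:

```
x_c(t) = sum_k  G[c,k] * a_k(t) * s_k(t)   +  (coupling contribution)  +  n_c(t)
```

* `s_k`: distant sources, each either a narrowband AR(2) oscillator or
  broadband white noise, unit stationary variance.
* `a_k(t)`: a per-epoch step envelope — `amplitude_run` inside run epochs,
  `amplitude_baseline` elsewhere. No ramps: the run/baseline contrast of the
  task is modeled as the simplest amplitude step.
* `G`: an instantaneous, real gain matrix (`MixingMap`). Volume conduction is
  *defined* as a column of `G` with several nonzero entries and no lags. No
  biophysical forward model (dipole geometry, conductivity tensors) is
  attempted.
* coupling: under the `lagged_coupling`/`mixed` scenarios a stable VAR
  (`CouplingSpec`, companion-matrix spectral radius < 1 enforced) provides a
  *lagged, directed* interaction between latent "cortex" and "striatum"
  signals; `coupling_gains` maps the latents onto channels. The latent
  amplitudes are normalized analytically by integrating the closed-form VAR
  spectrum, so channel SNR is controlled by the gain vectors, not by the
  resonance sharpness.
* `n_c`: independent white Gaussian noise per channel, SD `noise_std`
  (default 0.3 against unit-variance sources). The source papers in this
  area rarely quantify in-band SNR; this default puts the theta peak roughly
  1.5–2 orders of magnitude above the whitened noise floor during running,
  which is what prominent task-modulated theta looks like.

AR(2) sources place the complex pole pair at angle `2*pi*f0/fs` with modulus
`r = exp(-pi*bw/fs)`, so `bw` approximates the −3 dB width; innovations are
scaled by the closed-form stationary variance so that "amplitude" means the
stationary SD. An AR(2) was preferred over a sinusoid because real theta has
finite bandwidth, and several contracts (coherence < 1, peak/flank ratios)
are only meaningful with a stochastic peak.

Spike trains are inhomogeneous Poisson with intensity
`lambda(t) = r0 * exp(kappa*cos(phi(t) - theta)) / I0(kappa)`, sampled by
Lewis–Shedler thinning under the envelope `r0*exp(kappa)/I0(kappa)`. The
marginal mean rate is `r0` when the phase is uniform. Phase convention
(everywhere in the package): degrees, 0° at the oscillation peak, increasing
in time, reported in (−180°, 180°].

Determinism: every generator consumes a `numpy` `SeedSequence`-derived
child seed; the same config (including seed) reproduces a session
bit-identically, also across the numba-compiled VAR recursion.

## Preprocessing

Downsampling uses a zero-phase FIR low-pass at `0.4 * target_fs` followed by
integer decimation (the filter is unnamed in the source literature; a
Hamming-window FIR of order `16*factor` comfortably meets the <1% aliased
power contract). Band-pass (default 0.1–250 Hz, Butterworth order 4) and
mains notches (Q = 30 at every multiple of 50 Hz below Nyquist) are applied
forward–backward, so passband tones keep their timing to the sample.

Artifact screening is automated (the original procedure was visual): each
epoch × channel variance is z-scored across epochs per channel, and an epoch
is flagged when any channel exceeds `|z| > 4` (threshold in config;
per-epoch, not per-channel, rejection). Epoching from a trial table keeps
correct trials longer than 7 s, takes the run epoch as the 5 s before
stop-area entry, and the baseline as the 5 s immediately preceding trial
start — the latest admissible window inside the preceding intertrial, which
is the only placement the source description pins down.

Rereferencing: *bipolar* subtracts the mean of a reference shank from every
channel of a target shank; *common average* subtracts the across-shank mean
of per-shank mean traces. Both are linear, cancel exactly any equal-gain
common signal, and CAR is idempotent.

## Spectral estimation

Multitaper estimation (DPSS tapers) with two smoothing semantics:

* `fixed_bandwidth`: one taper family, half-bandwidth `W` Hz (`K <= 2NW-1`
  enforced), zero-padded FFT, nearest-bin lookup onto the analysis grid
  (default 1–20 Hz in 0.2 Hz steps — 96 points). One-sided density
  normalization: the integral of a white-noise PSD over [0, fs/2] equals the
  variance.
* `proportional`: half-bandwidth `W(f) = 0.8*f` with a fixed taper count
  (7), realized as a per-frequency DPSS family on the full epoch whose
  single-bin tapered DFT is evaluated at that frequency. This mimics the
  frequency-proportional smoothing used for display spectra in the LFP
  literature; its heavy smoothing at higher frequencies is intentional and
  the reason sharp quantities (peak frequency, the factorization input) are
  computed in fixed mode. When `K > 2NW-1` at the lowest grid frequencies
  the extra tapers are poorly concentrated; they are accepted (toolbox
  behavior) and only matter below ~1 Hz.

The grid-resolution guard rejects epochs shorter than `1/(2*f_step)` —
zero-padding interpolates up to twice the Rayleigh resolution, beyond that
the grid is cosmetic.

"Whitening" multiplies power by `f²` to flatten the ~1/f² LFP background; it
is exactly invertible on the stored grid.

The cross-spectral matrix averages `X_i(f) conj(X_j(f))` over epochs ×
tapers; its diagonal reproduces the PSD to ~1e-10 relative. For the
factorization path it is computed on the complete uniform FFT grid spanning
[0, fs/2], oversampled 4× by zero-padding: the minimum-phase factor of an
*estimated* (rough) spectrum carries energy at long lags, and without the
oversampling the factorization stalls at a ~1e-5 truncation floor.

## Coherency and the zero-lag diagnostic

`C_ij(f) = S_ij / sqrt(S_ii S_jj)`; modulus = coherence, argument =
coherence angle, imaginary part = imaginary coherence. Instantaneous real
mixing of one source keeps the coherency on the real axis, so
`(coherence high, Im C ≈ 0, angle ≈ 0)` within a structure is the
volume-conduction fingerprint; a transmission delay `d` instead rotates the
coherency by `2*pi*f*d`. Frequencies with zero power are flagged undefined
(NaN), never silently zeroed. Band summaries are plain means over the band;
angles near zero make the circular/arithmetic distinction immaterial here.

## Nonparametric spectral Granger causality

Wilson's iterative factorization splits the cross-spectral matrix into
`S = H Σ H*` with `H` minimum-phase, without fitting an autoregression.
Implementation notes:

* input converted to the discrete-time spectrum convention so that `Σ` comes
  out in sample-variance units and is directly comparable to a generating
  VAR's innovation covariance;
* initialization from the upper Cholesky factor of the lag-zero
  autocovariance; the plus-operator halves the zero lag and keeps its upper
  triangle (pinning the orthogonal ambiguity of the minimum-phase factor);
* stopping: relative update < 1e-9, at most 1000 iterations; if the update
  enters a strict limit cycle first (common within a few hundred iterations
  on estimated spectra), the fixed point is accepted only when the
  reconstruction residual `max_f ||S - HΣH*|| / max_f ||S||` is below
  `resid_tol` (1e-6 by default);
* optional diagonal loading (`ridge`): band-stop filtered data (notches,
  anti-alias stopbands) have near-singular spectral nulls that stall the
  iteration; the session pipeline loads `1e-6 × mean channel power` onto the
  diagonal and accepts residuals up to 1e-5, which is orders of magnitude
  below anything band-integrated shares can feel.

Geweke's measures for a pair (x, y):
`f_y→x = ln[S_xx / (S_xx − (Σ_yy − Σ_xy²/Σ_xx)|H_xy|²)]` (and symmetrically),
`f_total = −ln(1 − |C_xy|²)`, and the instantaneous term as the residual
`f_inst = f_total − f_x→y − f_y→x`, so the decomposition identity holds
pointwise to machine precision by construction. Two consequences are
documented rather than hidden: `f_total` is infinite where coherence hits 1
(flagged, excluded from band summaries), and the residual-defined
instantaneous term can dip genuinely below zero at off-peak frequencies on
estimated spectra — only numerical negatives in (−1e-8, 0) are clipped;
larger ones are kept (clipping them would break the identity) and logged.
Band reports integrate each component over the band and normalize by the
integrated total, so shares sum to 1.

A closed-form parametric reference (`parametric_geweke`: transfer matrix
`(I − Σ_k A_k e^{−2πifk/fs})^{-1}` from the true coefficients) provides the
independent oracle the estimator is tested against.

## Spike–LFP entrainment

Phases are read from the band-passed (Butterworth order 3, zero-phase)
analytic signal, unwrapped, linearly interpolated at spike times, and
wrapped back. The default bandwidth is 4 Hz at 8 Hz and scales
proportionally (`f/2`) across the 1–20 Hz grid; the clean-source recovery
benchmark widens it to 12 Hz so that extraction jitter (which attenuates the
apparent concentration multiplicatively) is negligible.

Statistics per unit: Rayleigh test (small-sample-corrected `Z = n R̄²`, via
pingouin — the same formula as the circular-statistics toolbox tradition),
PPC through the O(N) identity
`((Σcos)² + (Σsin)² − N)/(N(N−1))` (unbiased, range `[−1/(N−1), 1]`, and
with analytic von Mises expectation `(I₁(κ)/I₀(κ))²` used as a test
oracle), and a von Mises fit: circular-mean preferred phase plus κ from
inverting `I₁(κ)/I₀(κ) = R̄` by bracketed root finding (the MLE; capped at
1e3 with a flag for degenerate samples).

Classification: units with fewer than 20 spikes are excluded;
`theta_specific` requires Rayleigh p < 0.01 somewhere in 6–10 Hz *and* a PPC
maximum within one grid step of 8 Hz (slow-rhythm-locked cells reach
Rayleigh significance at theta without that specificity); a significant PPC
maximum below 6 Hz is `low_freq_modulated`; everything else
`not_modulated`. The "low" boundary at the lower theta edge is a package
decision — the distinction is qualitative in the source literature.

## Condition statistics

Run vs baseline contrasts use a one-sided paired Wilcoxon signed-rank test
per frequency (zeros dropped, exact null for small n, continuity-corrected
normal otherwise) corrected by Benjamini–Hochberg at q = 0.05. BH rather
than BY: the frequency-wise statistics are positively dependent at worst,
which BH tolerates in practice and which matches common usage of "FDR
correction" in this literature. Note the signed-rank test is invariant under
positive affine maps of the data but *not* under arbitrary monotone maps.

## The verdict

Three branch summaries, each with an explicit threshold (config):

1. rereferencing attenuation — whitened theta peak/flank ratio after bipolar
   and after CAR, each divided by the monopolar ratio; branch passes if the
   worse (larger) of the two is below `r_max = 0.2`;
2. within-structure `|Im C|` band mean below `i_max = 0.05`;
3. cross-structure instantaneous Granger share above `s_min = 0.8`.

All three passing → `volume_conducted`; exactly one failing → `mixed`; two
or more failing → `locally_generated`; any branch missing → verdict
withheld with a partial report. The source work draws this conclusion
qualitatively; the numeric rule (and its thresholds) is this package's
formalization and is labeled as such in the report. The peak/flank ratio
uses sidebands 2–4 Hz outside the theta band edges so that proportional
smoothing does not leak the peak into its own reference.

## Problem sizes used by the benchmarks

* VC coherency null: 200 five-second epochs at 250 Hz, gains 1.0/0.7, noise
  SD 0.2.
* Granger oracle: the classic two-resonance VAR(2) (own-coefficients 0.55,
  −0.8; drive 0.2 at lag 1; unit innovations) at fs 200 Hz, 400 epochs of
  4096 samples, W = 0.195 Hz, 7 tapers. Long epochs keep multitaper
  smoothing bias at the GC peak near 2%.
* von Mises recovery: ~1e4 spikes over 600 s against a clean 8 Hz source;
  PPC expectation checked with 200 × 500-spike Monte-Carlo draws.
* Calibration: 1e4 repetitions (100 spikes each) for Rayleigh; 1e4 × 96
  uniform p-values for BH. Under the global null E[FDP] equals q exactly,
  so the BH check compares the Monte-Carlo mean to q within 3 binomial
  standard errors — a tighter bound would reject a correct procedure half
  the time.
* Scenario battery: 20 volume-conduction + 20 lagged-coupling sessions of
  10 trials each (fs 1250 Hz, 5-s epochs), analyzed with a 0.5 Hz display
  grid and a 2 Hz spike grid for speed; verdict scored against ground truth
  (a lagged session counts as correct when *not* called volume-conducted).

## What passing does and does not show

The generator's mixing is exactly instantaneous and its local noise exactly
independent, so the zero-lag fingerprints are cleaner than any real
recording's; passing the battery shows the *inference machinery* is
consistent, not that real striatal theta is volume-conducted. Real data adds
spatially correlated noise, nonstationary amplitudes within epochs,
spike-sorting contamination, and reference-electrode activity — none of
which are modeled. Phase-shifted multi-generator fields (which can produce
nonzero imaginary coherence *without* genuine coupling) are representable
via `mixed` scenarios but are not part of the battery.

## Known limitations

* Bivariate Granger only; no conditional/multivariate or time-varying GC.
* No weighted phase-lag index or debiased coherency variants (extension
  point in `connectivity`).
* The proportional-smoothing semantics (fixed 5-s window, per-frequency
  bandwidth) is one of several readings of "0.8·f smoothing with seven
  tapers"; a cycle-proportional sliding window would give sharper
  high-frequency estimates.
* Artifact rejection is variance-based only; a channel exclude-list stands
  in for faulty-channel curation.
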