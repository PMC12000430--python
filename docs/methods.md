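# Methods

This note documents the models, parameter choices, numerical details
and validation design behind `ctxstn`, in the spirit of the methods
documentation of packages like statsmodels or mne: what each procedure
assumes, which knobs matter, and what the synthetic studies do and do
not demonstrate about real recordings.

## Signal model and preprocessing

Recordings are multichannel voltage traces (µV) from two sites: a
cortical ECoG strip and an STN DBS lead, under one of three conditions
(`off`, `levodopa`, `dbs`). The cleaning chain is:

1. **Notch** at the line frequency and all harmonics below Nyquist:
   zero-phase (forward–backward) IIR notches, Q = 35 per harmonic. The
   filter design is ours; the contract is ≥40 dB steady-state
   attenuation at each harmonic with <1 dB passband ripple, asserted
   spectrally in the tests (edge transients of the forward–backward pass
   are excluded from the measurement).
2. **Bandpass** 3–150 Hz: 4th-order Butterworth, `sosfiltfilt`
   (zero phase, effective 8th order). ≥40 dB below `lo/2` and above
   `2·hi`; verified by periodogram on white noise.
3. **Epoching** into non-overlapping 2 s windows starting at sample 0;
   the trailing partial epoch is discarded.
4. **Resampling** with `scipy.signal.resample_poly` (polyphase FIR
   anti-aliasing): 500 Hz for spectral/coupling analyses, 1000 Hz for
   the delay analysis, applied after epoching so per-epoch sample
   counts are exact.
5. **Artifact-epoch rejection** replaces visual inspection: per
   channel, the peak-to-peak amplitude of each epoch is z-scored across
   epochs; an epoch is dropped if any channel exceeds `z_thresh`
   (default 4.0). Zero-variance channels are guarded (z = 0). This is
   an automated surrogate, config-exposed; it will not reproduce a
   human marker's judgements.
6. **DBS artifact removal** (below).
7. **Bipolar referencing** of adjacent contacts per site (adjacency =
   order of appearance, i.e. physical contact order), used for power,
   SSD and delay analyses; coupling analyses use the unipolar data
   because ImCoh and net Granger scores are themselves insensitive to
   the common reference.
8. **Bootstrap length standardisation**: 30 kept epochs drawn uniformly
   with replacement per segment, 200 segments (400 for the delay
   analysis). Sampling with replacement does not guarantee full
   coverage of the recording, so the realised coverage fraction is
   reported, not enforced.

### DBS artifact removal (period-based template subtraction)

The stimulation artifact is periodic at the (unknown, near-nominal)
period `fs/f_stim`. The period is estimated by a coarse-then-fine grid
search (±0.05 samples, then ±0.002) maximising the energy captured by a
period-locked template; the template itself is expressed in a truncated
harmonic basis — cosines and sines at all multiples of the artifact
frequency below Nyquist — fitted by least squares over the recording
and subtracted per channel.

The harmonic basis is the fine-bin limit of period-phase bin averaging,
but it remains well behaved when the stimulation period is commensurate
with the sampling grid. That case is not hypothetical: 130 Hz at 4 kHz
gives a period of exactly 400/13 samples, so each phase bin maps to a
single residue class modulo 400 samples and literal bin averaging
absorbs genuine neural oscillations (a 20 Hz test sine loses ~28 dB)
while reconstructing the artifact poorly. With the harmonic basis the
pure-train residual is at numerical precision and a 20 Hz neural sine
is untouched (<0.01 dB).

Two guards: (i) recordings whose condition is not `dbs` are returned
unchanged; (ii) each harmonic is subtracted only if its fitted
amplitude clears a χ²-based noise floor (amplitude² > 20 × 4σ̂²/n), so
artifact-free input passes through essentially unchanged instead of
losing noise-fitted harmonic energy.

## Power and SSD

PSD and CSD share one tapered-FFT layer: dpss tapers with
time-bandwidth product NW = T·(bandwidth/2) and K = ⌊2NW⌋ − 1 tapers
("5 Hz bandwidth" is read as the full smoothing width, so 2 s epochs
give NW = 5, K = 9; the convention is config-exposed). Epochs are
demeaned before tapering; one-sided density scaling satisfies Parseval
(∫PSD df = variance, verified to 5% on sine fixtures). Per-epoch taper
coefficients are cached so the 200/400 bootstrap-segment CSDs and
bispectra reuse a single FFT pass — this is what keeps the bootstrap
loops fast. mne's `psd_array_multitaper` serves as an independent
cross-check in the tests (same tapers; mne additionally weights tapers
by concentration eigenvalue, so per-bin agreement is ~10%, integrated
power ~1%).

Percent-total normalisation: every bin is scaled by
100 / Σ(raw power over 5–60 Hz, excluding 45–55 Hz, boundaries
inclusive), per channel; the 5–95 Hz range is available as an
alternative. Band averages are arithmetic means over inclusive band
edges; canonical bands are θ 4–8, µ/α 8–12, low-β 12–20, high-β 20–30,
γ 30–90 Hz.

**Rank normalisation.** Before multivariate analyses each site is
projected onto a fixed number of principal components (SVD of the
channel-demeaned data): bipolar cortex 4, bipolar STN 3, unipolar
cortex 5, unipolar STN 3 — equalising dimensionality across recordings.
The projection matrix is retained to map component-space patterns back
to channels. Component signs follow a largest-weight-positive
convention so results are reproducible bit for bit.

**SSD.** Signal covariance from band-filtered data; noise covariance
from the flanking strips, realised as bandpass (lo−1, hi+1) followed by
bandstop (lo, hi) (4th-order Butterworth each, zero-phase). Both
covariances are divided by their filter cascades' equivalent noise
bandwidths (∫|H|⁴df for a forward–backward cascade), so the generalised
eigenvalues are per-Hz SNR ratios with the convenient calibration that
white noise gives eigenvalues ≈1; this normalisation is free in the SSD
formulation and does not affect the filters. `scipy.linalg.eigh` solves
the generalised problem; a ridge (1e-8 × trace/n, logged in the model
object) is added when the noise covariance is near singular.
Eigenvalues are sorted descending with the same sign convention as
above; patterns are `C_s W (Wᵀ C_s W)⁻¹`, absolute values Z-scored
across channels within each component (whether Z-scoring is within
component or across a cohort map is not determined by the study design
we mirror; within-component is implemented). The strongest component's
spectrum comes from applying its filter to band-filtered epochs and
running the multitaper PSD.

## Coupling

All coupling estimators consume the multitaper CSD (Hermitian by
construction) and are averaged across bootstrap segments; per-segment
CSDs are weighted averages of cached per-epoch cross-products.

**ImCoh (grand average).** Coherency `C_ij = S_ij/√(S_ii S_jj)`;
`|Im C_ij|` is averaged over all seed–target pairs. The absolute value
is taken per pair *before* averaging (the alternative — average first —
is a flag), because phase-angle signs are not of interest and mixed
signs would cancel.

**MIC.** Per frequency, seed and target blocks are whitened by the
inverse square roots of the real parts of their auto-blocks
(eigendecomposition; ridge 1e-8 × trace/n when near-singular, recorded
in the result's metadata); the largest singular value of the whitened
imaginary cross-block is the MIC and is bounded by 1. Singular vectors
back-transform to spatial filters; patterns are the real auto-block
times the filter, absolute, Z-scored across channels (after optional
back-projection through the rank-normalisation matrix).

**Spectral Granger causality and time reversal.** The autocovariance
sequence Γ₀…Γ_p is the inverse Fourier transform of the two-sided CSD
(the one-sided doubling is undone first; the CSD must sit on the full
uniform rfft grid). VAR coefficients solve the block Yule–Walker system
directly (dense solve of the mp × mp block-Toeplitz system; p = 60,
m ≤ 8 keeps this cheap and avoids the transposition pitfalls of
recursive Levinson implementations); the innovation covariance is
symmetrised and must be positive definite, otherwise the fit fails
loudly with condition diagnostics. Geweke's spectral GC uses the
transfer function H(f) = (I − ΣA_k e^{-2πifk/fs})⁻¹ and the partialised
innovation covariance Σ_yy − Σ_yx Σ_xx⁻¹ Σ_xy. Net scores are
GC(seed→target) − GC(target→seed); time reversal transposes every Γ_k,
the model is refitted, and the reversed net score subtracted. Exchanging
seed and target negates the result exactly (same fitted models), which
the tests assert at 1e-10. GC is evaluated on 3–50 Hz for statistics.
The closed-form VAR spectrum (`synth.var_csd`) provides the independent
oracle: fitting the analytic CSD of a known VAR recovers its
coefficients and its GC spectrum to <2%, and the frequency-averaged GC
equals the Geweke time-domain quantity computed by an independent scalar
Levinson recursion.

An important numerical fact, verified analytically in the tests: for a
purely real CSD (instantaneous mixing), TRGC is *exactly* zero, while
the uncorrected net score is not (it picks up SNR asymmetries between
channels). On finite data the TRGC of mixed signals fluctuates with a
variance that grows with coherence — see "zero-lag immunity" below for
how the null is therefore constructed.

## Bispectral time-delay estimation

Fourier coefficients: Hamming window, 4001-point transforms of 2 s
epochs at 1000 Hz, so delay estimates live on a ±2000 ms grid at 1 ms
steps. The cross-bispectrum slot convention is recorded in the output
metadata: `B_kmn(f₁,f₂) = ⟨k(f₁) m(f₂) n*(f₁+f₂)⟩` with the channel
letters naming the slots; the delay estimator uses `B_xxx` (seed
auto) and `B_yxx` (target at f₁). For `y(t) = x(t−τ)` the phase
difference φ_xxx − φ_yxx equals `2πf₁τ`, so the unit-modulus
phase-difference matrix is collapsed over f₂ and inverse-transformed
over f₁ (with Hermitian symmetrisation, making s(τ) real to numerical
precision). Estimation is restricted to the broadband 3–100 Hz region
(band-restricted delay estimates are deliberately out of scope). No
antisymmetrisation of the bispectrum is applied. The strength function's
units are arbitrary; only argmax positions and relative heights are
used.

Per single estimate, τ is the argmax of s(τ), ties resolved toward the
smallest |τ|. For bootstrap estimates τ is computed per segment and the
reported delay is the *mean of segment taus*: on band-limited sources
the segment-averaged strength function has near-equal side peaks
(observed at the true delay ±8 ms for 10–45 Hz sources) between which
an argmax hops, while the mean of per-segment argmaxes is stable; the
averaged-strength argmax is retained in `meta['strength_peak_ms']`. The
80% confidence interval over segment taus uses type-7 percentiles;
estimates whose CI contains 0 ms are flagged invalid and excluded from
delay summaries — the screen that removes noise-dominated connections.
Peak binning: baseline = s(0); strict local maxima above baseline at
τ ≥ 1 ms, accepted greedily by height with ≥5 ms separation, grouped
into bins 1–9, 10–19, 20–29 … ms and normalised to percentages per
connection set (per-subject percentages are averaged across subjects
when aggregating; pooling is available by flag).

Skewed sources are essential: the bispectrum estimates third-order
cumulants, which vanish for Gaussian signals — the tests verify that
Gaussian sources give <20% of the skewed sources' bispectral magnitude
at matched epoch counts, and that the estimator equals brute-force
triple-product sums on tiny inputs to <1e-10.

## Permutation statistics

Paired tests flip each subject pair's condition assignment
independently; the statistic is the difference in means. When all 2ⁿ
sign patterns fit within the permutation budget the null is enumerated
exactly (p then equals the exact enumeration p, asserted at n = 3);
otherwise p = (1 + #extreme)/(1 + n_perm), which cannot be zero.
Defaults: 100 000 permutations, α = 0.05, two-sided (one-sided drops
the absolute values). Cluster correction: the cluster-forming threshold
is the pointwise two-sided permutation α-quantile per bin (a
config-exposed choice — fixed-height thresholds are equally defensible
and the choice is logged in every output); contiguous suprathreshold
bins form clusters scored by the summed statistic (mass, not extent),
and cluster p-values come from the null of the maximal |mass| per
permutation. Calibration is demonstrated by simulation: paired-null
rejection rate 0.03–0.07 at α = 0.05 (500 reps × 1000 permutations,
n = 18) and cluster family-wise error ≤ 0.05 + 2 MC-sd over 200
global-null simulations on a 60-bin grid. Unequal condition groups are
handled by each contrast using only its complete pairs.

## Connectomics and mixed models

Structural connectivity counts streamlines whose minimum *vertex*
distance (Euclidean, MNI mm) to the ECoG contact is ≤5 mm and to the
STN contact ≤3 mm, boundaries inclusive; no segment interpolation is
performed, and the synthetic atlases are built to be insensitive to
that dialect choice (their counts equal a brute-force vertex scan
exactly, including a 5.0 mm-inclusive / 5.1 mm-exclusive boundary
fixture). Functional connectivity: the seed time course is the mean
over voxels within 5 mm of the contact; the map is the Pearson
correlation with every voxel (zero-variance voxels masked NaN); parcel
summaries are means over defined voxels. Raw correlations are used
(no Fisher-z; a transform flag is exposed).

Mixed models (`statsmodels.MixedLM`, REML) regress connectivity on the
band-averaged coupling-pattern value per contact (low-β 12–20 or high-β
20–30 Hz) and a binary medication term, with a subject random
intercept. Reported: per-term β/SE/p, conditional
R² = (var_fixed + var_random)/(var_fixed + var_random + var_residual),
BIC from a maximum-likelihood refit (REML likelihoods are not
comparable across fixed-effect sets), and the Pearson r of (fixed +
BLUP) fitted values against the response. Alternative fixed-effect sets
support model comparison. A degenerate design (response an exact linear
function of the predictors) makes the profiled likelihood singular; a
perfect-fit OLS fallback then returns the exact coefficients with
conditional R² = 1 and a boundary warning.

## Synthetic data: what it emulates, and what it does not

Sources are white noise bandpassed to the configured band; when
non-Gaussianity is requested they pass through a monotone exponential
skewing transform and are re-filtered. The re-filter keeps the
sum-frequency (harmonic) band at a fixed 8% variance fraction: filtering
back to the narrow band alone would restore a symmetric process with a
vanishing bispectrum (skewness ~1e-4 empirically), silently defeating
delay estimation, while 8% harmonics preserve ≥90% in-band variance and
skewness of order 1–3. The cortex→STN interaction is
`target = gain · seed(t − τ) + innovation` with τ an integer number of
samples (sub-sample delays are rejected with the finest representable
step named). Channels are random full-rank mixtures plus 1/f-shaped
background noise at the configured per-channel SNR (dB) and a common
zero-lag 50 Hz line component. Defaults mirror a clinical acquisition:
4 kHz sampling, 6 ECoG + 8 STN contacts, beta-band sources, 25 ms
delay, 10 dB SNR; SNR and artifact amplitudes are not constrained by
the mirrored acquisition (no such figures are available for real
recordings), so they are explicit configuration with these defaults.

The DBS artifact is synthesised band-limited: the truncated Fourier
series of a charge-balanced biphasic rectangular pulse (60 µs per
phase) at stimulation-frequency harmonics below Nyquist, with
log-uniform per-channel gains. Naively sampling a 60 µs pulse at 4 kHz
would alias the continuous pulse's strong high harmonics onto
non-harmonic frequencies; the band-limited construction keeps the
artifact's power exactly on the harmonic comb (>99%), which is also the
premise of period-based removal.

What the generator does **not** emulate: biophysical neural-mass
dynamics, cross-frequency or burst structure, movement/dyskinesia
artifacts, electrode drift, inter-subject anatomical variability, or
volume-conduction geometry beyond instantaneous linear mixing. Passing
the validation battery therefore demonstrates estimator correctness
under the stated statistical model — linear mixing, stationary
band-limited sources, additive 1/f noise — not robustness to everything
real recordings contain.

VAR fixtures are simulated with a companion-matrix stability check
(spectral radius <1 rejected) and 1000-sample burn-in; their closed-form
spectra provide analytic oracles. Fiber atlases construct each
requested streamline by rejection sampling until it qualifies for
exactly its designated contact pair, add decoys that qualify for no
pair (plus one 0.1 mm outside the cortex radius), and self-check
against a brute-force scan before returning; geometries where contacts
sit closer than the combined radii are rejected. Cohort tables follow
`response = β₀ + β_pattern·pattern + β_med·medication + u_subject + ε`
with alternating within-subject medication and standard-normal
patterns.

## Validation battery: study designs and problem sizes

`ctxstn.validation` fixes one study design per estimator; the same
functions back `tests/test_acceptance.py` (fixed seed) and
`scripts/acceptance.py` (caller's seed). Sizes were chosen so the whole
battery runs in a few minutes on one CPU while keeping every study's
statistical conditions meaningful:

- **Delay recovery**: 20 simulations, 25 ms delay, 10 dB SNR, 120 s of
  1000 Hz data, 400 bootstrap segments; median |τ−25| ≤ 2 ms among
  CI-valid connections.
- **Direction recovery**: 100 runs of a one-way bivariate VAR (60 s at
  250 Hz); band-mean TRGC > 0 in ≥95 runs; antisymmetry ≤1e-10.
- **Zero-lag immunity**: instantaneously mixed shared sources (120 s,
  strong common signal — sensor noise at 0.15× source scale, the
  volume-conduction regime this test targets). ImCoh and MIC
  (100-segment averages) must stay below the 95th percentile of a
  19-fold epoch-shuffle null at every 3–50 Hz bin. For TRGC an
  independence (epoch-shuffle) null is the wrong reference: TRGC's
  finite-sample variance grows with coherence, so independent surrogate
  data systematically understate it even though TRGC is exactly zero on
  the population CSD of mixed signals. The label-shuffled null instead
  relabels channels into seed/target sets (all balanced partitions of 8
  channels sharing 3 sources), preserving the mixing; under pure mixing
  the true partition is exchangeable with the relabellings and band-mean
  |TRGC| falls below the null's 95th percentile.
- **Pattern recovery**: 20 simulations each for SSD (single 15 Hz
  source into 4 channels) and MIC (5+3-channel coupled simulation);
  mean |r| against the true mixing columns > 0.9.
- **Permutation calibration**: 500 null repetitions × 1000 permutations
  (n = 18); cluster FWE over 200 simulations of an 18 × 60 global null.
- **Mixed models**: 100 cohorts of 18 subjects; 95% CI coverage of
  β_pattern ≥ 90%, BIC preference for the generating model ≥ 90%.
- **PARRM**: 20 s at 4 kHz, 20 Hz sine + unit noise + 130 Hz artifact;
  ≥20 dB suppression at 130 Hz, <1 dB distortion of 10–35 Hz power.
- **Pipeline determinism**: the demo cohort (6 subjects × 2 conditions,
  40 s at 1 kHz, 30/60 segments, 2000 permutations) run twice;
  SHA-256 manifests must be identical.

## Known limitations

- Delays are integer multiples of the simulation sample period;
  sub-sample delays are out of scope.
- The Whittle VAR fit assumes the CSD is well conditioned after rank
  normalisation; heavily rank-deficient inputs fail loudly rather than
  being regularised silently.
- The cluster-forming threshold and the ImCoh averaging order are
  conventions with defensible alternatives; both are config-exposed and
  recorded in outputs.
- Recording I/O uses the raw-binary + JSON sidecar backend with
  channels/electrodes TSVs; no EDF export is provided.
- Interhemispheric coupling, phase-amplitude coupling and waveform-shape
  analyses are out of scope.
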