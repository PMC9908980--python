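# Methods

This note documents the models implemented in `painsync`, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical conventions. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## ΔF/F₀ and active-soma calls

Baseline F₀ per ROI is the minimum over all contiguous 2-s windows (step
one frame) of the window-mean fluorescence; ΔF/F₀ = (F − F₀)/F₀. The
window length in frames is round-half-up of `window_s × frame_rate_hz`
with a minimum of one frame, so the window is deterministic across the
1.3–1.7 Hz frame-rate range (3 frames throughout). Ties between equal
window means go to the earliest window. A non-positive F₀ raises
`DegenerateBaselineError` naming the ROI; negative ΔF/F₀ values are
retained — the formula does not clip.

The *baseline SD* that feeds the 3-SD active criterion is not uniquely
defined by the phrase "standard deviation of the baseline"; the default
(`sd_mode="baseline_window"`) takes the sample SD (ddof = 1) of ΔF/F₀
inside the selected lowest window — the most literal reading — and
`sd_mode="robust"` offers 1.4826 × MAD over the full trace, because a
3-frame window yields a noisy SD estimate at these frame rates. A zero
baseline SD marks a perfectly flat baseline: the ROI is then called
active iff the trace is non-constant.

Integrated Ca²⁺ activity is the plain sum of ΔF/F₀ samples over the
first `floor(duration_s × frame_rate_hz)` frames (default 150 s). Frames,
not interpolated seconds, are the unit of summation, which makes the
value frame-rate dependent; recordings shorter than the span raise rather
than silently truncate.

## Pairwise synchrony and the circular-shift bootstrap

Synchrony is the Pearson correlation of raw ΔF/F₀ samples (not binarised
events — the most literal reading of correlating "activity") between
active cells over a 150-s span; the correlation matrix is exactly
symmetrised and zero-variance traces yield missing entries excluded from
the mean. The analysis span and the integrated-activity span are
independently configurable, since they need not refer to the same epoch.

The cross-correlogram evaluates the Pearson coefficient of the
overlapping segments at each integer lag; its zero-lag value is exactly
the matrix entry, and the bootstrap statistic is this Pearson-normalised
zero-lag value (not a raw dot product), keeping correlogram and test
consistent.

Significance per pair: one trace is circularly rotated by an offset drawn
uniformly from {1, …, T−1} (never 0), 500 times, with replacement —
unavoidable, since a T-frame trace has only T−1 distinct nonzero
rotations. `p_hat` is the fraction of shuffles whose value is *strictly*
greater than the observed one (ties count for the observed data) and a
pair is significant when `p_hat < 0.05`. No multiple-testing correction
is applied across pairs; the per-pair 5% rule is applied directly, as is
conventional for this readout. Constant traces return `p_hat = 1`.

A point worth knowing when interpreting the calibration: for independent
pairs the rank of the observed value among {observed + T−1 rotations} is
uniform by exchangeability, so with T = 225 the exact type-I level of
this recipe is E_r[P(Binom(500, (r−1)/224) ≤ 24)] ≈ 5.2% — marginally
above the nominal 5% because the 500 draws only estimate the exceedance
fraction of the 224 rotations. Measured fractions over 1000 pairs
therefore scatter around 5.2% with SE ≈ 0.7%. The package reports the
empirical fraction as computed; it does not correct the recipe.

## ECoG spectra

Each annotated awake-resting interval is carved into non-overlapping
epochs (10 s default; 11.46 s supported for imaging-simultaneous
sessions, where 11.46 s corresponds to 10 imaging frames). Epoch
selection itself (movement/sleep exclusion) is an input annotation, not
an algorithm here — no detection rule is defined for it. Per epoch the
mean is removed, a Hann window applied (rectangular available via
`window="boxcar"`), and the FFT periodogram computed with density
scaling; periodograms are averaged across epochs without overlap. The
average is restricted to 0.5–40 Hz and normalised to *relative power*
summing to one over that band — "relative" needs a denominator and total
0.5–40 Hz power is the natural one. The pre-normalisation density and its
full-band integral (≈ mean epoch variance; Parseval) are kept on the
result for consumers who need absolute units, since figures reporting
"mean power" may be on either scale.

Band means are the mean relative power density within delta 0.5–4 Hz,
theta 4–8 Hz, alpha 8–12 Hz, with half-open edges [lo, hi): 4 Hz belongs
to theta and 8 Hz to alpha, resolving the overlapping printed band edges
deterministically. Band-power-vs-behaviour association uses the Pearson
coefficient with the two-sided t-distribution p-value (n−2 df).

## Up-down threshold estimation

Filament stepping: no withdrawal → next stronger, withdrawal → next
weaker, starting at 0.4 g (index 4 of the standard 0.008–4.0 g series;
configurable). The first response change defines the crossing; the two
responses straddling it retrospectively open the scored series, which
runs to six presentations. The 50% threshold is 10^(Xf + κδ)/10 000 g
with Xf = log₁₀(final filament force in 0.1 mg units) — the /10 000
denominator forces that unit convention — and δ = 0.2699.

Two open points and how they are handled:

* **δ.** The conventional constant 0.2699 does not equal the mean log₁₀
  spacing of the standard 10-filament series (≈ 0.2999, exposed as
  `FilamentSeries.delta_from_series()`). The constant is the default;
  the computed spacing is available.
* **κ.** κ depends on the scored response pattern via a tabulated lookup
  that is not reproduced here from any copyrighted source. The bundled
  editable table (`painsync/data/kappa_default.tsv`) assigns κ = +0.5
  when the final scored response is negative and −0.5 when positive — the
  simplified up-down convention, which preserves the estimator's
  half-step correction toward the true threshold. Labs holding the full
  tabulated values can pass their own file to `load_kappa_table`.

Sequences that exit the filament range before the score completes (never
withdraws at 4.0 g, withdraws at 0.008 g) are flagged and assigned the
boundary force as threshold, preserving auditability rather than
discarding the trial.

CPP preference is time in the drug-paired minus the vehicle-paired
compartment over a 600-s test; subjects with a pre-conditioning side bias
strictly greater than 400 s are flagged for exclusion.

## Spine classification, matching, turnover

A protrusion is a filopodium iff head/neck diameter ratio < 1.2 *and*
length/neck ratio > 3 (both strict); everything else is a spine.
Positions are 1-D arc lengths along the branch — landmark registration is
assumed done upstream. Matching is greedy nearest-neighbour per branch:
candidate pairs within 0.7 μm are accepted in order of increasing
distance (ties by lowest id), each spine matched at most once. Greedy
with deterministic tie-breaks was chosen over optimal assignment because
it mirrors how matching is done manually and determinism matters more
than optimality at biological spine densities; the test suite verifies
agreement with an exhaustive optimal-assignment oracle on small fixtures,
where the two coincide. Filopodia are excluded from matching and
turnover by default (turnover is a spine measure; configurable).

Turnover compares each later view with the *first* view by default —
eliminated = first-view spines unmatched there, formed = that view's
spines unmatched in the first view, both divided by the first-view count
(×100 for percent). Because some designs mark changes between successive
sessions instead, `reference="consecutive"` compares each view with its
predecessor and divides by the predecessor's count. Inclusion screening
drops branches ≤ 30 μm and flags (never drops) animals contributing
≤ 150 spines, both strict inequalities read off the stated criteria.

## Synthetic-data generators

The generators define the operating conditions under which the pipeline
is calibrated; their defaults are fixed, not tuned.

* **Calcium populations.** Events are homogeneous Poisson: per-neuron
  background (default 0.05 Hz — a sparse spontaneous rate typical of
  resting sensory neurons at these recording lengths) plus population
  co-events (rate configurable) that each neuron joins with
  `participation_prob`. Fluorescence is
  `baseline_f × (1 + amplitude_dff × Σ kernel)` with a
  difference-of-exponentials kernel, rise 0.18 s and decay 1.8 s —
  slow-indicator (GCaMP6s-like) kinetics, a generator convention since no
  indicator time constants are part of the analysis itself. Frames are
  instantaneous point samples at `frame_rate_hz` (default 1.5 Hz, the
  middle of the 1.3–1.7 Hz acquisition range) over 150 s; noise is
  additive i.i.d. Gaussian on fluorescence (default SD 1 on a baseline of
  100, i.e. 1% of baseline). Not emulated: photon/shot noise, neuropil
  contamination, bleaching, motion — so passing calibration here shows
  the statistics are computed correctly, not that they are robust to
  those artefacts.
* **ECoG.** Spectrally shaped Gaussian noise (amplitude ∝ f^(−α/2),
  default α = 1) rescaled to `noise_sd` RMS, plus a sinusoid gated by a
  deterministic duty cycle (on for the first `burst_duty` fraction of
  each 2-s period). The gate is deterministic so band power is an exact
  function of amplitude and duty.
* **Psychometric responders.** Withdrawal probability is logistic in
  log₁₀ force with P = 0.5 exactly at the true threshold; infinite slope
  gives the deterministic step responder used for hand-checkable
  sequences.
* **Spine views.** Each interval eliminates existing spines i.i.d. with
  `p_elim` and adds Binomial(n_initial, `p_form`) new spines. New
  positions keep a minimum gap (default 1.5 μm > 2 × 0.7 μm) to *every
  site ever occupied*, so position-based matching is provably
  unambiguous against the carried identity labels; real dendrites do not
  guarantee this, which is exactly why the tolerance rule exists.

All generators are bitwise-reproducible from their config and seed
(single `numpy` Generator per call).

## Numerical conventions and problem sizes

Times in seconds, frame indices 0-based, intervals half-open [start,
end). CSV uses 17-significant-digit serialization and round-trip float
parsing so write→read is bit-exact. One seeded RNG drives each stochastic
routine; the pipeline records seed, package version and a parameter hash
in its manifest, and reruns with identical config produce byte-identical
summaries.

The calibration suite uses desk-scale problem sizes chosen to make the
statistical checks sharp while remaining quick: 1000 independent pairs ×
500 shuffles for the type-I calibration (binomial SE ≈ 0.7 percentage
points), 12–15 neuron populations on 5-point parameter grids for
recovery/monotonicity (Spearman ≥ 0.9), 200 simulated subjects for the
up-down estimator, 600 × 10-s epochs for the white-noise flatness check.

## Known limitations

* No ROI segmentation, motion correction, bleaching correction or spike
  inference; firing rates are deliberately not decoded from the slow
  indicator.
* Lag-resolved significance is not tested (zero lag only), and no
  graph/community structure is derived from the correlation matrix.
* EMG-based sleep/movement scoring, gamma-band analysis and spectrogram
  rendering are out of scope.
* The up-down estimator's accuracy depends on the κ table supplied; the
  bundled simplified convention is a half-step approximation, accurate to
  within one filament step for steep responders (verified in the test
  suite), not a reproduction of the full tabulated values.
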