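# Methods

This note documents the models and numerical choices behind `alkaquant`:
what the simulator emulates, how each statistic is computed, and where the
design was genuinely open.

## Measurement model and the synthetic-data generator

One injection produces, per MRM transition, a uniformly sampled
time–intensity trace over the transition's scheduled acquisition window
(120 s centred on the expected retention time, 3 points/s → 361 samples, so
the narrowest simulated peak spans well over 20 samples and width
measurements are stable). Each trace carries a single
exponentially-modified-Gaussian (EMG) peak

    h(t) = A/(2τ) · exp(−z²/2) · erfcx((σ/τ − z)/√2),   z = (t − µ)/σ,

evaluated in the scaled-complementary-erf form (with a plain exponential
branch in the far tail where `erfcx` would overflow); τ = 0 degenerates to a
Gaussian. The EMG is the minimal shape that reproduces realistic tailing
factors (T ≈ 1.0–2.2 over τ/σ ≈ 0–2.7 at the default σ).

The peak area encodes the whole measurement chain:

    A = c_milk · f_prep · recovery · (1 − suppression·in_matrix) · R
        [qualifier transitions additionally × expected ion ratio]

* `f_prep` — sample-preparation concentration factor,
  (v_loaded/(v_milk+v_acid)) · v_milk/v_reconst = (15/33)·3/0.5 = 2.727
  ng/mL extract per µg/L milk with the default volumes. µg/L and ng/mL are
  the same numerical scale, so the factor is a pure ratio; its inverse
  converts every reported limit and concentration back to milk units.
* `recovery` — process recovery of extraction/clean-up (fraction, default
  per analyte from the packaged validation summary, mid-spike column).
* `suppression` — matrix ion suppression (fraction). It is applied to
  matrix-matched standards and samples alike, which is exactly why
  matrix-matched bracketing calibration cancels it in back-calculation.
* `R` — instrument response, default 1·10⁴ area counts·min per ng/mL on the
  quantifier. An arbitrary scale: no absolute response data are published
  for the panel.

Noise is additive Gaussian on a constant baseline (default level 10⁴
counts, sd 1200 counts), clipped at zero. Poisson shot noise is
deliberately omitted — there is no count-level information to calibrate it
against. The noise sd and response defaults were fixed once so that the
simulated full-panel DIN limits land in the printed plausibility band of
the validated method (LOD/LOQ of order 0.005–0.12 µg/L); they are not tuned
per analyte, so analytes whose real limits are dominated by analyte-specific
response (not recovery/suppression) will deviate — the worst simulated LOQs
(≈0.14–0.18 µg/L) belong to the semiquantitative analytes whose instrument
response is unpublished.

What the generator does *not* emulate: retention-time drift, heteroscedastic
(signal-proportional) noise, interfering matrix peaks inside the window,
carry-over, and isomer co-elution on a shared trace (each analyte owns its
trace; the co-elution logic is exercised with constructed doublets).
Passing tests therefore demonstrate the correctness of the computations
under the stated statistical model, not instrument performance on real
extracts.

## Peak processing

Baseline level and noise are the median and 1.4826×MAD of the samples
outside an exclusion zone (default ±0.25 min) around the expected retention
time — robust against the peak itself and against spikes. Peak acceptance
uses the conventional S/N = 3 criterion on the baseline-subtracted apex
height, with a minimum-width requirement of 3 samples so single-sample
noise excursions that clear 3σ by chance are not reported as peaks. When
several candidate maxima survive (isomers sharing a transition within one
window), the apex closest to the expected retention time wins — retention
order is the only disambiguator for identical mass transitions.

Integration bounds walk outward from the apex to the crossing of
max(3σ_noise, 0.5% of height), interpolated linearly between samples, or to
a valley that starts rising again (partially resolved neighbours). The
"baseline width" w_B used in the resolution formula is operationalised as
the width between these crossings; tangent constructions were deliberately
avoided as they are fragile on noisy traces. Consequently agreement with
vendor-software resolutions is approximate by construction; the resolution
and tailing formulas themselves are exact arithmetic on the measured
widths. The 5%-height width and front distance for the tailing factor are
measured on the baseline-subtracted signal, again with linear
interpolation; the apex position is refined with a three-point parabola.

Low-level calibration series (the DIN limit grids) are integrated by a
*forced* fixed window (±0.15 min around the expected retention time,
baseline-subtracted, not clipped) instead of threshold-gated detection. The
DIN decision limit corresponds to S/N ≈ 1, below any sensible acceptance
gate, so gated integration would censor exactly the observations the
regression needs and bias the residuals; forced integration yields
zero-mean blank areas, which is what the prediction-band construction
assumes. Vendor quantification software behaves the same way ("forced
baseline" integration of scheduled windows).

## Calibration and linearity

Quantification curves are unweighted OLS of area on extract concentration
through all standard injections *plus one (0, 0) observation*: "including
the point of origin" is read as the origin entering as a datum, not as
forcing a zero intercept. Unweighted, because the calibrated range spans
less than two decades. Back-calculated standards must satisfy the strict
band 80 < accuracy < 120%; one failure voids the sequence.

Mandel's test compares the straight-line and second-order fits via
F = ((n−2)s₁² − (n−3)s₂²)/s₂² against F(1, n−3; 99%); while it rejects, the
highest level is dropped, and fewer than 5 remaining levels is reported as
"nonlinear range". The residual-based variant is used (replicate-pooled
lack-of-fit would need balanced replicates); α = 0.01 matches the customary
99% confidence of the test and is configurable. The DIN limit regressions
are fitted *without* the origin datum and without replicate averaging — the
origin rule belongs to the bracketing quantification calibration, and
duplicate handling in the limit series is not specified by the underlying
standard, so the conservative single-injection regression is used.

## Detection limits

The DIN 32645 calibration-curve equations with α = 0.01 (both one-sided
error probabilities equal) and k = 3 (33.3% relative uncertainty at the
quantification limit):

    x_LOD = s_x0 · t(n−2; 1−α) · √(1/m + 1/n + x̄²/Q_x)
    x_LOQ = k · s_x0 · t(n−2; 1−α) · √(1/m + 1/n + (x_LOQ − x̄)²/Q_x)

with s_x0 = s_y/b and m = 1 future determination (samples are injected in
duplicate but confirmation is per injection, so m = 1 is the conservative
choice; configurable). The LOQ fixed point is iterated from 3·x_LOD to a
relative tolerance of 10⁻⁶; the map is a contraction iff (k·t·s_x0)² < Q_x,
and when that fails the quantification limit is reported as unattainable
(+inf) for that transition — this occurs only for the least sensitive
qualifier transitions, whose LOQ is never used. Numerically zero residuals
(relative to the signal scale) short-circuit to the degenerate (0, 0).

Two equidistant grids are simulated (12 levels at 0.01–0.12 and 11 levels
at 0.2–1.2 ng/mL); an analyte uses the low grid unless its fitted LOD or
quantifier LOQ falls outside that grid's top level, in which case the high
grid takes over. Per analyte the reported LOD is the maximum over the two
transitions (identity needs the qualifier detectable too) and the reported
LOQ is the quantifier's; both are divided by `f_prep` into milk units. The
reported LOD can reach or exceed the reported LOQ when the qualifier is far
less sensitive than the quantifier; such pairs are reported as computed.

## Confirmation, censoring and reporting

A compound is confirmed only if both duplicate injections show accepted
peaks on both transitions, match the bracketing standards' mean retention
time within ±0.10 min, and match their mean ion ratio within a *relative*
±20% (the SANTE reading of the tolerance; the absolute reading would be far
looser for small ratios). The three flags are evaluated independently so
the gating logic is fully auditable.

Concentrations are the mean of the duplicate back-calculations divided by
`f_prep`, never recovery-corrected. Censoring: unconfirmed or below-LOD →
not detected; LOD ≤ c < LOQ → "detected below LOQ"; otherwise quantified.
Sum contents count below-LOQ detections at 0.5×LOQ and round half away from
zero to 3 decimals (plain banker's rounding would report 0.0195 as 0.019
rather than 0.020). Semiquantitative analytes (riddelliine-, merenskine-
and merepoxine-*N*-oxide) and the two *N*-oxides excluded from the
cation-exchange clean-up carry flags in reports but are treated identically
by the arithmetic.

Recovery is mean(back-calculated)/nominal ×100 with RSD_r from the sample
standard deviation (n−1); spike levels below an analyte's LOQ are skipped.
Exposure is conc × intake/(density × bw) in ng/kg bw/day (milk density
1.0 g/mL by default) and MOE = 1000·BMDL₁₀/exposure with BMDL₁₀ = 237
µg/kg bw/day. For the reference toddler scenario (0.04 µg/L, 230.4 g/day,
16.15 kg) this arithmetic yields 0.571 ng/kg bw/day; the function exposes
the computation rather than any tabulated value.

## Problem sizes and determinism

The packaged panel drives full-58-analyte simulations throughout (a full
calibration + limits + spike validation takes about a second); the
statistical calibration checks use 5000 Monte-Carlo draws for the
false-positive rate of the decision limit and 2000 simulated series for
Mandel's type-I rate, judged against binomial confidence bands. All
randomness flows through explicit integer seeds (batch generators derive
per-injection child seeds from a single batch seed), so identical seeds
reproduce batches bit for bit.

## Known limitations

* Chromatographic statistics are only as defined here; no deconvolution of
  overlapping peaks — unresolved isomer pairs are reported combined, as in
  the packaged validation summary ("IcN/LyN", "EnN/RrN", "Ic/Im").
* The homoscedastic noise model makes high-level RSDs optimistic; real
  repeatability is dominated by signal-proportional terms the simulator
  does not carry.
* No isotope-dilution internal-standard correction, no blank-value (direct)
  DIN method (the S/N 3σ/10σ limits exist only as a cross-check utility),
  no vendor raw-file ingestion.
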