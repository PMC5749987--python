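# Methods

`blastpam` implements a complete analysis chain for passive acoustic
monitoring (PAM) of delphinid responses to underwater detonations, driven
entirely by a synthetic acoustic-scene generator.  This note documents the
models, the defaults and why they were chosen, the numerical choices, and
what the synthetic tests do and do not demonstrate about real data.

## The monitoring model

A bottom-moored recorder samples on a duty cycle of 180 s out of every
360 s (50%).  Each 3-min recording is scored by an analyst (here: by the
simulator) for three signal types — whistles, burst pulses (BP) and
echolocation clicks — and mapped to a 9-level ordinal *acoustic activity
index* {0, 1, 1.5, …, 4}.  The hourly mean of the index (MAA), divided by
4, is the [0, 1] response used in regression.

### Index-table boundary conventions

The published index bands leave a few integers unassigned (whistle band
"&gt; 41" skips 41; BP bands "&lt;10"/"&gt;10" skip 10).  The implementation
closes the upper bands — whistles 1–20 / 21–40 / ≥41, BP &lt;10 / ≥10,
clicks &lt;2 / ≥2 s⁻¹ — so that the map is a total function.  This choice is
isolated in one table-driven function and verified against an independent
literal row encoding over an exhaustive lattice of counts.

## Scene simulator

The generator reproduces the structure of the study conditions, not any
particular dataset:

- **Presence/absence.** A dolphin group is present in a recording with
  probability `presence_prob_{day,night}` (defaults 0.35 / 0.50 — night
  elevated) times a monthly seasonal multiplier.  The default seasonal
  curve peaks in August–October (1.0) and bottoms in February (0.1),
  i.e. a 90% winter reduction relative to the peak, with near-daily
  presence year-round.
- **Signal rates.** Given presence, whistle and BP counts are negative
  binomial (means 15 and 3 per recording, dispersion k = 2 — overdispersion
  typical of PAM count data) and the click rate is gamma distributed
  (mean 1.5 s⁻¹, present with probability 0.7).  A 24-h diel curve
  multiplies the conditional rates: elevated at night with a midday peak.
  No published distribution exists for these counts; the negative
  binomial / gamma choices are stand-ins and only the ordinal index
  consumes them.
- **Response to detonations.** Daytime presence is multiplied by
  `suppression` (default 0.4) from the first detonation of each blast day
  (for up to `suppression_hours`, default 12) and through the daytime of
  the day after the last blast; on the second day after, daytime presence
  is multiplied by `rebound` (default 1.3).  Night blocks are unaffected,
  matching the observed return to baseline at night.  Suppression acts on
  the *presence probability* — the response is modelled as animals leaving
  the area — so the mean signal count scales exactly with the suppression
  factor while the banded index responds through reduced occurrence.
- **Waveforms.** Gaussian ambient noise at a configurable dBFS level;
  a detonation is white noise under an envelope with a ≤1 ms linear rise
  and exponential amplitude decay `exp(-t/tau)`.  The closed-form time for
  a +30 dB transient to decay to ambient + 6 dB is `tau · ln(10^{30/20} /
  10^{6/20}) ≈ 2.763 tau`, the oracle used in the detector tests.  (The
  measured duration runs a few percent long because the *total* envelope
  is the root sum of squares of reverberation and ambient power.)
- **Seeding.** One integer seed; `numpy.random.SeedSequence` spawning
  gives the count simulator and waveform synthesizer independent
  substreams (children 0 and 1).  All outputs are bit-identical across
  runs for a fixed seed.

What the simulator does *not* emulate: realistic whistle contours or click
spectra, analyst subjectivity and inter-analyst drift, weather/noise-driven
detectability changes, multipath propagation, or spatial structure beyond
per-site labels.  Passing tests therefore demonstrate that the pipeline's
statistics behave correctly under a plausible generating process — not that
the field results would replicate.

## Transient detector

Envelope = RMS in non-overlapping 10 ms frames; background = median
envelope over the preceding 30 s (median so the transient itself, and the
tail of a previous one, barely contaminate the estimate; the window
excludes the current frame).  A detection requires the envelope to exceed
background by 20 dB (default) *and* to have risen from background + 6 dB to
the trigger level within 50 ms — the operationalization of a "near
instantaneous" rise to peak levels that rejects ship-like swells (the
first trigger-level crossing is used rather than the envelope argmax,
which RMS fluctuations can displace well into a slowly decaying
reverberation).  The reverberation duration runs from
onset until the (lightly smoothed, 3-frame mean) envelope stays below
background + 6 dB for at least 50 ms; if the recording ends first, the
duration is right-censored and kept with a flag, so a short recording
ending mid-reverberation still yields a (lower-bound) size class.  Size
classes are half-open intervals: [0, 2) s small, [2, 7) s medium, [7, ∞) s
large, so the boundary durations 2 s and 7 s fall in the upper class and
the map is a partition.

All thresholds are relative to the background, making the detector exactly
invariant to constant gain, and equivariant (to one frame) under time
shifts.

## Event windows

Detonations on calendar days separated by ≤1 day form one training event.
The day before the first detonation is baseline; all detonation days are
"day of"; the two days after the last detonation are "day after" and
"second day after".  Events without a clean 3-day pre-event baseline are
excluded.  Daytime is 06:00–17:59 and night 18:00–05:59, the night block
attributed to the date it starts on (keeping each label's night
contiguous); a variant daytime window of 10:00–17:59 supports day-of
comparisons at distant sites, since most detonations fall in that window.
Hour-scale comparisons use whole clock hours relative to the detonation's
clock hour.  Missing hours or blocks propagate as missing and are dropped
from pairing — never imputed as zero, because index 0 is a valid
observation.

## Paired statistics

A Shapiro–Wilk gate (α = 0.05) on the paired differences routes each
comparison to a paired t-test (normal) or a Wilcoxon signed-rank test.
Zero differences are dropped before ranking (the classical treatment;
Pratt's alternative would change Z).  The reported Wilcoxon Z is the
tie-corrected normal-approximation statistic; p-values are exact for
n ≤ 15 without ties and continuity-corrected normal otherwise.  Effect
sizes: r = |Z|/√(pairs) by default; the 30-s whistle comparison uses
r = |Z|/√(2·pairs) (total observations) and carries an explicit convention
flag — both conventions appear in the behavioural literature and they are
surfaced rather than harmonized.  Cohen's d for paired t is |t|/√n.  All
p-values are two-sided; no multiple-testing correction is applied.

## Beta-regression GAM

Response: MAA squeezed off the boundary by y′ = (y(n−1) + ½)/n
(Smithson–Verkuilen), applied once globally.  Model: y′ ~ Beta(μφ,
(1−μ)φ) with logit(μ) = Xβ.  Continuous predictors get penalized cubic
B-spline smooths (10 basis functions, sum-to-zero constrained, second-order
difference penalty — P-splines, the same low-rank penalized machinery as
thin-plate regression splines but with a simpler basis); categoricals get
treatment-coded dummies; ordinals enter linearly.

Fitting is alternating penalized Fisher scoring: a Newton step for β using
the expected information `φ² (ψ′(μφ)+ψ′((1−μ)φ)) μ²(1−μ)²`, then a Newton
step for log φ, each with step halving so the penalized objective is
monotone non-decreasing (the trace is stored on the fit).  Initialisation:
penalized least squares on logit(y′) for β, method-of-moments for φ.
Fitted means are clipped to (1e-10, 1−1e-10) inside the link only.

The smoothing parameter (shared across smooths) minimizes AICc over a
log-spaced grid spanning 1e-2–1e8; the wide top end lets degenerate
near-constant responses shrink their smooths to ~0 effective df.  The
effective df is tr[(XᵀWX + S)⁻¹ XᵀWX], partitioned by term via the
diagonal; AICc uses k = edf + 1 (for φ).  Explained deviance is
1 − D(model)/D(null) with both deviances computed at the model's φ̂ (the
null mean is the 1-d beta MLE at that φ).  An adjusted-R²-style summary
(squared-error based) is emitted alongside, since either flavour of
pseudo-R² may be wanted.

All-subsets selection fits every predictor subset (intercept always
included; ≤12 candidates enforced), ranks by AICc, and selects the
minimum; among models within ΔAICc ≤ 2 that tie to 2 d.p., the fewest
predictors wins.  Per-predictor deviance contributions come from
leave-one-out refits: DE(full) − DE(without); they need not sum to
DE(full).  Residual autocorrelation diagnostics: ACF to lag 48 and the
Durbin–Watson statistic with a permutation p-value (≥2000 shuffles of the
residual order; the classical DW bounds assume an ordinary linear model,
which this is not).

Hours with no recordings are dropped from the model, not imputed.

## Propagation

Similitude relations for a shallow-water charge at range r (m):
peak pressure `52.16e6 (W^{1/3}/r)^{1.13}` Pa and
`SEL = 6.14 log₁₀W − 13.26 log₁₀r + A` dB re 1 µPa²·s.  A is calibrated
once by least squares to an eight-cell reference grid (5 and 20 lb × 1, 3,
6, 12 km), giving A ≈ 218.88 with every cell reproduced within 0.5 dB and
every peak-pressure cell within 2%.  The reference grid is only reproduced
when the tabulated charge weight is plugged in as printed (nominal lb of
C4), not after conversion to kg TNT; the functions therefore take the
as-printed number, and `c4_lb_to_tnt_kg` is provided for physically
explicit use.

## Problem sizes and numerical choices in the test suite

Synthetic recordings for detector tests run at 4 kHz (the detector is
sample-rate agnostic; all windows are in seconds) with 20 s background
windows, keeping each fixture under a megasample.  Calibration and power
checks of the paired pipeline use 31 single-day events with full coverage
of each event's five-day window (≈30k recordings per replicate): 500 null
replicates for the type-I error, 100 for power.  GAM recovery uses
n = 5000 (single fit) and selection consistency n = 3000 × 100 replicates
with a 3-point λ grid.  Monte-Carlo tolerances are stated in each test in
units of the standard error of the quantity checked.

## Known limitations

- The detector has no matched filter and no multi-band features; it will
  confuse any impulsive broadband source with comparable rise time for a
  detonation.
- The beta GAM uses a single shared smoothing parameter per model rather
  than per-term selection, and AICc rather than REML; on strongly
  heterosmooth data per-term REML would be preferable.
- The Wilcoxon normal approximation (used above n = 15) carries the usual
  lattice discreteness error; two-sided agreement with exhaustive
  enumeration is limited to ~0.01–0.02 at n ≤ 12 even with continuity
  correction, which is why the exact distribution is used there.
- Ordinal index values are treated as interval-scaled when averaged into
  MAA, inheriting the corresponding caveat of the source methodology.
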