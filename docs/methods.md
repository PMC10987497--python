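# Methods

This note documents the models, conventions, and design decisions behind
`circatemp`: what the synthetic generator simulates, how each analysis stage
is defined, which choices were genuinely open, and what the tests do and do
not establish about real data.

## Synthetic locomotion model

Each fly-day is 8640 epochs of 10 s. A fly alternates between wake and sleep
via a discrete two-state Markov chain whose transition probabilities follow a
target wake probability w(ZT) ∈ [0, 1]:

* entry into sleep: p_entry = r · (1 − w(ZT)) per epoch,
* exit from sleep: p_exit = r · w(ZT) per epoch,

so the chain's local stationary wake probability equals w(ZT). While awake
the fly emits Poisson movement counts at rate λ(ZT) per epoch; asleep it
emits zero. λ(ZT) is a baseline plus circular-Gaussian morning and evening
peaks, matching the bimodal fly activity profile.

Defaults (the simulated study conditions): λ_b = 1 count/epoch, morning peak
at ZT 0.5 (σ 1 h, amplitude 3), evening peak at ZT 11 (σ 1.2 h, amplitude 5);
w = 0.85 (ZT0–4), 0.45 (siesta, ZT4–9), 0.85 (ZT9–12), 0.30 (night);
switching scale r = 0.02 per epoch. These give mean bout durations of roughly
10–50 min and ~730 min of sleep per fly-day, typical of wild-type flies, and
keep per-fly window means well away from zero — important because the
behavior indices are per-fly ratios, whose estimator bias grows as the
squared coefficient of variation of the denominator.

Temperature conditions perturb this program through four knobs per condition
label: a shift of the evening-peak center (hours), an additive change to
night wake probability (ZT12–24), an additive change to siesta wake
probability, and a multiplicative rate factor applied inside ZT6–12. The
default condition set is 24 °C/22 °C controls (no effect), an 18 °C cooling
day (evening peak −1 h, ZT6–12 rate × 1.3, siesta wake +0.2, night wake
−0.1) and a 30 °C heating day (evening peak +1.5 h, night wake +0.3, siesta
wake −0.15) — the qualitative signatures of cooling (earlier, stronger
evening activity; better night sleep) and heating (later evening offset;
night-sleep loss; deeper siesta).

### Expectation oracle

`expected_window_mean` returns the large-sample expectation of the per-bin
window mean. For **activity** it is analytic: the marginal P(awake) per epoch
follows from forward iteration of the chain (initialized at w(ZT0), exactly
as the simulator initializes), and the expected count per epoch is
λ(ZT) · P(awake). For **scored sleep** no closed form exists — the 5-min
run-length rule couples chain state with the chance that an awake epoch
emits zero counts — so the expectation is estimated by Monte Carlo over
simulated flies (default 10⁴–5·10⁴; the returned object names the method and
n). Recovery tests use n = 6000–10 000 flies, where the Monte-Carlo error is
negligible against the n = 64 experimental SEM.

### A note on the label-permutation null

For a difference statistic, permuting condition labels within flies gives a
null distribution centered exactly at zero. The indices here are *ratios*
((x − y)/y), for which label swapping across a true effect has positive
expectation ((x − y)/y averaged with (y − x)/x is (x − y)²(x + y)/(2xy·…) ≥ 0).
The null sanity check is therefore run under exchangeability: two record sets
generated under the *same* condition on different days, fed to each index,
whose group mean must be statistically indistinguishable from zero (within
3 SEM plus the small CV² ratio bias).

## Synthetic calcium model

Latent activity of one ROI recorded at Zeitgeber time zt:

a(t) = b(zt) + s · g(zt) · R(ΔT(t)) [+ coupling]

* **b(zt)** — diurnal baseline, sinusoid rising through the day and falling
  at night (minimum ZT0, peak ZT12; midpoint 1.0, amplitude 0.3 by default).
* **g(zt) ≥ 0** — circadian gating of the temperature response, piecewise
  constant: 0.25 (ZT0–8), 0.6 (ZT8–10), 1.0 (ZT10–20), 0.6 (ZT20–24). Weak
  morning/afternoon responses, strong evening/midnight responses, and a
  planted night:day (ZT17–19 vs ZT6–8) gain ratio of exactly 4.
* **R(ΔT) = sign(ΔT) · min(|ΔT|/ΔT_sat, 1)** — saturating step response with
  ΔT_sat = 6 °C for cooling and 8 °C for heating; ΔT(t) follows the protocol
  temperature (piecewise-linear ramps, default 80 s) minus baseline.
* **coupling** — LNd and DN3 latent activity receives w · (s_DN1a · g · R)
  with negative weights (−0.6 LNd, −0.8 DN3): the inhibitory DN1a→LNd and
  DN1a→DN3 links. Ablating DN1a zeroes the coupling; the class's own small
  direct gain (0.15) remains as the configurable residual drive.

The latent is low-pass filtered with the sensor time constant τ = 10 s using
the exact single-pole exponential update (zero-order hold), then rendered
into channels: GCaMP F = F₀(1 + κ·a)·bleach(t) + ε, tdTomato
F = F₀·bleach(t) + ε, with κ = 0.5, F₀ = 100 a.u., exponential bleach
(τ = 2000 s), and i.i.d. Gaussian noise (SD 2 a.u. ≈ 2 % of F₀).

## Calcium quantification conventions

* **F₀** — "fluorescence at time 0" read literally is one noisy sample; the
  default is the mean over a 30-s pre-stimulus window, with
  `f0_mode="literal"` restoring the single-sample definition. ΔF/F₀ is
  exactly gain-invariant (multiplicative) and deliberately *not* invariant
  to additive offsets; both properties are asserted in tests.
* **Fold change** — post-window mean / pre-window mean, on the
  GCaMP/tdTomato ratio when both channels exist (common multiplicative drift
  then cancels exactly). Pre window ends at step onset; post window opens at
  ramp completion. Responder class: activated/inhibited when
  |post − pre| > 2 baseline SD (configurable k).
* **Saturation experiments** — the post window spans 60 s of sustained
  response (≈ 6 sensor time constants past the ramp). A shorter window mixes
  in the ramp transient: larger steps cross the clamp earlier in the ramp,
  which biases the smallest saturated amplitude one grid step high. Means per
  amplitude are flagged saturated when within 5 % of the dynamic range of the
  largest-amplitude mean on the same side (cool/heat treated separately), and
  a Spearman rank trend across |ΔT| is reported.
* **Gating estimation** — per-window response magnitude is |post − pre| on
  the ratiometric scale, *not* fold change − 1: the diurnal baseline b(zt)
  differs between windows and would contaminate the gain ratio through the
  denominator. Windows default to ZT0–2, ZT6–8 (reference), ZT10–14, ZT17–19;
  CIs are seeded percentile bootstraps (1000 resamples).
* **Clustering** — traces are linearly interpolated onto a common grid at the
  coarsest native rate over the overlapping range (no extrapolation); Pearson
  correlation, average linkage on 1 − r, deterministic scipy leaf order.
  Zero-variance traces are excluded with a warning and reported as missing.

## Diurnal curve stitching

Samples map to ZT = (local time + group shift) mod 24. Bins are 30 min wide
and **centered on the sampling grid** (centers ZT 0.0, 0.5, …, 23.5; edges
±0.25 h; wraparound bin across ZT0): samples taken on the half-hour land at
bin centers, so a noiseless experiment reproduces the planted curve exactly
at the centers. (Behavioral binning, by contrast, uses conventional
left-edge bins [t, t+0.5) — natural for epoch data, 180 epochs per bin.)
Flies are the statistical unit: within-fly means per bin first, then
mean/SEM/n across flies, so the 6-h-window edges where neighboring groups
overlap are pooled at the fly level rather than averaged as averages. Empty
bins stay NaN and are never interpolated. The double plot is purely
presentational (second copy offset +24 h) and round-trips to the identity.

## Sleep scoring and indices

An epoch is inactive when its count ≤ 0 (threshold configurable; the video
tracker's internal threshold is unknown). Runs of ≥ 5 min of inactivity are
sleep bouts; sleep + wake minutes always sum to 1440 per fly-day. The scorer
is verified against an independent brute-force run-length scanner on 10⁴
random fly-days.

Index conventions: window means are taken over the fly's 30-min-binned
series (bins fully inside the half-open ZT window); per-fly indices are then
averaged with SEM across flies. Flies with a zero control-window mean are
excluded with a warning. Pairing is by fly id across condition days. Signs
follow the printed formulas, including the cold E-peak-sleep variant whose
positive direction is a sleep *gain* (flagged in the result metadata), and
the night-sleep-reduction index whose numerator is control − hot.

Group statistics: one-way ANOVA + Tukey HSD (statsmodels), with a two-group
t-test fallback, and a compact letter display computed by insert-and-absorb:
start with one column holding all groups; each significant pair splits every
column containing both; columns contained in another are absorbed. The
construction guarantees two groups share a letter iff their pairwise
comparison is non-significant, verified brute-force over random layouts.
All-tied inputs (zero variance everywhere) skip the test with a message.

## Connectome ranking

Type-level aggregation is primary (matching type-grouped Sankey summaries);
duplicate body pairs are summed on load, untyped bodies become "untyped".
Rankings are sorted by descending summed weight with lexicographic
tie-breaks for determinism. Thresholded weight is conserved
(retained + dropped = source-incident total) and the downstream/upstream
views are dual. The inclusion threshold used by published figures is not
stated; the default is min_weight = 1, echoed in output metadata.

## Determinism and seeding

One master seed; every fly/trace/group draws from a substream keyed by
(seed, generator tag, condition, unit index) — counter-style, so adding
flies never reshuffles earlier ones, and identical config + seed reproduces
outputs byte for byte. Large-n Monte-Carlo oracles use a pooled cohort
stream (vectorized, ~10× faster) since subset reproducibility is irrelevant
for an expectation estimate. CLI runs write a manifest (seed, full parameter
echo, SHA-256 of each output) sufficient to reproduce any artifact; no
timestamps enter outputs.

## Problem sizes

Recovery experiments use n = 64 paired flies per index (6000–10 000
Monte-Carlo flies for sleep expectations), 8 ROIs per step amplitude over a
2 °C grid (20 seeds) for saturation, 12 traces per ZT window over 100 seeded
runs for gating, 6 flies per group for stitching, and 100–200 randomized
layouts for the clustering and compact-letter checks — sizes chosen to match
the study's per-figure n while keeping a full run on one CPU in minutes.

## What the synthetic data does and does not establish

The generator reproduces the *structure* of the study's data: bimodal
diurnal activity with temperature-dependent evening shifts, two-state sleep
architecture, diurnal calcium baseline, circadian-gated saturating step
responses with inhibitory DN1a coupling, and exact planted connectivity. It
omits, among others: inter-fly parameter heterogeneity beyond chain noise,
sensor nonlinearity and motion artifacts, correlated (non-i.i.d.) imaging
noise, activity-dependent bleaching, and any genotype structure. Passing
recovery tests therefore demonstrates that the *estimators are correct and
well-calibrated under the stated model*, not that the model captures every
property of live-fly recordings.

## Known limitations

* All neuron classes share one diurnal baseline b(zt); class-specific phases
  (e.g. DN3 peaking at night) are not modeled.
* The ratio-form indices carry an O(CV²) small-sample bias inherited from
  their published definitions; oracles and tolerances account for it rather
  than redefining the indices.
* The saturation estimate is grid-limited (±2 °C) by design of the stimulus
  protocol.
* `epeak_timing` on flat profiles returns missing values rather than
  guessing a peak.
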