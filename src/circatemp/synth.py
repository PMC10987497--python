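"""Synthetic raw-data generator with planted, recoverable parameters.

Every downstream stage of the pipeline (sleep scoring, behavior indices,
ΔF/F quantification, gating/saturation estimation, curve stitching,
partner ranking) is testable against data generated here, with the ground
truth known exactly.

The generator emulates the study conditions:

* **Locomotion** — per-fly movement counts at 10-s epochs over 24 h. A fly
  alternates wake/sleep via a two-state Markov chain whose transition
  probabilities track a ZT-dependent target wake probability w(ZT); while
  awake it emits Poisson counts at a bimodal diurnal rate λ(ZT) (morning
  and evening Gaussian peaks over a baseline); asleep it emits zero.
  Temperature conditions perturb the evening-peak timing, the night wake
  probability, the siesta depth, and the ZT6-12 rate.
* **Calcium traces** — two-channel (GCaMP + tdTomato) ROI series. Latent
  activity a(t) = b(zt) + s·g(zt)·R(ΔT(t)), where b is the diurnal
  baseline (rising through the day, falling at night), g ≥ 0 the circadian
  gating of the temperature response (weak ZT0-2/6-8, strong
  ZT10-14/17-19), and R the saturating step response
  sign(ΔT)·min(|ΔT|/ΔT_sat, 1) with ΔT_sat = 6 °C for cooling and 8 °C for
  heating. LNd and DN3 latent activity receives a negative coupling from
  the DN1a response (inhibitory DN1a→LNd and DN1a→DN3 links); ablating
  DN1a removes the coupling, leaving a configurable residual direct drive.
  The latent is low-pass filtered with the sensor time constant (exact
  single-pole exponential update), scaled into the GCaMP channel with an
  exponential bleach and additive Gaussian noise; tdTomato carries bleach
  and noise only.
* **Diurnal groups** — four entrainment groups shifted by 0/6/12/18 h,
  each fly sampled at 30-min intervals over 6 h of its local schedule;
  sampled ratiometric values equal b(ZT) + noise.
* **Synapse tables** — connection rows whose per-type-pair summed weights
  reproduce a planted map exactly, with globally unique body ids.

Determinism: one master seed; per-fly / per-trace substreams are derived
from counter-style keys (seed, tag, condition, unit index), so the same
config + seed reproduces outputs bit-for-bit and adding flies never
reshuffles earlier ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .calcium import FluorescenceTrace, TemperatureProtocol
from .diurnal import DiurnalGroup, FlySeries
from .connectome import SynapseTable, from_dataframe
from .sleep import (
    EPOCH_S,
    EPOCHS_PER_DAY,
    ActivityRecord,
    sleep_mask_from_counts,
)

import pandas as pd


class SynthError(ValueError):
    """Raised for invalid generator configuration."""


# substream tags (counter-based seeding)
_TAG_ACTIVITY = 1
_TAG_TRACE = 2
_TAG_DIURNAL = 3
_TAG_SYNAPSE = 4
_TAG_MC = 5

_BATCH = 2000  # flies per vectorized simulation batch


def _cond_key(condition: str) -> int:
    return zlib.crc32(condition.encode()) & 0x7FFFFFFF


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(master_seed) & 0x7FFFFFFF, *map(int, key)])


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

@dataclass
class GaussianPeak:
    """Circular Gaussian activity peak (center/width in ZT hours)."""

    center_h: float
    sigma_h: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.sigma_h <= 0:
            raise SynthError("peak sigma must be > 0")

    def rate(self, zt: np.ndarray) -> np.ndarray:
        d = (np.asarray(zt) - self.center_h + 12.0) % 24.0 - 12.0
        return self.amplitude * np.exp(-0.5 * (d / self.sigma_h) ** 2)


@dataclass
class PiecewiseZT:
    """Piecewise-constant function of ZT on half-open intervals.

    ``edges`` are breakpoints in hours starting at 0 and ending at 24;
    ``values[i]`` applies on [edges[i], edges[i+1]).
    """

    edges: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.values) + 1:
            raise SynthError("need len(edges) == len(values) + 1")
        if self.edges[0] != 0 or self.edges[-1] != 24:
            raise SynthError("edges must span [0, 24]")
        if any(np.diff(self.edges) <= 0):
            raise SynthError("edges must be increasing")

    def __call__(self, zt: np.ndarray) -> np.ndarray:
        zt = np.asarray(zt, dtype=float) % 24.0
        idx = np.searchsorted(self.edges, zt, side="right") - 1
        idx = np.clip(idx, 0, len(self.values) - 1)
        return np.asarray(self.values, dtype=float)[idx]


@dataclass
class ActivityParams:
    """Wake-state Poisson rate model: baseline + morning/evening peaks."""

    baseline_rate: float = 1.0  # counts per 10-s epoch while awake
    morning: GaussianPeak = field(
        default_factory=lambda: GaussianPeak(center_h=0.5, sigma_h=1.0, amplitude=3.0)
    )
    evening: GaussianPeak = field(
        default_factory=lambda: GaussianPeak(center_h=11.0, sigma_h=1.2, amplitude=5.0)
    )
    # wake probability: alert morning, midday siesta, evening ramp-up, night
    wake_prob: PiecewiseZT = field(
        default_factory=lambda: PiecewiseZT(
            edges=(0.0, 4.0, 9.0, 12.0, 24.0), values=(0.85, 0.45, 0.85, 0.3)
        )
    )
    switch_rate: float = 0.02  # per-epoch chain switching scale
    siesta_window: tuple[float, float] = (4.0, 9.0)

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise SynthError("baseline rate must be >= 0")
        if not (0 < self.switch_rate <= 1):
            raise SynthError("switch_rate must be in (0, 1]")
        if any(v < 0 or v > 1 for v in self.wake_prob.values):
            raise SynthError("wake probabilities must lie in [0, 1]")


@dataclass
class TempEffect:
    """How one temperature condition perturbs the diurnal program."""

    dt_evening_h: float = 0.0  # shift of the evening peak center
    d_night_wake: float = 0.0  # added to w(ZT) during ZT12-24
    d_siesta_wake: float = 0.0  # added to w(ZT) in the siesta window
    evening_rate_factor: float = 1.0  # multiplies lambda within ZT6-12


@dataclass
class CalciumParams:
    """Latent-activity model for the two-channel trace generator."""

    baseline_mid: float = 1.0  # diurnal baseline b(ZT) midpoint
    baseline_amp: float = 0.3  # b rises through the day, falls at night
    gating: PiecewiseZT = field(
        default_factory=lambda: PiecewiseZT(
            edges=(0.0, 8.0, 10.0, 20.0, 24.0), values=(0.25, 0.6, 1.0, 0.6)
        )
    )
    gains: dict[str, float] = field(
        default_factory=lambda: {"DN1a": 1.0, "LNd": 0.15, "DN3": 0.15}
    )
    coupling: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("DN1a", "LNd"): -0.6, ("DN1a", "DN3"): -0.8}
    )
    sat_cool_c: float = 6.0  # cooling saturates 6 degC below baseline
    sat_heat_c: float = 8.0  # heating saturates 8 degC above baseline
    tau_sensor_s: float = 10.0
    kappa: float = 0.5  # fluorescence gain per unit latent activity
    f0_gcamp: float = 100.0
    f0_tdtom: float = 100.0
    noise_sd: float = 2.0  # a.u., additive per channel sample
    bleach_tau_s: float = 2000.0
    sample_hz: float = 1.0
    diurnal_noise_sd: float = 0.05  # on the ratiometric scale

    def __post_init__(self) -> None:
        if self.tau_sensor_s <= 0:
            raise SynthError("tau_sensor_s must be > 0")
        if self.f0_gcamp <= 0 or self.f0_tdtom <= 0:
            raise SynthError("F0 values must be > 0")
        if any(v < 0 for v in self.gating.values):
            raise SynthError("gating profile must be >= 0")
        if self.sat_cool_c <= 0 or self.sat_heat_c <= 0:
            raise SynthError("saturation limits must be > 0")

    def baseline(self, zt: np.ndarray) -> np.ndarray:
        """Diurnal calcium baseline b(ZT): minimum at ZT0, peak at ZT12."""
        zt = np.asarray(zt, dtype=float)
        return self.baseline_mid + self.baseline_amp * np.sin(
            2 * np.pi * (zt - 6.0) / 24.0
        )


def default_temp_effects() -> dict[str, TempEffect]:
    """Study conditions: 24/22 °C controls, 18 °C cooling day, 30 °C heating day.

    Cooling advances the evening peak by 1 h, boosts the ZT6-12 rate by
    30%, lightens the siesta and deepens night sleep; heating delays the
    evening peak, raises night wakefulness and deepens the siesta.
    """
    return {
        "24C": TempEffect(),
        "22C": TempEffect(),
        "18C": TempEffect(
            dt_evening_h=-1.0,
            evening_rate_factor=1.3,
            d_siesta_wake=+0.2,
            d_night_wake=-0.1,
        ),
        "30C": TempEffect(
            dt_evening_h=+1.5,
            d_night_wake=+0.3,
            d_siesta_wake=-0.15,
        ),
    }


@dataclass
class SynthConfig:
    """Master configuration for all synthetic-data generators."""

    master_seed: int = 0
    n_flies: int = 8
    n_days: int = 1
    lights_on_zt: float = 0.0
    lights_off_zt: float = 12.0
    epoch_s: int = EPOCH_S
    activity: ActivityParams = field(default_factory=ActivityParams)
    temp_effects: dict[str, TempEffect] = field(default_factory=default_temp_effects)
    calcium: CalciumParams = field(default_factory=CalciumParams)
    ablate_dn1a: bool = False

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise SynthError("n_flies must be >= 1")
        if self.epoch_s != EPOCH_S:
            raise SynthError(f"epoch length is fixed at {EPOCH_S} s")

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, master_seed=seed)


# ---------------------------------------------------------------------------
# Locomotion generation
# ---------------------------------------------------------------------------

def _epoch_zt() -> np.ndarray:
    return np.arange(EPOCHS_PER_DAY) * (EPOCH_S / 3600.0)


def _condition_effect(config: SynthConfig, condition: str) -> TempEffect:
    if condition not in config.temp_effects:
        raise SynthError(
            f"unknown condition {condition!r}; valid labels: "
            f"{sorted(config.temp_effects)}"
        )
    return config.temp_effects[condition]


def condition_rate(config: SynthConfig, condition: str, zt: np.ndarray) -> np.ndarray:
    """Awake Poisson rate λ(ZT) under a temperature condition (counts/epoch)."""
    eff = _condition_effect(config, condition)
    act = config.activity
    evening = GaussianPeak(
        center_h=(act.evening.center_h + eff.dt_evening_h) % 24.0,
        sigma_h=act.evening.sigma_h,
        amplitude=act.evening.amplitude,
    )
    lam = act.baseline_rate + act.morning.rate(zt) + evening.rate(zt)
    zt = np.asarray(zt, dtype=float) % 24.0
    in_epeak = (zt >= 6.0) & (zt < 12.0)
    return np.where(in_epeak, lam * eff.evening_rate_factor, lam)


def condition_wake_prob(
    config: SynthConfig, condition: str, zt: np.ndarray
) -> np.ndarray:
    """Target wake probability w(ZT) under a condition, clipped to [0, 1]."""
    eff = _condition_effect(config, condition)
    act = config.activity
    zt = np.asarray(zt, dtype=float) % 24.0
    w = act.wake_prob(zt)
    night = (zt >= 12.0) & (zt < 24.0)
    lo, hi = act.siesta_window
    siesta = (zt >= lo) & (zt < hi)
    w = w + eff.d_night_wake * night + eff.d_siesta_wake * siesta
    return np.clip(w, 0.0, 1.0)


def _chain_counts(
    uni: np.ndarray, pois: np.ndarray, init: np.ndarray, w0: float,
    p_entry: np.ndarray, p_exit: np.ndarray,
) -> np.ndarray:
    """Run the wake/sleep chain over pre-drawn randoms (rows = flies)."""
    n = uni.shape[0]
    state = init < w0
    counts = np.empty_like(pois)
    for t in range(uni.shape[1]):
        counts[:, t] = pois[:, t] * state
        stay_awake = state & (uni[:, t] >= p_entry[t])
        wake_up = (~state) & (uni[:, t] < p_exit[t])
        state = stay_awake | wake_up
    return counts


def _chain_params(config: SynthConfig, condition: str):
    zt = _epoch_zt()
    lam = condition_rate(config, condition, zt)
    w = condition_wake_prob(config, condition, zt)
    r = config.activity.switch_rate
    return lam, w, r * (1.0 - w), r * w  # lam, w, p_entry, p_exit


def _simulate_counts(
    config: SynthConfig,
    condition: str,
    fly_indices: np.ndarray,
    day: int,
    tag: int,
    extra_key: int = 0,
) -> np.ndarray:
    """Simulate (n_flies, 8640) count matrix with per-fly substreams.

    Randomness for fly *i* comes exclusively from the substream keyed by
    (master_seed, tag, condition, extra_key, day, i): simulating any subset
    of flies reproduces exactly the rows it shares with a larger run.
    """
    lam, w, p_entry, p_exit = _chain_params(config, condition)
    ckey = _cond_key(condition)
    out = np.empty((fly_indices.size, EPOCHS_PER_DAY), dtype=np.int64)
    for b0 in range(0, fly_indices.size, _BATCH):
        batch = fly_indices[b0 : b0 + _BATCH]
        n = batch.size
        uni = np.empty((n, EPOCHS_PER_DAY))
        pois = np.empty((n, EPOCHS_PER_DAY), dtype=np.int64)
        init = np.empty(n)
        for row, fly in enumerate(batch):
            g = _rng(config.master_seed, tag, ckey, extra_key, day, int(fly))
            init[row] = g.random()
            uni[row] = g.random(EPOCHS_PER_DAY)
            pois[row] = g.poisson(lam)
        out[b0 : b0 + n] = _chain_counts(uni, pois, init, w[0], p_entry, p_exit)
    return out


def _simulate_counts_pooled(
    config: SynthConfig, condition: str, n_flies: int, extra_key: int = 0
) -> np.ndarray:
    """Fast pooled-stream simulation for large-n Monte-Carlo oracles.

    Single substream for the whole cohort with vectorized draws — roughly
    an order of magnitude faster than the per-fly-stream generator, at the
    cost of the subset-reproducibility guarantee (irrelevant for an
    expectation estimate). Statistically identical to
    :func:`_simulate_counts`.
    """
    lam, w, p_entry, p_exit = _chain_params(config, condition)
    g = _rng(config.master_seed, _TAG_MC, _cond_key(condition), extra_key)
    out = np.empty((n_flies, EPOCHS_PER_DAY), dtype=np.int64)
    for b0 in range(0, n_flies, _BATCH):
        n = min(_BATCH, n_flies - b0)
        init = g.random(n)
        uni = g.random((n, EPOCHS_PER_DAY))
        pois = g.poisson(lam[None, :], size=(n, EPOCHS_PER_DAY))
        out[b0 : b0 + n] = _chain_counts(uni, pois, init, w[0], p_entry, p_exit)
    return out


def gen_activity(
    config: SynthConfig,
    condition: str,
    n_flies: int | None = None,
    n_days: int | None = None,
) -> list[ActivityRecord]:
    """Generate one ActivityRecord per fly per day under a condition."""
    _condition_effect(config, condition)  # validate label early
    n_flies = config.n_flies if n_flies is None else n_flies
    n_days = config.n_days if n_days is None else n_days
    if n_flies < 1:
        raise SynthError("n_flies must be >= 1")
    records: list[ActivityRecord] = []
    indices = np.arange(n_flies)
    for day in range(n_days):
        counts = _simulate_counts(config, condition, indices, day, _TAG_ACTIVITY)
        for i in range(n_flies):
            records.append(
                ActivityRecord(
                    fly_id=f"fly{i:04d}",
                    temp_condition=condition,
                    counts=counts[i],
                    day_index=day,
                    lights_on_zt=config.lights_on_zt,
                    lights_off_zt=config.lights_off_zt,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Expectation oracle
# ---------------------------------------------------------------------------

@dataclass
class WindowExpectation:
    """Large-sample expected per-bin window mean, with the method used."""

    value: float
    method: str
    window_zt: tuple[float, float]
    condition: str
    measure: str


def _window_bin_slices(window_zt: tuple[float, float], bin_min: int = 30):
    width_h = bin_min / 60.0
    per_bin = bin_min * 60 // EPOCH_S
    lo, hi = window_zt
    lefts = np.arange(0, 24, width_h)
    idx = np.flatnonzero((lefts >= lo - 1e-9) & (lefts + width_h <= hi + 1e-9))
    return idx, per_bin


def wake_probability_profile(config: SynthConfig, condition: str) -> np.ndarray:
    """Marginal P(awake) per epoch from the two-state chain, analytically.

    Forward iteration of the chain's marginal starting from the target wake
    probability at ZT0 — the same initial law the simulator uses.
    """
    zt = _epoch_zt()
    w = condition_wake_prob(config, condition, zt)
    r = config.activity.switch_rate
    p_entry = r * (1.0 - w)
    p_exit = r * w
    p = np.empty(EPOCHS_PER_DAY)
    p[0] = w[0]
    for t in range(EPOCHS_PER_DAY - 1):
        p[t + 1] = p[t] * (1.0 - p_entry[t]) + (1.0 - p[t]) * p_exit[t]
    return p


def expected_window_mean(
    config: SynthConfig,
    condition: str,
    window_zt: tuple[float, float],
    measure: str = "activity",
    bin_min: int = 30,
    n_mc: int = 50_000,
    mc_seed: int = 0,
) -> WindowExpectation:
    """Large-sample expectation of the per-bin window mean under a condition.

    * ``measure="activity"`` — analytic: per-epoch expected count is
      λ(ZT) × P(awake at ZT), with P(awake) from deterministic forward
      iteration of the two-state chain; expected bin sums are summed per
      30-min bin and averaged over the bins inside the window.
    * ``measure="sleep"`` — scored sleep (5-min rule) has no closed form
      because wake epochs can emit zero counts; a Monte-Carlo estimate over
      ``n_mc`` simulated flies is used and the method string reports it.
    """
    idx, per_bin = _window_bin_slices(window_zt, bin_min)
    if idx.size == 0:
        raise SynthError(f"window {window_zt} contains no whole {bin_min}-min bin")
    if measure == "activity":
        zt = _epoch_zt()
        lam = condition_rate(config, condition, zt)
        p = wake_probability_profile(config, condition)
        expected_epoch = lam * p
        bin_sums = expected_epoch.reshape(-1, per_bin).sum(axis=1)
        return WindowExpectation(
            value=float(bin_sums[idx].mean()),
            method="analytic (chain marginals x Poisson rate)",
            window_zt=window_zt,
            condition=condition,
            measure=measure,
        )
    if measure == "sleep":
        counts = _simulate_counts_pooled(config, condition, n_mc, extra_key=mc_seed)
        min_per_epoch = EPOCH_S / 60.0
        vals = np.empty(n_mc)
        for i in range(n_mc):
            mask, _ = sleep_mask_from_counts(counts[i])
            per_bin_sleep = mask.reshape(-1, per_bin).sum(axis=1) * min_per_epoch
            vals[i] = per_bin_sleep[idx].mean()
        return WindowExpectation(
            value=float(vals.mean()),
            method=f"monte-carlo (n={n_mc} simulated flies)",
            window_zt=window_zt,
            condition=condition,
            measure=measure,
        )
    raise SynthError(f"unknown measure {measure!r}")


def expected_sleep_window_means(
    config: SynthConfig,
    condition: str,
    windows: list[tuple[float, float]],
    bin_min: int = 30,
    n_mc: int = 10_000,
    mc_seed: int = 0,
) -> dict[tuple[float, float], WindowExpectation]:
    """Monte-Carlo expected sleep window means, one simulation per condition.

    Same estimator as ``expected_window_mean(measure="sleep")`` but the
    ``n_mc`` simulated flies are shared across all requested windows.
    """
    counts = _simulate_counts_pooled(config, condition, n_mc, extra_key=mc_seed)
    min_per_epoch = EPOCH_S / 60.0
    per_bin = bin_min * 60 // EPOCH_S
    sleep_bins = np.empty((n_mc, EPOCHS_PER_DAY // per_bin))
    for i in range(n_mc):
        mask, _ = sleep_mask_from_counts(counts[i])
        sleep_bins[i] = mask.reshape(-1, per_bin).sum(axis=1) * min_per_epoch
    out = {}
    for window in windows:
        idx, _ = _window_bin_slices(window, bin_min)
        if idx.size == 0:
            raise SynthError(f"window {window} contains no whole {bin_min}-min bin")
        out[window] = WindowExpectation(
            value=float(sleep_bins[:, idx].mean(axis=1).mean()),
            method=f"monte-carlo (n={n_mc} simulated flies)",
            window_zt=window,
            condition=condition,
            measure="sleep",
        )
    return out


# ---------------------------------------------------------------------------
# Two-channel calcium traces
# ---------------------------------------------------------------------------

def response_curve(
    delta_t: np.ndarray, sat_cool_c: float, sat_heat_c: float
) -> np.ndarray:
    """Saturating step response R(ΔT) = sign(ΔT)·min(|ΔT|/ΔT_sat, 1)."""
    dt = np.asarray(delta_t, dtype=float)
    heat = np.minimum(dt / sat_heat_c, 1.0)
    cool = -np.minimum(-dt / sat_cool_c, 1.0)
    return np.where(dt >= 0, heat, cool)


def _lowpass(signal: np.ndarray, dt_s: float, tau_s: float) -> np.ndarray:
    """Single-pole low-pass, exact exponential update (zero-order hold)."""
    alpha = np.exp(-dt_s / tau_s)
    out = np.empty_like(signal)
    out[0] = signal[0]
    for i in range(1, signal.size):
        out[i] = signal[i] + (out[i - 1] - signal[i]) * alpha
    return out


def latent_activity(
    config: SynthConfig,
    protocol: TemperatureProtocol,
    zt: float,
    neuron_class: str,
    times: np.ndarray,
    filtered: bool = True,
) -> np.ndarray:
    """Noise-free latent activity a(t) for one neuron class.

    This is the deterministic core of the trace generator and doubles as
    the closed-form oracle for response-recovery tests: the expected
    GCaMP/tdTomato ratio is ``(f0_gcamp/f0_tdtom)·(1 + κ·a_filtered)``.
    """
    cal = config.calcium
    if neuron_class not in cal.gains:
        raise SynthError(
            f"unknown neuron class {neuron_class!r}; known: {sorted(cal.gains)}"
        )
    temp = protocol.temperature(times)
    r_t = response_curve(temp - protocol.baseline_c, cal.sat_cool_c, cal.sat_heat_c)
    g = float(cal.gating(np.array([zt]))[0])
    b = float(cal.baseline(np.array([zt]))[0])
    a = b + cal.gains[neuron_class] * g * r_t
    w_c = cal.coupling.get(("DN1a", neuron_class), 0.0)
    if w_c != 0.0 and not config.ablate_dn1a:
        a = a + w_c * (cal.gains["DN1a"] * g * r_t)
    if not filtered:
        return a
    dt_s = float(np.median(np.diff(times)))
    return _lowpass(a, dt_s, cal.tau_sensor_s)


def gen_two_channel_traces(
    config: SynthConfig,
    protocol: TemperatureProtocol,
    zt: float,
    neuron_classes: tuple[str, ...] = ("DN1a",),
    n_per_class: int = 1,
) -> list[tuple[FluorescenceTrace, FluorescenceTrace]]:
    """Generate (GCaMP, tdTomato) trace pairs for a temperature protocol.

    Each ROI gets its own noise substream keyed by (class, ROI index, zt),
    so regenerating a subset reproduces the shared ROIs exactly.
    """
    cal = config.calcium
    for s in protocol.steps:
        if s[0] + s[2] > protocol.recording_span_s:
            raise SynthError("protocol steps must lie within the recording span")
    times = np.arange(0.0, protocol.recording_span_s, 1.0 / cal.sample_hz)
    bleach = np.exp(-times / cal.bleach_tau_s)
    pairs: list[tuple[FluorescenceTrace, FluorescenceTrace]] = []
    for ci, cls in enumerate(neuron_classes):
        a_f = latent_activity(config, protocol, zt, cls, times)
        for roi in range(n_per_class):
            g = _rng(
                config.master_seed, _TAG_TRACE, _cond_key(cls),
                int(round(zt * 100)), ci, roi,
            )
            gcamp = cal.f0_gcamp * (1.0 + cal.kappa * a_f) * bleach
            tdtom = cal.f0_tdtom * bleach
            if cal.noise_sd > 0:
                gcamp = gcamp + g.normal(0.0, cal.noise_sd, times.size)
                tdtom = tdtom + g.normal(0.0, cal.noise_sd, times.size)
            roi_id = f"{cls}_zt{zt:g}_{roi:02d}"
            pairs.append(
                (
                    FluorescenceTrace(roi_id, cls, "GCaMP", times, gcamp, zt),
                    FluorescenceTrace(roi_id, cls, "tdTomato", times, tdtom, zt),
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# Diurnal groups
# ---------------------------------------------------------------------------

DIURNAL_SHIFTS = (0.0, 6.0, 12.0, 18.0)


def gen_diurnal_groups(
    config: SynthConfig,
    n_flies_per_group: int = 6,
) -> list[DiurnalGroup]:
    """Four phase-shifted groups sampled at 30-min intervals over 6 h.

    The planted truth is the diurnal baseline b(ZT): each sample's
    GCaMP/tdTomato ratio is b(ZT) + Gaussian noise
    (``calcium.diurnal_noise_sd``); both raw channels carry a slow common
    bleach that the ratio cancels.
    """
    cal = config.calcium
    local = np.arange(0.0, 6.0 + 1e-9, 0.5)  # 13 samples, 0..6 h inclusive
    groups: list[DiurnalGroup] = []
    for gi, shift in enumerate(DIURNAL_SHIFTS):
        flies: list[FlySeries] = []
        for fi in range(n_flies_per_group):
            g = _rng(config.master_seed, _TAG_DIURNAL, gi, fi)
            zt = (local + shift) % 24.0
            ratio = cal.baseline(zt)
            if cal.diurnal_noise_sd > 0:
                ratio = ratio + g.normal(0.0, cal.diurnal_noise_sd, local.size)
            ratio = np.maximum(ratio, 1e-6)
            bleach = np.exp(-local / 50.0)  # mild common-mode drift over 6 h
            tdtom = cal.f0_tdtom * bleach
            gcamp = ratio * tdtom
            flies.append(
                FlySeries(
                    fly_id=f"g{gi}_fly{fi:02d}",
                    local_time_h=local.copy(),
                    gcamp=gcamp,
                    tdtom=tdtom,
                )
            )
        groups.append(DiurnalGroup(shift_h=shift, flies=flies))
    return groups


# ---------------------------------------------------------------------------
# Synapse tables
# ---------------------------------------------------------------------------

def gen_synapse_table(
    config: SynthConfig,
    planted: dict[tuple[str, str], int],
) -> SynapseTable:
    """Connection rows whose per-type-pair summed weights equal ``planted``.

    Each planted (pre type, post type, weight) is split across one to three
    body pairs with unique body ids; occasionally a body pair is emitted as
    two rows to exercise duplicate summing on load. An empty map yields an
    empty (but well-formed) table.
    """
    g = _rng(config.master_seed, _TAG_SYNAPSE)
    rows = []
    next_body = 100_000
    for (pre_t, post_t) in sorted(planted):
        w = int(planted[(pre_t, post_t)])
        if w < 1:
            raise SynthError(f"planted weight for {pre_t}->{post_t} must be >= 1")
        m = int(g.integers(1, min(3, w) + 1))
        parts = g.multinomial(w - m, [1.0 / m] * m) + 1
        for part in parts:
            pre_b, post_b = next_body, next_body + 1
            next_body += 2
            part = int(part)
            if part >= 2 and g.random() < 0.3:  # duplicate body pair split
                cut = int(g.integers(1, part))
                rows.append((pre_b, pre_t, post_b, post_t, cut))
                rows.append((pre_b, pre_t, post_b, post_t, part - cut))
            else:
                rows.append((pre_b, pre_t, post_b, post_t, part))
    df = pd.DataFrame(rows, columns=["bodyId_pre", "type_pre", "bodyId_post",
                                     "type_post", "weight"])
    if df.empty:
        df = pd.DataFrame(
            {c: pd.Series(dtype="int64" if "Id" in c or c == "weight" else "object")
             for c in ["bodyId_pre", "type_pre", "bodyId_post", "type_post", "weight"]}
        )
    return from_dataframe(df)
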