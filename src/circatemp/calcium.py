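"""Quantification of two-photon calcium traces.

Operations here turn raw per-ROI fluorescence time series into the standard
derived quantities of stimulus-evoked calcium imaging: fractional change
ΔF/F0 (in percent), peak response ΔFmax/F0, pre/post window statistics of a
temperature-step response (fold change, responder class), saturation of the
response across step amplitudes, trace correlation/clustering, and the
paired comparison of locomotion speed around a temperature event.

ΔF/F0 is exactly (F_t − F0)/F0 × 100 where F0 is the baseline fluorescence.
The literal "fluorescence at time 0" definition is noise-fragile, so the
default F0 is a mean over a pre-stimulus baseline window; ``f0_mode="literal"``
restores the single-sample definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage


class CalciumError(ValueError):
    """Raised for non-physical or inconsistent fluorescence inputs."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FluorescenceTrace:
    """One ROI/channel fluorescence time series in arbitrary units.

    Parameters
    ----------
    roi_id : str
        Identifier of the region of interest.
    neuron_class : str
        Neuron-class label attached to the ROI (metadata only).
    channel : str
        ``"GCaMP"`` (calcium-sensitive) or ``"tdTomato"`` (insensitive).
    times : array of float
        Sample times in seconds, strictly increasing.
    values : array of float
        Fluorescence in arbitrary units, finite and nonnegative.
    zt : float
        Zeitgeber time (hours since lights-on) of the recording.
    """

    roi_id: str
    neuron_class: str
    channel: str
    times: np.ndarray
    values: np.ndarray
    zt: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size < 2:
            raise CalciumError("trace needs at least 2 samples")
        if self.times.size != self.values.size:
            raise CalciumError("times and values length mismatch")
        if not np.all(np.diff(self.times) > 0):
            raise CalciumError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise CalciumError("values must be finite")


@dataclass
class TemperatureProtocol:
    """Baseline temperature plus ramped steps.

    Each step is ``(onset_s, target_c, ramp_s)``: starting at ``onset_s`` the
    chamber temperature ramps linearly from its current value to ``target_c``
    over ``ramp_s`` seconds (the Peltier stage reaches the target in roughly
    80 s, the default ramp).
    """

    baseline_c: float
    steps: list[tuple[float, float, float]]
    recording_span_s: float

    def __post_init__(self) -> None:
        onsets = [s[0] for s in self.steps]
        if any(np.diff(onsets) <= 0):
            raise CalciumError("step onsets must be increasing")
        for onset, _target, ramp in self.steps:
            if ramp <= 0:
                raise CalciumError("ramp_s must be positive")
            if onset < 0 or onset + ramp > self.recording_span_s:
                raise CalciumError("step outside recording span")

    def temperature(self, times: np.ndarray) -> np.ndarray:
        """Chamber temperature (°C) at each time, piecewise-linear ramps."""
        times = np.asarray(times, dtype=float)
        temp = np.full_like(times, self.baseline_c)
        current = self.baseline_c
        for onset, target, ramp in self.steps:
            frac = np.clip((times - onset) / ramp, 0.0, 1.0)
            temp = np.where(times >= onset, current + frac * (target - current), temp)
            current = target
        return temp

    def delta_t(self, step_index: int) -> float:
        """ΔT of a step relative to the protocol baseline."""
        return self.steps[step_index][1] - self.baseline_c


@dataclass
class DeltaFTrace:
    """ΔF/F0 series in percent, with the baseline used to compute it."""

    roi_id: str
    times: np.ndarray
    dff: np.ndarray
    f0: float
    baseline_window: tuple[float, float]
    neuron_class: str = ""
    zt: float = 0.0


@dataclass
class TemperatureResponse:
    """Pre/post window summary of one ROI's response to one temperature step."""

    roi_id: str
    neuron_class: str
    zt: float
    delta_t_c: float
    pre_mean: float
    post_mean: float
    fold_change: float
    max_dff: float
    response_class: str  # activated | inhibited | nonresponsive
    baseline_sd: float

    @property
    def magnitude(self) -> float:
        """Signed response amplitude post − pre (ratiometric units if
        a tdTomato partner was supplied)."""
        return self.post_mean - self.pre_mean


@dataclass
class LocomotionEpisode:
    """Ball-rotation speed around a temperature event for one fly.

    ``speed`` is the tracked rotation speed (units/s); the tracking itself is
    an input, not performed here.
    """

    fly_id: str
    times: np.ndarray
    speed: np.ndarray
    event_s: float
    pre_window_s: float
    post_window_s: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.event_s - self.pre_window_s < self.times[0] - 1e-9 or (
            self.event_s + self.post_window_s > self.times[-1] + 1e-9
        ):
            raise CalciumError("pre/post windows fall outside the speed series")

    def pre_mean(self) -> float:
        m = (self.times >= self.event_s - self.pre_window_s) & (self.times < self.event_s)
        return float(np.mean(self.speed[m]))

    def post_mean(self) -> float:
        m = (self.times >= self.event_s) & (self.times < self.event_s + self.post_window_s)
        return float(np.mean(self.speed[m]))


@dataclass
class ClusterResult:
    """Correlation matrix + hierarchical clustering of ΔF/F traces."""

    corr: pd.DataFrame
    leaf_order: list[str]
    labels: dict[str, int]
    linkage_matrix: np.ndarray
    excluded: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def compute_dff(
    trace: FluorescenceTrace,
    baseline_window: tuple[float, float],
    f0_mode: str = "window",
) -> DeltaFTrace:
    """ΔF/F0 in percent: (F_t − F0)/F0 × 100.

    ``f0_mode="window"`` (default) takes F0 as the mean of samples inside
    ``baseline_window`` (half-open, seconds); ``"literal"`` takes the first
    sample of the window, reproducing the fluorescence-at-time-0 definition.
    The result is invariant to multiplying the whole trace by any positive
    constant; it is *not* invariant to additive offsets.
    """
    lo, hi = baseline_window
    mask = (trace.times >= lo) & (trace.times < hi)
    if not mask.any():
        raise CalciumError(f"baseline window [{lo}, {hi}) contains no samples")
    if f0_mode == "window":
        f0 = float(np.mean(trace.values[mask]))
    elif f0_mode == "literal":
        f0 = float(trace.values[mask][0])
    else:
        raise CalciumError(f"unknown f0_mode {f0_mode!r}")
    if f0 <= 0:
        raise CalciumError(f"non-physical baseline F0={f0} (must be > 0)")
    dff = (trace.values - f0) / f0 * 100.0
    return DeltaFTrace(
        roi_id=trace.roi_id,
        times=trace.times.copy(),
        dff=dff,
        f0=f0,
        baseline_window=(lo, hi),
        neuron_class=trace.neuron_class,
        zt=trace.zt,
    )


def compute_max_dff(
    dff: DeltaFTrace,
    response_window: tuple[float, float],
    signed_extremum: bool = False,
) -> float:
    """ΔFmax/F0 in percent within a half-open response window.

    By default returns the maximum of ΔF/F in the window. With
    ``signed_extremum=True`` returns the sample with the largest absolute
    value with its sign preserved, which is the appropriate summary for
    inhibitory responses.
    """
    lo, hi = response_window
    mask = (dff.times >= lo) & (dff.times < hi)
    if not mask.any():
        raise CalciumError(f"response window [{lo}, {hi}) contains no samples")
    vals = dff.dff[mask]
    if signed_extremum:
        return float(vals[np.argmax(np.abs(vals))])
    return float(np.max(vals))


def quantify_step_response(
    trace: FluorescenceTrace,
    protocol: TemperatureProtocol,
    step_index: int,
    pre_s: float = 30.0,
    post_s: float = 30.0,
    tdtom: FluorescenceTrace | None = None,
    k_sd: float = 2.0,
) -> TemperatureResponse:
    """Pre/post window summary of one temperature step.

    The pre window is ``[onset − pre_s, onset)`` and the post window
    ``[onset + ramp, onset + ramp + post_s)`` — the post window opens only
    after the ramp completes. ``fold_change = post_mean / pre_mean`` on raw
    GCaMP fluorescence, or on the GCaMP/tdTomato ratio when a tdTomato
    partner is supplied (the ratio cancels common multiplicative drift).
    The responder class compares post − pre against ``k_sd`` baseline SDs:
    activated above, inhibited below, nonresponsive otherwise.
    """
    if step_index < 0 or step_index >= len(protocol.steps):
        raise CalciumError(
            f"step_index {step_index} out of range for {len(protocol.steps)} steps"
        )
    onset, _target, ramp = protocol.steps[step_index]
    pre_lo, pre_hi = onset - pre_s, onset
    post_lo, post_hi = onset + ramp, onset + ramp + post_s
    if pre_hi > post_lo:
        raise CalciumError("pre and post windows overlap")

    values = trace.values
    if tdtom is not None:
        if tdtom.times.size != trace.times.size or not np.allclose(
            tdtom.times, trace.times
        ):
            raise CalciumError("tdTomato partner must share the GCaMP time base")
        if np.any(tdtom.values <= 0):
            raise CalciumError("tdTomato values must be positive for ratiometry")
        values = values / tdtom.values

    t = trace.times
    pre_mask = (t >= pre_lo) & (t < pre_hi)
    post_mask = (t >= post_lo) & (t < post_hi)
    if not pre_mask.any() or not post_mask.any():
        raise CalciumError("pre or post window contains no samples")

    pre_mean = float(np.mean(values[pre_mask]))
    post_mean = float(np.mean(values[post_mask]))
    baseline_sd = float(np.std(values[pre_mask], ddof=1)) if pre_mask.sum() > 1 else 0.0
    if pre_mean <= 0:
        raise CalciumError("non-positive pre-window mean; cannot form fold change")
    fold = post_mean / pre_mean

    diff = post_mean - pre_mean
    if diff > k_sd * baseline_sd and diff > 0:
        cls = "activated"
    elif diff < -k_sd * baseline_sd and diff < 0:
        cls = "inhibited"
    else:
        cls = "nonresponsive"

    # max |ΔF/F| (signed) in the post window, baseline = pre window
    dff = (values - pre_mean) / pre_mean * 100.0
    post_vals = dff[post_mask]
    max_dff = float(post_vals[np.argmax(np.abs(post_vals))])

    return TemperatureResponse(
        roi_id=trace.roi_id,
        neuron_class=trace.neuron_class,
        zt=trace.zt,
        delta_t_c=protocol.delta_t(step_index),
        pre_mean=pre_mean,
        post_mean=post_mean,
        fold_change=fold,
        max_dff=max_dff,
        response_class=cls,
        baseline_sd=baseline_sd,
    )


def saturation_summary(
    responses: list[TemperatureResponse],
    tol_frac: float = 0.05,
) -> pd.DataFrame:
    """Mean response ± SEM per step amplitude, with saturation flags.

    Groups responses by signed ΔT, computes mean/SEM of the response
    magnitude (post − pre), and — separately for cooling and heating —
    flags an amplitude as saturated when its mean lies within
    ``tol_frac`` × dynamic range of the largest-amplitude mean on the same
    side. Also reports a Spearman rank trend of |response| vs |ΔT| per side.
    Requires at least two distinct ΔT values.
    """
    if len({r.delta_t_c for r in responses}) < 2:
        raise CalciumError("need responses at >= 2 distinct delta-T values")
    df = pd.DataFrame(
        {
            "delta_t_c": [r.delta_t_c for r in responses],
            "magnitude": [r.magnitude for r in responses],
        }
    )
    rows = []
    for sign, side in ((-1, "cooling"), (1, "heating")):
        sub = df[np.sign(df["delta_t_c"]) == sign]
        if sub.empty:
            continue
        g = sub.groupby("delta_t_c")["magnitude"]
        means = g.mean()
        sems = g.sem(ddof=1)  # NaN when n == 1 (SEM undefined)
        ns = g.size()
        abs_dt = np.abs(means.index.to_numpy())
        order = np.argsort(abs_dt)
        m = np.abs(means.to_numpy()[order])
        rng = m.max() - m.min()
        ref = m[-1]  # largest |ΔT| on this side
        saturated = np.abs(m - ref) <= tol_frac * rng if rng > 0 else np.ones_like(m, bool)
        if len(sub["delta_t_c"].unique()) > 1:
            rho, trend_p = stats.spearmanr(np.abs(sub["delta_t_c"]), np.abs(sub["magnitude"]))
        else:
            rho, trend_p = np.nan, np.nan
        for i, idx in enumerate(order):
            dt = means.index[idx]
            rows.append(
                {
                    "side": side,
                    "delta_t_c": dt,
                    "abs_delta_t_c": abs(dt),
                    "mean": means.iloc[idx],
                    "sem": sems.iloc[idx],
                    "n": int(ns.iloc[idx]),
                    "saturated": bool(saturated[i]),
                    "trend_rho": rho,
                    "trend_p": trend_p,
                }
            )
    return pd.DataFrame(rows)


def estimate_saturation_point(summary: pd.DataFrame, side: str) -> float:
    """Smallest |ΔT| flagged as saturated on a side ('cooling'/'heating')."""
    sub = summary[(summary["side"] == side) & summary["saturated"]]
    if sub.empty:
        return float("nan")
    return float(sub["abs_delta_t_c"].min())


def correlate_and_cluster(
    dff_set: list[DeltaFTrace],
    n_clusters: int = 2,
) -> ClusterResult:
    """Pairwise Pearson correlation + average-linkage clustering on 1 − r.

    Traces are resampled by linear interpolation onto a common grid at the
    coarsest native rate over the overlapping time range (no extrapolation).
    Zero-variance traces cannot be correlated: they are reported as missing
    and excluded from clustering with a warning. Leaf order is the
    deterministic scipy dendrogram order.
    """
    if len(dff_set) < 2:
        raise CalciumError("need at least 2 traces")
    ids = [d.roi_id for d in dff_set]
    if len(set(ids)) != len(ids):
        raise CalciumError("roi_id values must be unique")

    dt = max(float(np.median(np.diff(d.times))) for d in dff_set)
    lo = max(d.times[0] for d in dff_set)
    hi = min(d.times[-1] for d in dff_set)
    if hi <= lo:
        raise CalciumError("traces share no overlapping time range")
    grid = np.arange(lo, hi + dt / 2, dt)
    mat = np.vstack([np.interp(grid, d.times, d.dff) for d in dff_set])

    variances = mat.var(axis=1)
    excluded = [ids[i] for i in np.flatnonzero(variances == 0)]
    if excluded:
        warnings.warn(
            f"zero-variance traces excluded from clustering: {excluded}",
            stacklevel=2,
        )
    keep = [i for i in range(len(ids)) if ids[i] not in excluded]
    if len(keep) < 2:
        raise CalciumError("fewer than 2 traces with nonzero variance")

    corr_full = pd.DataFrame(np.nan, index=ids, columns=ids)
    sub = np.corrcoef(mat[keep])
    kept_ids = [ids[i] for i in keep]
    corr_full.loc[kept_ids, kept_ids] = sub

    dist = 1.0 - sub
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    condensed = dist[np.triu_indices(len(keep), k=1)]
    z = linkage(condensed, method="average")
    order = [kept_ids[i] for i in leaves_list(z)]
    flat = fcluster(z, t=n_clusters, criterion="maxclust")
    labels = {kept_ids[i]: int(flat[i]) for i in range(len(kept_ids))}
    return ClusterResult(
        corr=corr_full, leaf_order=order, labels=labels, linkage_matrix=z,
        excluded=excluded,
    )


def locomotion_change(episodes: list[LocomotionEpisode]) -> dict:
    """Paired pre/post mean speeds across flies with a paired t-test.

    Returns per-fly pre/post means, the group mean difference, and the
    two-sided paired t-test p-value (scipy ``ttest_rel``). With fewer than
    two flies only the means are reported. Degenerate zero-variance
    differences are resolved exactly: all-zero differences give p = 1,
    identical nonzero differences give p = 0.
    """
    if not episodes:
        raise CalciumError("no episodes supplied")
    pre = np.array([e.pre_mean() for e in episodes])
    post = np.array([e.post_mean() for e in episodes])
    diff = post - pre
    out = {
        "fly_ids": [e.fly_id for e in episodes],
        "pre_means": pre,
        "post_means": post,
        "mean_difference": float(np.mean(diff)),
        "n": len(episodes),
        "p_value": None,
    }
    if len(episodes) >= 2:
        if np.std(diff, ddof=1) == 0:
            out["p_value"] = 1.0 if np.allclose(diff, 0) else 0.0
        else:
            out["p_value"] = float(stats.ttest_rel(post, pre).pvalue)
    return out
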