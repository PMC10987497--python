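"""Reconstruction of the 24-h diurnal calcium curve and circadian gating.

Long-term imaging of one fly is limited to a ~6-h session, so the full
diurnal calcium profile is assembled from four fly groups entrained on
light-dark schedules shifted by 0, 6, 12 and 18 h. Each fly is sampled at
30-min intervals over 6 h of its *local* schedule; mapping local time
through the group's shift (mod 24) places every sample on a common
Zeitgeber-time axis, and pooling the four groups covers the whole day.

Signals are ratiometric: the GCaMP sum over the ROI divided by the
tdTomato sum, which cancels common-mode intensity drift (bleaching, focus)
exactly.

Binning convention: 30-min bins *centered* on the sampling grid
(centers ZT 0.0, 0.5, …, 23.5 h; edges ±0.25 h, with a wraparound bin
across ZT 0). Flies are the statistical unit: samples are averaged within
fly per bin first, then mean/SEM taken across flies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calcium import TemperatureResponse


class DiurnalError(ValueError):
    """Raised for invalid diurnal-group input."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FlySeries:
    """One fly's 6-h sampling series (local schedule time, channel sums)."""

    fly_id: str
    local_time_h: np.ndarray  # 30-min spacing over 6 h
    gcamp: np.ndarray
    tdtom: np.ndarray

    def __post_init__(self) -> None:
        self.local_time_h = np.asarray(self.local_time_h, dtype=float)
        self.gcamp = np.asarray(self.gcamp, dtype=float)
        self.tdtom = np.asarray(self.tdtom, dtype=float)
        if self.local_time_h.size < 2:
            raise DiurnalError(f"fly {self.fly_id}: need >= 2 samples")
        if not (self.local_time_h.size == self.gcamp.size == self.tdtom.size):
            raise DiurnalError(f"fly {self.fly_id}: channel length mismatch")
        if np.any(self.gcamp <= 0) or np.any(self.tdtom <= 0):
            raise DiurnalError(f"fly {self.fly_id}: both channels must be positive")


@dataclass
class DiurnalGroup:
    """One phase-shifted entrainment group (shift in {0, 6, 12, 18} h)."""

    shift_h: float
    flies: list[FlySeries]


@dataclass
class CircadianCurve:
    """30-min-binned 24-h mean ± SEM curve (NaN where no fly contributed)."""

    bin_centers: np.ndarray  # ZT h: 0.0, 0.5, ..., 23.5
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray  # flies per bin

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"zt": self.bin_centers, "mean": self.mean, "sem": self.sem, "n": self.n}
        )


@dataclass
class GatingProfile:
    """Per-ZT-window temperature-response gain estimates ± bootstrap CI."""

    windows: dict[str, tuple[float, float]]
    gain: dict[str, float]  # mean |response| per window
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    n: dict[str, int]
    reference: str
    ratio_to_reference: dict[str, float]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def ratiometric_normalize(gcamp: np.ndarray, tdtom: np.ndarray) -> np.ndarray:
    """Pointwise GCaMP / tdTomato ratio.

    Any drift multiplying both channels equally (bleaching, laser power)
    cancels exactly. Fails loudly on a non-positive tdTomato sample, naming
    the first offending index.
    """
    gcamp = np.asarray(gcamp, dtype=float)
    tdtom = np.asarray(tdtom, dtype=float)
    if gcamp.shape != tdtom.shape:
        raise DiurnalError("channel shapes differ")
    bad = np.flatnonzero(tdtom <= 0)
    if bad.size:
        raise DiurnalError(
            f"non-positive tdTomato value at sample {bad[0]} ({tdtom[bad[0]]})"
        )
    return gcamp / tdtom


N_BINS = 48
BIN_W = 0.5


def zt_bin_index(zt: np.ndarray) -> np.ndarray:
    """Bin index for center-aligned 30-min bins (center k*0.5, edges ±0.25)."""
    return (np.floor((np.asarray(zt) + BIN_W / 2) / BIN_W).astype(int)) % N_BINS


def stitch_groups(groups: list[DiurnalGroup]) -> CircadianCurve:
    """Pool phase-shifted groups into one 24-h ratiometric curve.

    Each sample maps to ZT = (local_time + shift) mod 24 and joins the
    center-aligned 30-min bin containing it. Within-fly means are taken per
    bin first; the curve's mean/SEM/n are then across flies, so overlapping
    samples at group edges are pooled at the fly level rather than averaged
    as averages. Empty bins stay NaN — never interpolated.
    """
    shifts = [g.shift_h for g in groups]
    if len(set(shifts)) != len(shifts):
        raise DiurnalError("group shifts must be distinct")
    per_fly_bin: dict[str, dict[int, list[float]]] = {}
    for group in groups:
        for fly in group.flies:
            zt = (fly.local_time_h + group.shift_h) % 24.0
            ratio = ratiometric_normalize(fly.gcamp, fly.tdtom)
            bins = zt_bin_index(zt)
            store = per_fly_bin.setdefault(fly.fly_id, {})
            for b, v in zip(bins, ratio):
                store.setdefault(int(b), []).append(float(v))

    mean = np.full(N_BINS, np.nan)
    sem = np.full(N_BINS, np.nan)
    n = np.zeros(N_BINS, dtype=int)
    for b in range(N_BINS):
        fly_vals = [
            float(np.mean(vals[b])) for vals in per_fly_bin.values() if b in vals
        ]
        if not fly_vals:
            continue
        arr = np.asarray(fly_vals)
        n[b] = arr.size
        mean[b] = arr.mean()
        sem[b] = arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else np.nan
    centers = np.arange(N_BINS) * BIN_W
    return CircadianCurve(bin_centers=centers, mean=mean, sem=sem, n=n)


def double_plot(curve: CircadianCurve) -> pd.DataFrame:
    """48-h table: the 24-h curve repeated with the second copy offset +24 h.

    Purely presentational — no recomputation. ``undouble`` inverts it.
    """
    one = curve.to_frame()
    two = one.copy()
    two["zt"] = two["zt"] + 24.0
    return pd.concat([one, two], ignore_index=True)


def undouble(doubled: pd.DataFrame) -> CircadianCurve:
    """Inverse of :func:`double_plot` (keeps the first 24-h copy)."""
    half = len(doubled) // 2
    first = doubled.iloc[:half]
    second = doubled.iloc[half:]
    if not np.allclose(
        second["zt"].to_numpy() - 24.0, first["zt"].to_numpy()
    ) or not np.allclose(
        second["mean"].to_numpy(), first["mean"].to_numpy(), equal_nan=True
    ):
        raise DiurnalError("input is not a doubled curve")
    return CircadianCurve(
        bin_centers=first["zt"].to_numpy(),
        mean=first["mean"].to_numpy(),
        sem=first["sem"].to_numpy(),
        n=first["n"].to_numpy().astype(int),
    )


DEFAULT_GATING_WINDOWS: dict[str, tuple[float, float]] = {
    "ZT0-2": (0.0, 2.0),
    "ZT6-8": (6.0, 8.0),
    "ZT10-14": (10.0, 14.0),
    "ZT17-19": (17.0, 19.0),
}


def estimate_gating(
    responses: list[TemperatureResponse],
    windows: dict[str, tuple[float, float]] | None = None,
    reference: str = "ZT6-8",
    n_boot: int = 1000,
    seed: int = 0,
) -> GatingProfile:
    """Circadian gating of the temperature response across ZT windows.

    Groups step responses by the ZT window of their recording and estimates
    the per-window gain as the mean absolute response amplitude
    |post − pre| (ratiometric units), with a seeded percentile bootstrap CI
    (95%, ``n_boot`` resamples). Each window's gain is also expressed as a
    ratio to the reference window (daytime ZT6-8 by default), which is the
    night:day gating ratio when applied to a night window.

    The absolute amplitude is used rather than fold change − 1 because the
    diurnal calcium baseline varies with ZT and would otherwise leak into
    the gain ratio through the denominator.
    """
    windows = dict(DEFAULT_GATING_WINDOWS if windows is None else windows)
    by_window: dict[str, list[float]] = {w: [] for w in windows}
    for r in responses:
        for wname, (lo, hi) in windows.items():
            if lo <= r.zt < hi:
                by_window[wname].append(abs(r.magnitude))
                break
    populated = {w: v for w, v in by_window.items() if len(v) >= 2}
    if len(populated) < 2:
        raise DiurnalError("need >= 2 windows with >= 2 responses each")
    if reference not in populated:
        raise DiurnalError(f"reference window {reference!r} is empty")

    rng = np.random.default_rng(seed)
    gain, lo_ci, hi_ci, n = {}, {}, {}, {}
    for wname, vals in populated.items():
        arr = np.asarray(vals)
        gain[wname] = float(arr.mean())
        boots = rng.choice(arr, size=(n_boot, arr.size), replace=True).mean(axis=1)
        lo_ci[wname] = float(np.percentile(boots, 2.5))
        hi_ci[wname] = float(np.percentile(boots, 97.5))
        n[wname] = arr.size
    ref_gain = gain[reference]
    ratios = {
        w: (g / ref_gain if ref_gain > 0 else float("inf") if g > 0 else float("nan"))
        for w, g in gain.items()
    }
    return GatingProfile(
        windows={w: windows[w] for w in populated},
        gain=gain, ci_low=lo_ci, ci_high=hi_ci, n=n,
        reference=reference, ratio_to_reference=ratios,
    )
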