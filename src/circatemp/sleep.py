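"""Sleep scoring and temperature-response behavior indices.

Fly locomotion is recorded as movement counts per 10-s epoch (8640 epochs
per 24-h day). Sleep is scored with the field-standard rule: any run of
behavioral immobility lasting at least 5 minutes (30 consecutive inactive
epochs) is a sleep bout. Activity profiles sum counts in 30-min bins
(half-open [left, left+0.5) h, 180 epochs per bin).

Four indices quantify how a temperature shift reshapes the diurnal pattern,
each a per-fly relative change of a window mean between a shifted-temperature
day and its control day:

* E peak advance (cold):        (ZT6-12 activity at 18° − at 24°) / at 24°
* E peak offset delay (hot):    (ZT12-18 activity at 30° − at 22°) / at 22°
* Nighttime sleep reduction:    (ZT12-24 sleep at 22° − at 30°) / at 22°
* E peak sleep reduction:
    cold variant:               (ZT6-12 sleep at 18° − at 24°) / at 24°
    hot variant:                (ZT12-18 sleep at 30° − at 22°) / at 22°

Signs are implemented exactly as printed: the cold E-peak-sleep formula is
positive for a sleep *gain*, which the result metadata flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

EPOCH_S = 10
EPOCHS_PER_DAY = 24 * 3600 // EPOCH_S  # 8640
MIN_PER_EPOCH = EPOCH_S / 60.0


class BehaviorError(ValueError):
    """Raised for malformed activity records or degenerate index inputs."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ActivityRecord:
    """One fly-day of movement counts at 10-s epochs.

    ``temp_condition`` is the temperature label for the day (e.g. "18C");
    ``lights_on_zt``/``lights_off_zt`` document the LD schedule in ZT hours.
    """

    fly_id: str
    temp_condition: str
    counts: np.ndarray
    day_index: int = 0
    genotype: str = ""
    lights_on_zt: float = 0.0
    lights_off_zt: float = 12.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.size != EPOCHS_PER_DAY:
            raise BehaviorError(
                f"expected {EPOCHS_PER_DAY} epochs per day, got {counts.size}"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise BehaviorError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise BehaviorError("counts must be nonnegative")
        self.counts = counts


@dataclass
class SleepSeries:
    """Boolean sleep state per epoch plus the scored bout list."""

    sleep: np.ndarray  # bool per epoch
    bouts: list[tuple[int, int]]  # (start_epoch, length_epochs), sorted

    @property
    def total_sleep_min(self) -> float:
        return float(self.sleep.sum() * MIN_PER_EPOCH)

    def sleep_min_per_bin(self, bin_min: int = 30) -> np.ndarray:
        """Minutes asleep within each bin of the day."""
        per_bin = bin_min * 60 // EPOCH_S
        if (24 * 60) % bin_min != 0:
            raise BehaviorError("bin width must divide 24 h")
        return self.sleep.reshape(-1, per_bin).sum(axis=1) * MIN_PER_EPOCH


@dataclass
class ActivityProfile:
    """Mean ± SEM binned activity across flies (48 bins per day at 30 min)."""

    bin_centers: np.ndarray  # ZT hours
    mean: np.ndarray
    sem: np.ndarray
    n: int


@dataclass
class IndexResult:
    """Per-fly values and group summary of one temperature-response index."""

    index_name: str
    per_fly: pd.DataFrame  # fly_id, test_mean, control_mean, value
    mean: float
    sem: float
    window_zt: tuple[float, float]
    test_condition: str
    control_condition: str
    measure: str  # "activity" | "sleep"
    notes: str = ""
    excluded_flies: list[str] = field(default_factory=list)


@dataclass
class GroupStats:
    """One-way ANOVA + Tukey HSD pairwise table + compact letter display."""

    anova_f: float | None
    anova_p: float | None
    pairwise: pd.DataFrame | None  # group1, group2, meandiff, p_adj, reject
    letters: dict[str, str]
    method: str
    message: str = ""


# ---------------------------------------------------------------------------
# Sleep scoring and binning
# ---------------------------------------------------------------------------

def sleep_mask_from_counts(
    counts: np.ndarray,
    min_bout_min: float = 5.0,
    inactive_threshold: int = 0,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Run-length sleep scoring on a raw counts array.

    Returns the boolean sleep mask and the sorted bout list
    ``(start_epoch, length_epochs)``. Used by :func:`score_sleep` and by
    the synthetic generator's large-n oracles, which operate on bare
    arrays.
    """
    counts = np.asarray(counts)
    min_bout_epochs = int(round(min_bout_min * 60 / EPOCH_S))
    inactive = counts <= inactive_threshold
    padded = np.concatenate(([False], inactive, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    lengths = ends - starts
    keep = lengths >= min_bout_epochs
    bouts = [(int(s), int(l)) for s, l in zip(starts[keep], lengths[keep])]
    sleep = np.zeros(counts.size, dtype=bool)
    for s, l in bouts:
        sleep[s : s + l] = True
    return sleep, bouts


def score_sleep(
    record: ActivityRecord,
    min_bout_min: float = 5.0,
    inactive_threshold: int = 0,
) -> SleepSeries:
    """Score sleep as runs of inactivity lasting >= ``min_bout_min``.

    An epoch is inactive when its count is <= ``inactive_threshold``
    (default 0: any movement breaks a bout). Runs of at least
    ``min_bout_min`` minutes (30 epochs at the 5-min default) become sleep
    bouts; every epoch inside a bout is marked asleep.
    """
    sleep, bouts = sleep_mask_from_counts(
        record.counts, min_bout_min, inactive_threshold
    )
    return SleepSeries(sleep=sleep, bouts=bouts)


def bin_activity(records: list[ActivityRecord], bin_min: int = 30) -> ActivityProfile:
    """Per-fly binned activity (counts summed per bin), averaged across flies."""
    if (24 * 60) % bin_min != 0:
        raise BehaviorError(f"bin width {bin_min} min does not divide 24 h")
    if not records:
        raise BehaviorError("no records supplied")
    per_bin = bin_min * 60 // EPOCH_S
    binned = np.vstack([r.counts.reshape(-1, per_bin).sum(axis=1) for r in records])
    n = len(records)
    mean = binned.mean(axis=0)
    sem = binned.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(mean.shape, np.nan)
    n_bins = binned.shape[1]
    centers = (np.arange(n_bins) + 0.5) * (24.0 / n_bins)
    return ActivityProfile(bin_centers=centers, mean=mean, sem=sem, n=n)


def _window_bins(window_zt: tuple[float, float], bin_min: int = 30) -> np.ndarray:
    """Indices of bins fully inside the half-open ZT window [lo, hi)."""
    lo, hi = window_zt
    width = bin_min / 60.0
    lefts = np.arange(0, 24, width)
    return np.flatnonzero((lefts >= lo - 1e-9) & (lefts + width <= hi + 1e-9))


def window_mean_activity(
    record: ActivityRecord, window_zt: tuple[float, float], bin_min: int = 30
) -> float:
    """Mean of the fly's 30-min binned activity over a ZT window."""
    per_bin = bin_min * 60 // EPOCH_S
    binned = record.counts.reshape(-1, per_bin).sum(axis=1)
    return float(binned[_window_bins(window_zt, bin_min)].mean())


def window_mean_sleep(
    record: ActivityRecord,
    window_zt: tuple[float, float],
    bin_min: int = 30,
    min_bout_min: float = 5.0,
    inactive_threshold: int = 0,
) -> float:
    """Mean sleep minutes per 30-min bin over a ZT window."""
    series = score_sleep(record, min_bout_min, inactive_threshold)
    per_bin = series.sleep_min_per_bin(bin_min)
    return float(per_bin[_window_bins(window_zt, bin_min)].mean())


# ---------------------------------------------------------------------------
# Temperature-response indices
# ---------------------------------------------------------------------------

def _relative_index(
    name: str,
    test_records: list[ActivityRecord],
    control_records: list[ActivityRecord],
    window_zt: tuple[float, float],
    measure: str,
    test_condition: str,
    control_condition: str,
    notes: str = "",
) -> IndexResult:
    """Per-fly (test − control)/control of a window mean, paired by fly_id."""
    if not test_records or not control_records:
        raise BehaviorError("both condition record sets must be nonempty")
    fn = window_mean_activity if measure == "activity" else window_mean_sleep

    def per_fly_means(records: list[ActivityRecord]) -> dict[str, float]:
        vals: dict[str, list[float]] = {}
        for r in records:
            vals.setdefault(r.fly_id, []).append(fn(r, window_zt))
        return {f: float(np.mean(v)) for f, v in vals.items()}

    test_means = per_fly_means(test_records)
    ctrl_means = per_fly_means(control_records)
    common = sorted(set(test_means) & set(ctrl_means))
    if not common:
        raise BehaviorError("no flies present in both conditions")

    rows, excluded = [], []
    for fly in common:
        c = ctrl_means[fly]
        if c <= 0:
            excluded.append(fly)
            continue
        rows.append(
            {
                "fly_id": fly,
                "test_mean": test_means[fly],
                "control_mean": c,
                "value": (test_means[fly] - c) / c,
            }
        )
    if excluded:
        warnings.warn(
            f"{name}: flies excluded for zero control-window mean: {excluded}",
            stacklevel=3,
        )
    if not rows:
        raise BehaviorError(f"{name}: all flies had zero control-window means")
    per_fly = pd.DataFrame(rows)
    values = per_fly["value"].to_numpy()
    sem = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else float("nan")
    return IndexResult(
        index_name=name,
        per_fly=per_fly,
        mean=float(values.mean()),
        sem=sem,
        window_zt=window_zt,
        test_condition=test_condition,
        control_condition=control_condition,
        measure=measure,
        notes=notes,
        excluded_flies=excluded,
    )


def epeak_advance_index(
    cold_records: list[ActivityRecord],
    control_records: list[ActivityRecord],
    cold: str = "18C",
    control: str = "24C",
) -> IndexResult:
    """Cooling-induced E-peak advance: relative ZT6-12 activity gain at 18 °C.

    Greater values mean the evening locomotion bout begins earlier.
    """
    return _relative_index(
        "epeak_advance", cold_records, control_records, (6.0, 12.0),
        "activity", cold, control,
    )


def epeak_offset_delay_index(
    hot_records: list[ActivityRecord],
    control_records: list[ActivityRecord],
    hot: str = "30C",
    control: str = "22C",
) -> IndexResult:
    """Heating-induced E-peak offset delay: relative ZT12-18 activity gain at 30 °C.

    Greater values mean evening locomotion finishes later.
    """
    return _relative_index(
        "epeak_offset_delay", hot_records, control_records, (12.0, 18.0),
        "activity", hot, control,
    )


def night_sleep_reduction_index(
    hot_records: list[ActivityRecord],
    control_records: list[ActivityRecord],
    hot: str = "30C",
    control: str = "22C",
) -> IndexResult:
    """Heating-induced nighttime sleep loss: (ZT12-24 sleep at 22° − at 30°)/at 22°.

    Note the reversed numerator relative to the activity indices: a *larger*
    index means *more* sleep lost to heat.
    """
    if not hot_records or not control_records:
        raise BehaviorError("both condition record sets must be nonempty")
    window_zt = (12.0, 24.0)

    def per_fly_means(records: list[ActivityRecord]) -> dict[str, float]:
        vals: dict[str, list[float]] = {}
        for r in records:
            vals.setdefault(r.fly_id, []).append(window_mean_sleep(r, window_zt))
        return {f: float(np.mean(v)) for f, v in vals.items()}

    hot_means = per_fly_means(hot_records)
    ctrl_means = per_fly_means(control_records)
    common = sorted(set(hot_means) & set(ctrl_means))
    if not common:
        raise BehaviorError("no flies present in both conditions")
    rows, excluded = [], []
    for fly in common:
        c = ctrl_means[fly]
        if c <= 0:
            excluded.append(fly)
            continue
        rows.append(
            {
                "fly_id": fly,
                "test_mean": hot_means[fly],
                "control_mean": c,
                "value": (c - hot_means[fly]) / c,
            }
        )
    if excluded:
        warnings.warn(
            f"night_sleep_reduction: flies excluded for zero control sleep: {excluded}",
            stacklevel=2,
        )
    if not rows:
        raise BehaviorError("night_sleep_reduction: all flies had zero control sleep")
    per_fly = pd.DataFrame(rows)
    values = per_fly["value"].to_numpy()
    sem = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else float("nan")
    return IndexResult(
        index_name="night_sleep_reduction",
        per_fly=per_fly,
        mean=float(values.mean()),
        sem=sem,
        window_zt=window_zt,
        test_condition=hot,
        control_condition=control,
        measure="sleep",
        notes="positive = heat-induced sleep loss",
        excluded_flies=excluded,
    )


def epeak_sleep_reduction_index(
    test_records: list[ActivityRecord],
    control_records: list[ActivityRecord],
    variant: str = "cold",
) -> IndexResult:
    """Evening sleep change under a temperature shift, sign as printed.

    cold: (ZT6-12 sleep at 18° − at 24°)/at 24° — positive = sleep *gain*.
    hot:  (ZT12-18 sleep at 30° − at 22°)/at 22°.
    """
    if variant == "cold":
        return _relative_index(
            "epeak_sleep_reduction_cold", test_records, control_records,
            (6.0, 12.0), "sleep", "18C", "24C",
            notes="positive direction is sleep gain (formula as printed)",
        )
    if variant == "hot":
        return _relative_index(
            "epeak_sleep_reduction_hot", test_records, control_records,
            (12.0, 18.0), "sleep", "30C", "22C",
        )
    raise BehaviorError(f"unknown variant {variant!r} (use 'cold' or 'hot')")


def epeak_timing(
    profile: ActivityProfile,
    search_window: tuple[float, float] = (6.0, 14.0),
) -> tuple[float | None, float | None, float | None]:
    """(onset, peak, offset) ZT of the evening activity peak.

    The peak is the argmax bin inside the search window (earlier bin on
    ties). Onset/offset are the first/last bins whose activity rises at
    least 50% of (peak − window baseline) above the baseline (window
    minimum). A flat profile has no peak: all three are None.
    """
    lo, hi = search_window
    mask = (profile.bin_centers >= lo) & (profile.bin_centers < hi)
    if not mask.any():
        raise BehaviorError("search window contains no bins")
    centers = profile.bin_centers[mask]
    vals = profile.mean[mask]
    baseline = float(vals.min())
    peak_idx = int(np.argmax(vals))
    peak_val = float(vals[peak_idx])
    if peak_val == baseline:
        return None, None, None
    level = baseline + 0.5 * (peak_val - baseline)
    above = np.flatnonzero(vals >= level)
    return float(centers[above[0]]), float(centers[peak_idx]), float(centers[above[-1]])


# ---------------------------------------------------------------------------
# Group statistics with compact letter display
# ---------------------------------------------------------------------------

def _compact_letters(
    names: list[str], means: dict[str, float], sig: np.ndarray
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Two groups share a letter iff their pairwise comparison is
    non-significant. Starts with all groups in one letter column; every
    significant pair splits each column containing both; columns that
    become subsets of another are absorbed. Deterministic: pairs and
    columns are processed in sorted order, letters assigned to columns by
    their best (largest-mean) member.
    """
    k = len(names)
    cols: list[frozenset[int]] = [frozenset(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            new_cols: list[frozenset[int]] = []
            for col in cols:
                if i in col and j in col:
                    new_cols.append(col - {i})
                    new_cols.append(col - {j})
                else:
                    new_cols.append(col)
            # absorb: drop any column contained in another
            cols = [
                c for c in new_cols
                if c and not any(c < other for other in new_cols)
            ]
            cols = sorted(set(cols), key=lambda c: sorted(c))
    # assign letters: columns ordered by their largest-mean member
    rank = sorted(range(k), key=lambda g: -means[names[g]])
    pos = {g: r for r, g in enumerate(rank)}
    cols = sorted(cols, key=lambda c: min(pos[g] for g in c))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    letters = {name: "" for name in names}
    for li, col in enumerate(cols):
        letter = alphabet[li % 26] * (1 + li // 26)
        for g in sorted(col, key=lambda g: pos[g]):
            letters[names[g]] += letter
    return letters


def group_stats(groups: dict[str, np.ndarray], alpha: float = 0.05) -> GroupStats:
    """One-way ANOVA, Tukey HSD post-test, and compact significance letters.

    With exactly two groups falls back to a two-tailed unpaired t-test.
    Groups with zero variance everywhere (exact ties) cannot be tested:
    the test is skipped with a message and letters are assigned by exact
    mean equality.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise BehaviorError("need at least 2 groups")
    arrays = {n: np.asarray(groups[n], dtype=float) for n in names}
    for n, a in arrays.items():
        if a.size < 2:
            raise BehaviorError(f"group {n!r} needs n >= 2")
    means = {n: float(a.mean()) for n, a in arrays.items()}
    k = len(names)

    if all(a.std(ddof=1) == 0 for a in arrays.values()):
        # exact ties: distinct means are trivially different, equal means equal
        sig = np.zeros((k, k), dtype=bool)
        for i in range(k):
            for j in range(i + 1, k):
                sig[i, j] = sig[j, i] = means[names[i]] != means[names[j]]
        return GroupStats(
            anova_f=None, anova_p=None, pairwise=None,
            letters=_compact_letters(names, means, sig),
            method="skipped",
            message="zero within-group variance everywhere; letters reflect exact ties",
        )

    if k == 2:
        t = stats.ttest_ind(arrays[names[0]], arrays[names[1]])
        reject = t.pvalue < alpha
        sig = np.array([[False, reject], [reject, False]])
        pairwise = pd.DataFrame(
            {
                "group1": [names[0]],
                "group2": [names[1]],
                "meandiff": [means[names[1]] - means[names[0]]],
                "p_adj": [float(t.pvalue)],
                "reject": [bool(reject)],
            }
        )
        return GroupStats(
            anova_f=float(t.statistic) ** 2, anova_p=float(t.pvalue),
            pairwise=pairwise,
            letters=_compact_letters(names, means, sig),
            method="t-test (two groups)",
        )

    f, p = stats.f_oneway(*(arrays[n] for n in names))
    endog = np.concatenate([arrays[n] for n in names])
    labels = np.concatenate([[n] * arrays[n].size for n in names])
    tukey = pairwise_tukeyhsd(endog, labels, alpha=alpha)
    tk = pd.DataFrame(
        tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]]
    )
    pairwise = pd.DataFrame(
        {
            "group1": tk["group1"].astype(str),
            "group2": tk["group2"].astype(str),
            "meandiff": tk["meandiff"].astype(float),
            "p_adj": tk["p-adj"].astype(float),
            "reject": tk["reject"].astype(bool),
        }
    )
    idx = {n: i for i, n in enumerate(names)}
    sig = np.zeros((k, k), dtype=bool)
    for _, row in pairwise.iterrows():
        i, j = idx[row["group1"]], idx[row["group2"]]
        sig[i, j] = sig[j, i] = bool(row["reject"])
    return GroupStats(
        anova_f=float(f), anova_p=float(p), pairwise=pairwise,
        letters=_compact_letters(names, means, sig),
        method="one-way ANOVA + Tukey HSD",
    )
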