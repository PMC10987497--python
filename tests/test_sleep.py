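"""Sleep scoring, binning, indices and group statistics."""

from itertools import groupby

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circatemp import sleep, synth
from circatemp.sleep import (
    ActivityRecord,
    BehaviorError,
    bin_activity,
    epeak_advance_index,
    epeak_offset_delay_index,
    epeak_sleep_reduction_index,
    epeak_timing,
    group_stats,
    night_sleep_reduction_index,
    score_sleep,
    sleep_mask_from_counts,
)


def brute_force_bouts(counts, min_epochs=30, threshold=0):
    """Independent run-length scanner (itertools.groupby)."""
    z = (np.asarray(counts) <= threshold).tolist()
    bouts, i = [], 0
    for inactive, grp in groupby(z):
        length = sum(1 for _ in grp)
        if inactive and length >= min_epochs:
            bouts.append((i, length))
        i += length
    return bouts


def record(counts, fly="f0", cond="24C", day=0) -> ActivityRecord:
    return ActivityRecord(fly_id=fly, temp_condition=cond, counts=counts, day_index=day)


class TestScoreSleep:
    def test_all_zeros_is_one_full_day_bout(self):
        s = score_sleep(record(np.zeros(8640, dtype=int)))
        assert s.bouts == [(0, 8640)]
        assert s.total_sleep_min == 1440.0

    def test_movement_every_29_epochs_prevents_sleep(self):
        counts = np.zeros(8640, dtype=int)
        counts[::29] = 1  # longest zero run = 28 epochs < 30
        s = score_sleep(record(counts))
        assert s.bouts == []
        assert s.total_sleep_min == 0.0

    def test_rejects_negative_and_fractional_counts(self):
        with pytest.raises(BehaviorError):
            record(np.full(8640, -1))
        with pytest.raises(BehaviorError):
            record(np.full(8640, 0.5))

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(200):
            counts = rng.integers(0, 2, size=8640)
            s = score_sleep(record(counts))
            assert s.bouts == brute_force_bouts(counts)

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=300), st.integers(2, 10))
    @settings(max_examples=200, deadline=None)
    def test_mask_equals_brute_force_property(self, counts, min_epochs):
        counts = np.asarray(counts)
        mask, bouts = sleep_mask_from_counts(
            counts, min_bout_min=min_epochs / 6.0  # epochs -> minutes at 10 s
        )
        assert bouts == brute_force_bouts(counts, min_epochs=min_epochs)
        expect = np.zeros(counts.size, dtype=bool)
        for s, l in bouts:
            expect[s : s + l] = True
        np.testing.assert_array_equal(mask, expect)

    def test_sleep_plus_wake_is_1440_minutes(self, rng):
        for _ in range(20):
            counts = rng.poisson(0.5, size=8640)
            s = score_sleep(record(counts))
            wake_min = (~s.sleep).sum() * sleep.MIN_PER_EPOCH
            assert s.total_sleep_min + wake_min == pytest.approx(1440.0)


class TestBinActivity:
    def test_constant_one_count_gives_180_per_bin(self):
        prof = bin_activity([record(np.ones(8640, dtype=int))])
        np.testing.assert_allclose(prof.mean, 180.0)
        assert prof.bin_centers[0] == 0.25 and prof.bin_centers[-1] == 23.75

    def test_single_fly_sem_is_missing(self):
        prof = bin_activity([record(np.ones(8640, dtype=int))])
        assert np.all(np.isnan(prof.sem))

    def test_matches_double_loop_summation(self, rng):
        records = [record(rng.integers(0, 5, 8640), fly=f"f{i}") for i in range(4)]
        prof = bin_activity(records)
        naive = np.zeros((4, 48))
        for i, r in enumerate(records):
            for b in range(48):
                for e in range(180):
                    naive[i, b] += r.counts[b * 180 + e]
        np.testing.assert_allclose(prof.mean, naive.mean(axis=0))

    def test_bin_width_must_divide_day(self):
        with pytest.raises(BehaviorError):
            bin_activity([record(np.zeros(8640, dtype=int))], bin_min=50)


def _uniform_record(count, fly="f0", cond="24C"):
    return record(np.full(8640, count, dtype=int), fly=fly, cond=cond)


def _zero_window_record(zero_zt, fly="f0", cond="24C"):
    """Counts of 1 everywhere except zero inside the given ZT window."""
    counts = np.ones(8640, dtype=int)
    lo, hi = zero_zt
    epochs = (np.arange(8640) * 10) / 3600.0
    counts[(epochs >= lo) & (epochs < hi)] = 0
    return record(counts, fly=fly, cond=cond)


class TestIndices:
    def test_identical_conditions_give_zero(self):
        cold = [_uniform_record(2, cond="18C")]
        ctrl = [_uniform_record(2, cond="24C")]
        assert epeak_advance_index(cold, ctrl).mean == 0.0

    def test_doubled_evening_activity_gives_one(self):
        cold = [_uniform_record(2, cond="18C")]
        ctrl = [_uniform_record(1, cond="24C")]
        assert epeak_advance_index(cold, ctrl).mean == pytest.approx(1.0)

    def test_offset_delay_1p5x_gives_half(self):
        hot = [_uniform_record(3, cond="30C")]
        ctrl = [_uniform_record(2, cond="22C")]
        assert epeak_offset_delay_index(hot, ctrl).mean == pytest.approx(0.5)

    def test_night_sleep_fully_lost_gives_one(self):
        hot = [_uniform_record(1, cond="30C")]  # never asleep
        ctrl = [_zero_window_record((12.0, 24.0), cond="22C")]  # asleep all night
        res = night_sleep_reduction_index(hot, ctrl)
        assert res.mean == pytest.approx(1.0)
        assert "sleep loss" in res.notes

    def test_cold_halved_evening_sleep_gives_minus_half(self):
        ctrl = [_zero_window_record((6.0, 12.0), cond="24C")]  # 30 min/bin asleep
        cold = [_zero_window_record((6.0, 9.0), cond="18C")]  # 15 min/bin mean
        res = epeak_sleep_reduction_index(cold, ctrl, variant="cold")
        assert res.mean == pytest.approx(-0.5)
        assert "sleep gain" in res.notes  # positive direction documented

    def test_zero_denominator_excludes_fly_with_warning(self):
        cold = [_uniform_record(2, fly="a", cond="18C"),
                _uniform_record(2, fly="b", cond="18C")]
        ctrl = [_uniform_record(1, fly="a", cond="24C"),
                _uniform_record(0, fly="b", cond="24C")]
        with pytest.warns(UserWarning, match="excluded"):
            res = epeak_advance_index(cold, ctrl)
        assert res.excluded_flies == ["b"]
        assert len(res.per_fly) == 1

    def test_all_excluded_fails(self):
        cold = [_uniform_record(2, cond="18C")]
        ctrl = [_uniform_record(0, cond="24C")]
        with pytest.raises(BehaviorError), pytest.warns(UserWarning):
            epeak_advance_index(cold, ctrl)

    def test_expected_index_monotone_in_planted_rate_effect(self):
        """Noise-free monotonicity: a larger planted ZT6-12 rate factor
        strictly increases the expected E-peak-advance index."""
        oracle = []
        for factor in (1.0, 1.15, 1.3):
            effects = {
                "24C": synth.TempEffect(),
                "18C": synth.TempEffect(evening_rate_factor=factor),
            }
            cfg = synth.SynthConfig(master_seed=1, temp_effects=effects)
            cold = synth.expected_window_mean(cfg, "18C", (6.0, 12.0)).value
            ctrl = synth.expected_window_mean(cfg, "24C", (6.0, 12.0)).value
            oracle.append((cold - ctrl) / ctrl)
        assert oracle[0] < oracle[1] < oracle[2]
        assert oracle[0] == pytest.approx(0.0)
        assert oracle[2] == pytest.approx(0.3)


class TestEpeakTiming:
    def _profile(self, values):
        return sleep.ActivityProfile(
            bin_centers=(np.arange(48) + 0.5) * 0.5,
            mean=np.asarray(values, dtype=float),
            sem=np.zeros(48),
            n=1,
        )

    def test_triangular_peak_at_zt11(self):
        vals = np.zeros(48)
        centers = (np.arange(48) + 0.5) * 0.5
        vals[:] = np.maximum(0.0, 10.0 - 8.0 * np.abs(centers - 11.25))
        onset, peak, offset = epeak_timing(self._profile(vals))
        assert peak == pytest.approx(11.25)
        assert onset < peak < offset

    def test_tie_breaks_to_earlier_bin(self):
        vals = np.zeros(48)
        vals[18] = vals[20] = 10.0  # equal maxima at ZT 9.25 and 10.25
        _onset, peak, _offset = epeak_timing(self._profile(vals))
        assert peak == pytest.approx(9.25)

    def test_flat_profile_has_no_peak(self):
        assert epeak_timing(self._profile(np.ones(48))) == (None, None, None)


class TestGroupStats:
    def test_identical_groups_share_a_letter(self, rng):
        base = rng.normal(10.0, 1.0, size=12)
        res = group_stats({"a": base, "b": base.copy(), "c": base.copy()})
        assert len(set(res.letters.values())) == 1

    def test_separated_groups_get_distinct_letters(self, rng):
        res = group_stats(
            {
                "lo": rng.normal(0.0, 0.1, 10),
                "hi": rng.normal(10.0, 0.1, 10),
            }
        )
        assert res.letters["lo"] != res.letters["hi"]
        assert res.method == "t-test (two groups)"

    def test_zero_variance_everywhere_skips_test(self):
        res = group_stats({"a": np.full(5, 1.0), "b": np.full(5, 1.0),
                           "c": np.full(5, 2.0)})
        assert res.method == "skipped"
        assert "zero within-group variance" in res.message
        assert res.letters["a"] == res.letters["b"] != res.letters["c"]

    @staticmethod
    def letters_consistent(letters, names, sig):
        """Letters partition agrees with the pairwise significance matrix."""
        for i, a in enumerate(names):
            for j, b in enumerate(names[i + 1:], start=i + 1):
                share = bool(set(letters[a]) & set(letters[b]))
                if sig[i, j] and share:
                    return False
                if not sig[i, j] and not share:
                    return False
        return True

    def test_letters_match_pairwise_significance(self, rng):
        """Random 4-group layouts: shared letter iff non-significant (Tukey)."""
        for _ in range(40):
            groups = {
                f"g{k}": rng.normal(rng.uniform(0, 6), rng.uniform(0.5, 2.0), 8)
                for k in range(4)
            }
            res = group_stats(groups)
            names = sorted(groups)
            idx = {n: i for i, n in enumerate(names)}
            sig = np.zeros((4, 4), dtype=bool)
            for _i, row in res.pairwise.iterrows():
                a, b = idx[row["group1"]], idx[row["group2"]]
                sig[a, b] = sig[b, a] = row["reject"]
            assert self.letters_consistent(res.letters, names, sig)

    def test_needs_two_groups_of_two(self):
        with pytest.raises(BehaviorError):
            group_stats({"a": np.ones(3)})
        with pytest.raises(BehaviorError):
            group_stats({"a": np.ones(3), "b": np.ones(1)})
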