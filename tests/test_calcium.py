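"""ΔF/F0 quantification, step responses, saturation, clustering, locomotion."""

import dataclasses

import numpy as np
import pytest

from circatemp import synth
from circatemp.calcium import (
    CalciumError,
    DeltaFTrace,
    FluorescenceTrace,
    LocomotionEpisode,
    TemperatureProtocol,
    compute_dff,
    compute_max_dff,
    correlate_and_cluster,
    locomotion_change,
    quantify_step_response,
    saturation_summary,
    estimate_saturation_point,
)


def trace(values, dt=1.0, **kw):
    values = np.asarray(values, dtype=float)
    defaults = dict(roi_id="r0", neuron_class="DN1a", channel="GCaMP", zt=6.0)
    defaults.update(kw)
    return FluorescenceTrace(
        times=np.arange(values.size) * dt, values=values, **defaults
    )


class TestComputeDff:
    def test_constant_trace_gives_zero_percent(self):
        d = compute_dff(trace(np.full(50, 100.0)), (0.0, 10.0))
        np.testing.assert_allclose(d.dff, 0.0)

    def test_hand_computed_fifty_percent(self):
        values = np.full(40, 100.0)
        values[30] = 150.0
        d = compute_dff(trace(values), (0.0, 10.0))
        assert d.f0 == pytest.approx(100.0)
        assert d.dff[30] == pytest.approx(50.0)

    def test_multiplicative_scale_invariance(self, rng):
        values = rng.uniform(50.0, 150.0, size=60)
        a = compute_dff(trace(values), (0.0, 20.0))
        b = compute_dff(trace(values * 2.7), (0.0, 20.0))
        np.testing.assert_allclose(a.dff, b.dff, rtol=1e-12)

    def test_additive_offset_is_not_invariant(self, rng):
        values = rng.uniform(50.0, 150.0, size=60)
        a = compute_dff(trace(values), (0.0, 20.0))
        b = compute_dff(trace(values + 40.0), (0.0, 20.0))
        assert not np.allclose(a.dff, b.dff)

    def test_literal_mode_uses_first_sample(self):
        values = np.array([80.0, 120.0, 100.0, 90.0])
        d = compute_dff(trace(values), (0.0, 2.0), f0_mode="literal")
        assert d.f0 == 80.0

    def test_errors(self):
        with pytest.raises(CalciumError, match="no samples"):
            compute_dff(trace(np.ones(10)), (100.0, 110.0))
        with pytest.raises(CalciumError, match="non-physical"):
            compute_dff(trace(np.zeros(10)), (0.0, 5.0))


class TestMaxDff:
    def test_examples(self):
        d = DeltaFTrace("r", np.arange(4.0), np.array([0.0, 10.0, 50.0, 20.0]),
                        100.0, (0.0, 1.0))
        assert compute_max_dff(d, (0.0, 4.0)) == 50.0
        z = DeltaFTrace("r", np.arange(4.0), np.zeros(4), 100.0, (0.0, 1.0))
        assert compute_max_dff(z, (0.0, 4.0)) == 0.0

    def test_signed_extremum_preserves_inhibition_sign(self):
        d = DeltaFTrace("r", np.arange(4.0), np.array([0.0, -60.0, 30.0, 5.0]),
                        100.0, (0.0, 1.0))
        assert compute_max_dff(d, (0.0, 4.0)) == 30.0
        assert compute_max_dff(d, (0.0, 4.0), signed_extremum=True) == -60.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(50):
            vals = rng.normal(0.0, 30.0, size=100)
            d = DeltaFTrace("r", np.arange(100.0), vals, 100.0, (0.0, 1.0))
            lo = float(rng.integers(0, 50))
            hi = lo + float(rng.integers(5, 50))
            brute = max(v for t, v in zip(d.times, vals) if lo <= t < hi)
            assert compute_max_dff(d, (lo, hi)) == pytest.approx(brute)


class TestStepResponse:
    def test_flat_trace_is_nonresponsive_fold_one(self, heating_protocol):
        t = trace(np.full(240, 100.0))
        r = quantify_step_response(t, heating_protocol, 0)
        assert r.fold_change == pytest.approx(1.0)
        assert r.response_class == "nonresponsive"

    def test_noiseless_heating_activates_dn1a(self, heating_protocol):
        cfg = synth.SynthConfig(master_seed=0)
        cfg.calcium.noise_sd = 0.0
        (gc, td), = synth.gen_two_channel_traces(cfg, heating_protocol, 18.0)
        r = quantify_step_response(gc, heating_protocol, 0, tdtom=td)
        assert r.fold_change > 1.0
        assert r.response_class == "activated"
        assert r.delta_t_c == pytest.approx(8.0)

    def test_ratiometric_fold_invariant_to_common_drift(self, heating_protocol):
        cfg = synth.SynthConfig(master_seed=0)
        cfg.calcium.noise_sd = 0.0
        (gc, td), = synth.gen_two_channel_traces(cfg, heating_protocol, 18.0)
        drift = np.exp(-gc.times / 300.0)
        gc2 = dataclasses.replace(gc, values=gc.values * drift)
        td2 = dataclasses.replace(td, values=td.values * drift)
        r1 = quantify_step_response(gc, heating_protocol, 0, tdtom=td)
        r2 = quantify_step_response(gc2, heating_protocol, 0, tdtom=td2)
        assert r1.fold_change == pytest.approx(r2.fold_change, rel=1e-12)

    def test_mean_fold_change_matches_noiseless_expectation(self, heating_protocol):
        """n=16 noisy DN1a traces: mean fold change within 3 SE of the
        deterministic (noise-free) generator expectation."""
        cfg = synth.SynthConfig(master_seed=11)
        noiseless = dataclasses.replace(
            cfg, calcium=dataclasses.replace(cfg.calcium, noise_sd=0.0)
        )
        (gc0, td0), = synth.gen_two_channel_traces(noiseless, heating_protocol, 18.0)
        expect = quantify_step_response(gc0, heating_protocol, 0, tdtom=td0).fold_change
        folds = [
            quantify_step_response(gc, heating_protocol, 0, tdtom=td).fold_change
            for gc, td in synth.gen_two_channel_traces(
                cfg, heating_protocol, 18.0, ("DN1a",), n_per_class=16
            )
        ]
        folds = np.asarray(folds)
        se = folds.std(ddof=1) / np.sqrt(folds.size)
        assert abs(folds.mean() - expect) < 3 * se

    def test_window_validation(self, heating_protocol):
        t = trace(np.full(240, 100.0))
        with pytest.raises(CalciumError, match="out of range"):
            quantify_step_response(t, heating_protocol, 5)
        # trace begins after the step: pre window holds no samples
        late = FluorescenceTrace(
            "r0", "DN1a", "GCaMP",
            times=np.arange(150.0, 240.0), values=np.full(90, 100.0), zt=6.0,
        )
        with pytest.raises(CalciumError, match="no samples"):
            quantify_step_response(late, heating_protocol, 0)


class TestSaturationSummary:
    @staticmethod
    def responses_for_grid(seed, noise_sd=2.0, n_per=8, tau_sensor_s=10.0):
        cfg = synth.SynthConfig(master_seed=seed)
        cfg.calcium.noise_sd = noise_sd
        cfg.calcium.tau_sensor_s = tau_sensor_s
        out = []
        for target in (14.0, 16.0, 18.0, 20.0, 22.0):  # cooling from 24
            protocol = TemperatureProtocol(24.0, [(60.0, target, 80.0)], 240.0)
            for gc, td in synth.gen_two_channel_traces(
                cfg, protocol, 18.0, ("DN1a",), n_per_class=n_per
            ):
                out.append(quantify_step_response(gc, protocol, 0, tdtom=td))
        for target in (24.0, 26.0, 28.0, 30.0, 32.0):  # heating from 22
            protocol = TemperatureProtocol(22.0, [(60.0, target, 80.0)], 240.0)
            for gc, td in synth.gen_two_channel_traces(
                cfg, protocol, 18.0, ("DN1a",), n_per_class=n_per
            ):
                out.append(quantify_step_response(gc, protocol, 0, tdtom=td))
        return out

    def test_noiseless_clamp_means_equal_beyond_minus_six(self):
        # fast sensor so the post window holds pure steady-state response
        responses = self.responses_for_grid(
            seed=0, noise_sd=0.0, n_per=1, tau_sensor_s=0.1
        )
        table = saturation_summary(responses)
        cool = table[table["side"] == "cooling"].set_index("abs_delta_t_c")
        assert cool.loc[6.0, "mean"] == pytest.approx(cool.loc[8.0, "mean"], rel=1e-4)
        assert cool.loc[8.0, "mean"] == pytest.approx(cool.loc[10.0, "mean"], rel=1e-4)
        assert estimate_saturation_point(table, "cooling") == 6.0
        assert estimate_saturation_point(table, "heating") == 8.0

    def test_single_fly_sem_is_missing(self):
        responses = self.responses_for_grid(seed=0, noise_sd=0.0, n_per=1)
        table = saturation_summary(responses)
        assert table["sem"].isna().all()
        assert (table["n"] == 1).all()

    def test_requires_two_amplitudes(self, heating_protocol):
        cfg = synth.SynthConfig(master_seed=0)
        (gc, td), = synth.gen_two_channel_traces(cfg, heating_protocol, 18.0)
        r = quantify_step_response(gc, heating_protocol, 0, tdtom=td)
        with pytest.raises(CalciumError):
            saturation_summary([r, r])


class TestCorrelateAndCluster:
    def dff_pair(self, values, roi):
        return DeltaFTrace(roi, np.arange(len(values), dtype=float),
                           np.asarray(values, dtype=float), 100.0, (0.0, 1.0))

    def test_duplicate_traces_correlate_perfectly(self, rng):
        v = rng.normal(0, 10, 50)
        res = correlate_and_cluster([self.dff_pair(v, "a"), self.dff_pair(v, "b"),
                                     self.dff_pair(-v, "c")])
        assert res.corr.loc["a", "b"] == pytest.approx(1.0)
        assert res.corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_zero_variance_trace_excluded_with_warning(self, rng):
        v = rng.normal(0, 10, 50)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = correlate_and_cluster(
                [self.dff_pair(v, "a"), self.dff_pair(v * 0.5, "b"),
                 self.dff_pair(np.zeros(50), "flat")]
            )
        assert res.excluded == ["flat"]
        assert res.corr.loc["flat"].isna().all()
        assert "flat" not in res.labels

    def test_two_planted_classes_recovered(self, rng):
        resp = np.concatenate([np.zeros(20), np.ones(60), np.zeros(20)])
        dffs = []
        for i in range(8):
            noise = rng.normal(0, 0.2, 100)
            dffs.append(self.dff_pair(resp + noise, f"act{i}"))
        for i in range(8):
            noise = rng.normal(0, 0.2, 100)
            dffs.append(self.dff_pair(-resp + noise, f"inh{i}"))
        res = correlate_and_cluster(dffs, n_clusters=2)
        act = {res.labels[f"act{i}"] for i in range(8)}
        inh = {res.labels[f"inh{i}"] for i in range(8)}
        assert len(act) == 1 and len(inh) == 1 and act != inh

    def test_leaf_order_is_deterministic(self, rng):
        dffs = [self.dff_pair(rng.normal(0, 1, 40), f"r{i}") for i in range(6)]
        a = correlate_and_cluster(dffs)
        b = correlate_and_cluster(dffs)
        assert a.leaf_order == b.leaf_order
        assert a.labels == b.labels


class TestLocomotionChange:
    def episode(self, pre_level, post_level, fly="f0", noise=None):
        times = np.arange(0.0, 120.0, 1.0)
        speed = np.where(times < 60.0, pre_level, post_level).astype(float)
        if noise is not None:
            speed = speed + noise
        return LocomotionEpisode(fly, times, speed, event_s=60.0,
                                 pre_window_s=30.0, post_window_s=30.0)

    def test_identical_pre_post_gives_zero_and_p_one(self):
        eps = [self.episode(2.0, 2.0, fly=f"f{i}") for i in range(4)]
        res = locomotion_change(eps)
        assert res["mean_difference"] == 0.0
        assert res["p_value"] == pytest.approx(1.0)

    def test_stopped_fly_gives_negative_difference(self):
        res = locomotion_change([self.episode(3.0, 0.0)])
        assert res["mean_difference"] == pytest.approx(-3.0)
        assert res["p_value"] is None  # n < 2: means only

    def test_planted_speed_increase_recovered(self, rng):
        delta = 1.5
        eps = [
            self.episode(2.0, 2.0 + delta, fly=f"f{i}",
                         noise=rng.normal(0, 0.3, 120))
            for i in range(24)
        ]
        res = locomotion_change(eps)
        diffs = res["post_means"] - res["pre_means"]
        se = diffs.std(ddof=1) / np.sqrt(diffs.size)
        assert abs(res["mean_difference"] - delta) < 3 * se
        assert res["p_value"] < 0.001
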