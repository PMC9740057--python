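"""DCE conversion and semi-quantitative metrics: baseline, SPGR inversion,
AUC integration, and the T1 ratio."""

import warnings

import numpy as np
import pytest

from vdamri import dce
from vdamri.phantom.presets import tissue_concentration_curve
from vdamri.phantom.simulate import simulate_dce_series, spgr_signal
from vdamri.relaxometry import ParameterMap


def make_series(protocol, frames):
    return dce.DynamicSeries(frames, protocol.frame_times_s, protocol.n_pre_frames, protocol)


class TestBaseline:
    def test_constant_signal(self, protocol):
        frames = np.full((2, 2, 100), 500.0)
        base, sd = dce.estimate_baseline(make_series(protocol, frames))
        assert np.all(base == 500.0) and np.all(sd == 0.0)

    def test_mean_of_pre_frames(self, protocol):
        frames = np.zeros((1, 100))
        frames[0, :20] = np.tile([90.0, 110.0], 10)
        base, _ = dce.estimate_baseline(make_series(protocol, frames))
        assert base[0] == pytest.approx(100.0)

    def test_baseline_matches_spgr_forward_model(self, small_phantom, protocol):
        labels, records, vols = small_phantom
        dyn = simulate_dce_series(labels, records, protocol)
        base, _ = dce.estimate_baseline(dyn)
        rec = records["extracranial_tumor"]
        expected = spgr_signal(rec.t1_ms, rec.m0, protocol.dce_flip_angle_deg,
                               protocol.dce_tr_ms)
        roi = labels.roi_mask("extracranial_tumor")
        assert np.max(np.abs(base[roi] - expected)) < 1e-9 * expected

    def test_requires_two_pre_frames(self, protocol):
        with pytest.raises(ValueError):
            series = dce.DynamicSeries(np.ones((1, 81)), protocol.frame_times_s[19:],
                                       1, protocol)
            dce.estimate_baseline(series)


class TestSignalToConcentration:
    def test_signal_at_baseline_gives_zero(self, protocol):
        t10 = np.full((3, 3), 1500.0)
        base_val = spgr_signal(1500.0, 1000.0, protocol.dce_flip_angle_deg, protocol.dce_tr_ms)
        frames = np.full((3, 3, 100), base_val)
        series = make_series(protocol, frames)
        base, _ = dce.estimate_baseline(series)
        conc, valid = dce.signal_to_concentration(series, base, t10, protocol)
        assert np.all(valid)
        assert np.max(np.abs(conc)) < 1e-9

    def test_forward_inverse_round_trip(self, small_phantom, protocol):
        labels, records, vols = small_phantom
        dyn = simulate_dce_series(labels, records, protocol)
        base, _ = dce.estimate_baseline(dyn)
        conc, valid = dce.signal_to_concentration(dyn, base, vols["t1_ms"], protocol,
                                                  mask=labels.labels > 0)
        for roi, rec in records.items():
            m = labels.roi_mask(roi)
            true_c = tissue_concentration_curve(rec.curve_params,
                                                np.maximum(protocol.frame_times_s, 0.0))
            err = np.abs(conc[m] - true_c)
            assert valid[m].all()
            assert err.max() < 1e-6  # mmol/L

    def test_doubling_r1_halves_concentration(self, small_phantom, protocol):
        import dataclasses

        labels, records, vols = small_phantom
        dyn = simulate_dce_series(labels, records, protocol)
        base, _ = dce.estimate_baseline(dyn)
        c1, _ = dce.signal_to_concentration(dyn, base, vols["t1_ms"], protocol,
                                            mask=labels.labels > 0)
        prot2 = dataclasses.replace(protocol, r1_relaxivity=2 * protocol.r1_relaxivity)
        c2, _ = dce.signal_to_concentration(dyn, base, vols["t1_ms"], prot2,
                                            mask=labels.labels > 0)
        m = labels.labels > 0
        assert np.allclose(c2[m], c1[m] / 2, atol=1e-12)

    def test_saturating_signal_marked_invalid(self, protocol):
        t10 = np.full((1,), 1500.0)
        base_val = spgr_signal(1500.0, 1000.0, protocol.dce_flip_angle_deg, protocol.dce_tr_ms)
        frames = np.full((1, 100), base_val)
        frames[0, 50] = base_val * 1e4  # beyond the SPGR ceiling
        series = make_series(protocol, frames)
        base, _ = dce.estimate_baseline(series)
        conc, valid = dce.signal_to_concentration(series, base, t10, protocol)
        assert not valid[0, 50]
        assert valid[0, :20].all()

    def test_linear_mode_proportional_to_full_inversion_at_low_uptake(
            self, small_phantom, protocol):
        # the first-order mode carries a systematic gain (it assumes signal
        # proportional to R1) but must track the full inversion's shape
        labels, records, vols = small_phantom
        dyn = simulate_dce_series(labels, records, protocol)
        base, _ = dce.estimate_baseline(dyn)
        spgr_c, _ = dce.signal_to_concentration(dyn, base, vols["t1_ms"], protocol,
                                                mask=labels.labels > 0)
        lin_c, _ = dce.signal_to_concentration(dyn, base, vols["t1_ms"], protocol,
                                               mask=labels.labels > 0, mode="linear")
        m = labels.roi_mask("brain")  # low uptake -> first-order regime
        a = spgr_c[m].mean(axis=0)[25:]
        b = lin_c[m].mean(axis=0)[25:]
        assert np.corrcoef(a, b)[0, 1] > 0.999
        ratio = b / a
        assert np.std(ratio) / np.mean(ratio) < 0.1


class TestAuc:
    def _unit_curve(self):
        t = np.arange(1.8, 300, 3.6)
        return dce.ConcentrationCurve(t, np.ones_like(t))

    def test_rectangle_value(self):
        # C == 1 mmol/L over (0, 30] -> 0.5 mmol/L*min up to the C(0)=0 ramp
        t = np.array([0.01, 10.0, 20.0, 28.0, 32.0, 40.0])
        c = np.ones_like(t)
        val = dce.auc(dce.ConcentrationCurve(t, c), 30.0)
        assert val == pytest.approx(0.5, abs=1e-4)

    def test_additivity(self):
        curve = self._unit_curve()
        rng = np.random.default_rng(0)
        curve.conc_mM[:] = rng.uniform(0, 1, curve.conc_mM.size)
        whole = dce.auc_between(curve, 0.0, 250.0)
        split = dce.auc_between(curve, 0.0, 30.0) + dce.auc_between(curve, 30.0, 250.0)
        assert abs(whole - split) < 1e-12

    def test_monotone_in_window_and_scale(self):
        curve = self._unit_curve()
        a, b = dce.auc(curve, 30.0), dce.auc(curve, 200.0)
        assert b > a
        double = dce.ConcentrationCurve(curve.times_s, 2 * curve.conc_mM)
        assert dce.auc(double, 30.0) == pytest.approx(2 * a, rel=1e-12)

    def test_window_between_samples_interpolated(self):
        # samples at 28.8 and 32.4 straddle 30 s
        t = np.array([28.8, 32.4])
        c = np.array([1.0, 2.0])
        val = dce.auc(dce.ConcentrationCurve(t, c), 30.0)
        c30 = 1.0 + (30.0 - 28.8) / 3.6  # linear interpolation
        expected = (0.5 * 1.0 * 28.8 + 0.5 * (1.0 + c30) * 1.2) / 60.0
        assert val == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            dce.auc(self._unit_curve(), 0.0)

    def test_window_past_support_truncates_with_warning(self):
        curve = self._unit_curve()
        with pytest.warns(UserWarning, match="truncated"):
            val = dce.auc(curve, 310.0)
        assert val > 0

    def test_strict_mode_raises_far_past_support(self):
        curve = self._unit_curve()
        with pytest.raises(ValueError):
            dce.auc(curve, 400.0, strict=True)

    @pytest.mark.parametrize(
        "preset,roi,a30,a300",
        [
            ("extracranial_pre", "extracranial_tumor", 0.067, 0.193),
            ("intracranial_pre", "intracranial_tumor", 0.058, 0.063),
            ("extracranial_1h", "extracranial_tumor", 0.008, 0.030),
        ],
    )
    def test_roi_auc_recovery_within_one_percent(self, protocol, preset, roi, a30, a300):
        from vdamri.phantom.geometry import build_phantom, parameter_volumes

        labels, records = build_phantom((24, 24, 8), preset, seed=0)
        vols = parameter_volumes(labels, records)
        dyn = simulate_dce_series(labels, records, protocol)
        base, _ = dce.estimate_baseline(dyn)
        conc, valid = dce.signal_to_concentration(dyn, base, vols["t1_ms"], protocol,
                                                  mask=labels.labels > 0)
        curve = dce.roi_mean_curve(conc, valid, dyn, labels.roi_mask(roi), roi)
        assert dce.auc(curve, 30.0) == pytest.approx(a30, rel=0.01)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert dce.auc(curve, 300.0) == pytest.approx(a300, rel=0.01)

    def test_voxelwise_map_matches_roi_curve_on_uniform_roi(self, small_phantom, protocol):
        labels, records, vols = small_phantom
        dyn = simulate_dce_series(labels, records, protocol)
        base, _ = dce.estimate_baseline(dyn)
        conc, valid = dce.signal_to_concentration(dyn, base, vols["t1_ms"], protocol,
                                                  mask=labels.labels > 0)
        amap = dce.voxelwise_auc_map(conc, valid, dyn, 30.0, mask=labels.labels > 0)
        m = labels.roi_mask("extracranial_tumor")
        curve = dce.roi_mean_curve(conc, valid, dyn, m)
        assert amap.values[m].mean() == pytest.approx(dce.auc(curve, 30.0), rel=1e-9)

    def test_pre_injection_concentration_stays_at_noise_floor(self, protocol):
        from vdamri.phantom.geometry import build_phantom, parameter_volumes

        labels, records = build_phantom((20, 20, 8), "pre", seed=2)
        vols = parameter_volumes(labels, records)
        dyn = simulate_dce_series(labels, records, protocol, noise_sd=2.0, seed=5)
        base, sd = dce.estimate_baseline(dyn)
        conc, valid = dce.signal_to_concentration(dyn, base, vols["t1_ms"], protocol,
                                                  mask=labels.labels > 0)
        m = labels.labels > 0
        pre_c = conc[m][:, :20]
        # propagated noise floor: sigma_C ~ sigma_S * dC/dS at baseline,
        # bounded empirically by the ROI-mean pre-injection spread
        assert np.abs(pre_c.mean(axis=0)).max() < 3 * pre_c.std()


class TestT1Ratio:
    def _map(self, values, valid=None):
        values = np.asarray(values, dtype=float)
        valid = np.ones_like(values, dtype=bool) if valid is None else valid
        return ParameterMap(values, "ms", valid)

    def test_identity(self):
        m = self._map(np.full((3, 3), 1200.0))
        ratio = dce.t1_ratio(m, m)
        assert np.all(ratio.values == 1.0)

    def test_halving(self):
        pre = self._map(np.full(5, 1000.0))
        post = self._map(np.full(5, 500.0))
        assert np.all(dce.t1_ratio(post, pre).values == 0.5)

    def test_invalid_denominator_propagates(self):
        pre = self._map([1000.0, 0.0], valid=np.array([True, True]))
        post = self._map([500.0, 500.0])
        ratio = dce.t1_ratio(post, pre)
        assert ratio.validity_mask[0] and not ratio.validity_mask[1]

    def test_preset_ratio_through_fitted_maps(self, protocol):
        from vdamri.phantom.geometry import build_phantom, parameter_volumes
        from vdamri.phantom.simulate import simulate_vfa_series
        from vdamri.relaxometry import fit_t1_vfa

        labels, records = build_phantom((24, 24, 8), "extracranial_1h", seed=0)
        vols = parameter_volumes(labels, records)
        pre, _ = fit_t1_vfa(simulate_vfa_series(vols["t1_ms"], vols["m0"], protocol),
                            protocol.tr_ms, mask=labels.labels > 0)
        post, _ = fit_t1_vfa(simulate_vfa_series(vols["ce_t1_ms"], vols["m0"], protocol),
                             protocol.tr_ms, mask=labels.labels > 0)
        ratio = dce.t1_ratio(post, pre)
        m = labels.roi_mask("extracranial_tumor")
        assert ratio.values[m].mean() == pytest.approx(0.429, rel=0.005)
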