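"""Phantom presets, geometry, concentration curves and forward simulators."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.integrate import quad

from vdamri.phantom.geometry import build_phantom, parameter_volumes
from vdamri.phantom.presets import (
    GammaVariateParams,
    curve_integral,
    get_preset,
    ground_truth_from_json,
    ground_truth_to_json,
    solve_gamma_variate,
    tissue_concentration_curve,
)
from vdamri.phantom.simulate import (
    add_noise,
    simulate_dce_series,
    simulate_dwi_series,
    simulate_multiecho_series,
    simulate_vfa_series,
    spgr_signal,
)
from vdamri.relaxometry import fit_adc, fit_t1_vfa, fit_t2


class TestPresets:
    @pytest.mark.parametrize(
        "preset,roi,auc30",
        [
            ("extracranial_pre", "extracranial_tumor", 0.067),
            ("intracranial_pre", "intracranial_tumor", 0.058),
            ("extracranial_1h", "extracranial_tumor", 0.008),
        ],
    )
    def test_presets_carry_printed_perfusion_values(self, preset, roi, auc30):
        rec = get_preset(preset)[roi]
        assert rec.auc30_true == auc30
        # the stored curve's closed-form integral reproduces the preset
        assert curve_integral(rec.curve_params, 30.0) / 60.0 == pytest.approx(auc30, rel=1e-9)

    def test_relaxometry_presets(self):
        pre = get_preset("pre")
        assert pre["extracranial_tumor"].t2_ms == 128.2
        assert pre["extracranial_tumor"].ce_t1_ms == 786.1
        assert pre["intracranial_tumor"].t2_ms == 111.5
        assert pre["intracranial_tumor"].ce_t1_ms == 1020.9

    def test_t1_ratio_presets(self):
        assert get_preset("extracranial_1h")["extracranial_tumor"].t1_ratio_true == pytest.approx(
            0.429, rel=1e-12
        )
        assert get_preset("pre")["intracranial_tumor"].t1_ratio_true == pytest.approx(
            0.497, rel=1e-12
        )

    def test_unknown_preset(self):
        with pytest.raises(KeyError, match="unknown preset"):
            get_preset("nonexistent")

    def test_serialization_round_trip(self, tmp_path):
        records = get_preset("1h")
        path = tmp_path / "gt.json"
        ground_truth_to_json(records, path)
        back = ground_truth_from_json(path)
        assert back == records


class TestConcentrationCurve:
    def test_zero_amplitude_curve_is_flat(self):
        p = GammaVariateParams(0.0)
        t = np.linspace(0, 300, 50)
        assert np.all(tissue_concentration_curve(p, t) == 0)

    def test_curve_starts_at_zero_and_is_nonnegative(self):
        p = GammaVariateParams(1e-3, 2.0, 12.0)
        t = np.linspace(0, 300, 200)
        c = tissue_concentration_curve(p, t)
        assert c[0] == 0
        assert np.all(c >= 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            tissue_concentration_curve(GammaVariateParams(1e-3), [-1.0, 2.0])

    @pytest.mark.parametrize("bad", [dict(amplitude=-1), dict(amplitude=1, shape=0),
                                     dict(amplitude=1, scale_s=-2)])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            GammaVariateParams(**bad)

    def test_closed_form_integral_against_quadrature(self):
        p = GammaVariateParams(2e-3, 2.0, 14.0)
        for t_end in (30.0, 300.0):
            num, _ = quad(lambda t: tissue_concentration_curve(p, [t])[0], 0, t_end,
                          limit=200)
            assert curve_integral(p, t_end) == pytest.approx(num, rel=1e-9)

    def test_trapezoid_at_frame_rate_matches_closed_form(self):
        # sampling a gamma-variate at 3.6 s keeps the trapezoid within 0.5 %
        p = solve_gamma_variate(0.067, 0.193)
        t = np.arange(0, 300.1, 3.6)
        c = tissue_concentration_curve(p, t)
        trap = np.trapezoid(c, t)
        assert trap == pytest.approx(curve_integral(p, t[-1]), rel=5e-3)

    def test_solver_matches_both_windows(self):
        for a30, a300 in [(0.067, 0.193), (0.058, 0.063), (0.008, 0.030), (0.012, 0.035)]:
            p = solve_gamma_variate(a30, a300)
            assert curve_integral(p, 30.0) / 60.0 == pytest.approx(a30, rel=1e-9)
            assert curve_integral(p, 300.0) / 60.0 == pytest.approx(a300, rel=1e-9)

    def test_solver_rejects_impossible_targets(self):
        with pytest.raises(ValueError):
            solve_gamma_variate(0.1, 0.05)  # AUC300 < AUC30
        with pytest.raises(ValueError):
            solve_gamma_variate(0.0, 0.1)  # zero uptake cannot accumulate


class TestGeometry:
    def test_label_map_has_exactly_the_four_labels(self):
        labels, records = build_phantom((40, 40, 12), "pre", seed=3)
        assert set(np.unique(labels.labels).tolist()) == {0, 1, 2, 3}
        assert set(records) == {"brain", "intracranial_tumor", "extracranial_tumor"}

    def test_rois_nonempty_disjoint_connected(self):
        labels, _ = build_phantom((48, 48, 14), "pre", seed=7)
        struct = ndimage.generate_binary_structure(3, 1)
        for lab in (1, 2, 3):
            mask = labels.labels == lab
            assert mask.any()
            assert ndimage.label(mask, structure=struct)[1] == 1

    def test_grid_too_small_raises(self):
        with pytest.raises(ValueError):
            build_phantom((3, 3, 2), "pre", seed=0)

    def test_unknown_preset_raises_before_building(self):
        with pytest.raises(KeyError):
            build_phantom((32, 32, 8), "bogus", seed=0)

    def test_parameter_volumes_requires_all_records(self, small_phantom):
        labels, records, _ = small_phantom
        partial = {k: v for k, v in records.items() if k != "brain"}
        with pytest.raises(KeyError, match="brain"):
            parameter_volumes(labels, partial)


class TestForwardModels:
    def test_spgr_closed_form(self):
        # T1=1000 ms, M0=1000, TR=15 ms, alpha=30 deg
        e1 = np.exp(-15.0 / 1000.0)
        expected = 1000 * np.sin(np.pi / 6) * (1 - e1) / (1 - e1 * np.cos(np.pi / 6))
        assert spgr_signal(1000.0, 1000.0, 30.0, 15.0) == pytest.approx(expected, rel=1e-12)

    def test_spgr_long_t1_limit_vanishes(self):
        s = spgr_signal(1e12, 1000.0, np.array([5.0, 15.0, 25.0]), 15.0)
        assert np.all(s < 1e-6)

    def test_spgr_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            spgr_signal(1000, 1000, 95.0, 15.0)
        with pytest.raises(ValueError):
            spgr_signal(1000, 1000, 30.0, 0.0)

    def test_multiecho_closed_form_and_monotone(self, protocol):
        st = simulate_multiecho_series(np.array([100.0]), np.array([1000.0]), protocol)
        te = np.asarray(protocol.echo_times_ms)
        assert st.volumes[0] == pytest.approx(1000 * np.exp(-te / 100.0), rel=1e-12)
        assert np.all(np.diff(st.volumes[0]) < 0)
        assert st.volumes[0][0] < 1000.0

    def test_dwi_identity_and_closed_form(self):
        st = simulate_dwi_series(np.array([1.0e-3]), np.array([1000.0]), (0.0, 1000.0))
        assert st.volumes[0, 0] == 1000.0
        assert st.volumes[0, 1] == pytest.approx(1000.0 / np.e, rel=1e-12)

    def test_dwi_noiseless_round_trip(self):
        adc = np.full((6, 6), 0.8e-3)
        st = simulate_dwi_series(adc, np.full((6, 6), 500.0), (0, 500, 1000))
        fitted = fit_adc(st)
        assert np.max(np.abs(fitted.values - 0.8e-3) / 0.8e-3) < 1e-9

    def test_noise_determinism_under_seed(self, protocol):
        t1 = np.full((5, 5), 900.0)
        m0 = np.full((5, 5), 800.0)
        a = simulate_vfa_series(t1, m0, protocol, noise_sd=5.0, seed=77)
        b = simulate_vfa_series(t1, m0, protocol, noise_sd=5.0, seed=77)
        c = simulate_vfa_series(t1, m0, protocol, noise_sd=5.0, seed=78)
        assert np.array_equal(a.volumes, b.volumes)
        assert not np.array_equal(a.volumes, c.volumes)

    def test_rician_noise_is_magnitude_valued(self, rng):
        noisy = add_noise(np.zeros(10000), 5.0, rng, model="rician")
        assert np.all(noisy >= 0)
        # Rayleigh mean at zero signal: sigma * sqrt(pi/2)
        assert noisy.mean() == pytest.approx(5.0 * np.sqrt(np.pi / 2), rel=0.05)


class TestDceSimulation:
    def test_hundred_frames_and_baseline_flat(self, small_phantom, protocol):
        labels, records, _ = small_phantom
        dyn = simulate_dce_series(labels, records, protocol)
        assert dyn.frames.shape[-1] == 100
        pre = dyn.frames[..., :20]
        assert np.all(pre.std(axis=-1) < 1e-12)

    def test_zero_amplitude_curves_give_constant_series(self, protocol):
        labels, records = build_phantom((24, 24, 8), "pre", seed=0)
        import dataclasses

        from vdamri.phantom.presets import GammaVariateParams

        flat = {
            k: dataclasses.replace(v, curve_params=GammaVariateParams(0.0),
                                   auc30_true=0.0, auc300_true=0.0)
            for k, v in records.items()
        }
        dyn = simulate_dce_series(labels, flat, protocol)
        assert np.all(dyn.frames.std(axis=-1) < 1e-12)

    def test_missing_ground_truth_raises(self, small_phantom, protocol):
        labels, records, _ = small_phantom
        partial = {k: v for k, v in records.items() if k != "extracranial_tumor"}
        with pytest.raises(KeyError, match="extracranial_tumor"):
            simulate_dce_series(labels, partial, protocol)


class TestNoiseBias:
    """With Rician noise at SNR 50 the fitted T1/T2 stay essentially
    unbiased: the median signed relative error over thousands of voxels is
    well under 2 %."""

    def test_t2_bias_bound(self, protocol):
        n = 2000
        st = simulate_multiecho_series(np.full(n, 100.0), np.full(n, 1000.0),
                                       protocol, noise_sd=1000.0 / 50, seed=11)
        t2, _ = fit_t2(st)
        err = (t2.values[t2.validity_mask] - 100.0) / 100.0
        assert err.size >= 1000
        assert abs(np.median(err)) < 0.02

    def test_t1_bias_bound(self, protocol):
        n = 2000
        t1_true, m0 = np.full(n, 1000.0), np.full(n, 1000.0)
        peak = simulate_vfa_series(t1_true, m0, protocol).volumes.max()
        st = simulate_vfa_series(t1_true, m0, protocol, noise_sd=peak / 50, seed=42)
        t1, _ = fit_t1_vfa(st, protocol.tr_ms)
        err = (t1.values[t1.validity_mask] - 1000.0) / 1000.0
        assert err.size >= 1000
        assert abs(np.median(err)) < 0.02
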