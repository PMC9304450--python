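import hashlib

import numpy as np
import pytest

from ataa import io as ataa_io
from ataa.constitutive import FitOptions, cauchy_stresses, fit_hgo
from ataa.datasets import BIOMARKER_RANGES
from ataa.geometry import centerline_from_masks, max_diameter, \
    tortuosity_index
from ataa.hemodynamics import field_summary, osi, tawss, \
    WindkesselParams, windkessel_pressure
from ataa.stats import tobit_fit
from ataa.synthetic import (
    GeneratorConfig,
    gen_biaxial,
    gen_cohort,
    gen_inflow,
    gen_vessel,
    gen_wss_field,
    inline_wss_truth,
    voxelize_centerline,
)


class TestGenBiaxial:
    def test_zero_noise_self_consistency(self, truth_params):
        sample, sidecar = gen_biaxial(truth_params, seed=0)
        st, sz = cauchy_stresses(truth_params, sample.lambda_theta,
                                 sample.lambda_z)
        assert np.array_equal(st, sample.sigma_theta)
        assert np.array_equal(sz, sample.sigma_z)
        assert sidecar["truth_params"]["c_mpa"] == truth_params.c

    def test_six_protocols_emitted(self, noiseless_biaxial):
        sample, _ = noiseless_biaxial
        assert len(sample.protocols) == 6
        assert all(p.startswith(("inflation", "extension"))
                   for p in sample.protocols)

    def test_stress_monotone_in_pressure_along_inflation(self, truth_params):
        sample, _ = gen_biaxial(truth_params, seed=0)
        for pid in ("inflation_1.3", "inflation_1.4", "inflation_1.5"):
            m = sample.protocol_id == pid
            sig = sample.sigma_theta[m]  # rows are in pressure order
            assert np.all(np.diff(sig) > 0)

    def test_round_trip_fit(self, noiseless_biaxial):
        sample, _ = noiseless_biaxial
        result = fit_hgo(sample, FitOptions(n_starts=15, seed=2))
        assert result.mse < 1e-10

    def test_seed_reproducibility(self, truth_params, tmp_path):
        digests = []
        for _ in range(2):
            sample, _ = gen_biaxial(truth_params, noise_sd_mpa=0.01, seed=5)
            path = tmp_path / "b.csv"
            ataa_io.write_biaxial_csv(sample, path, seed=5)
            digests.append(hashlib.sha256(path.read_bytes()).hexdigest())
        assert digests[0] == digests[1]


class TestInlineWSSTruth:
    def test_no_oscillation(self):
        t, o = inline_wss_truth(2.0, 0.0)
        assert (t, o) == (2.0, 0.0)

    def test_pure_reversal(self):
        t, o = inline_wss_truth(3.0, 1.0)
        assert t == pytest.approx(2 * 3.0 / np.pi)
        assert o == pytest.approx(0.5)

    def test_subcritical_fraction_no_reversal(self):
        t, o = inline_wss_truth(1.0, 0.4)
        assert t == pytest.approx(0.6)
        assert o == 0.0

    def test_matches_quadrature(self):
        a, f, period = 1.7, 0.83, 0.1
        tt = np.linspace(0, period, 1_000_001)
        sig = a * ((1 - f) + f * np.cos(2 * np.pi * tt / period))
        t_num = np.trapezoid(np.abs(sig), tt) / period
        o_num = 0.5 * (1 - abs(np.trapezoid(sig, tt))
                       / np.trapezoid(np.abs(sig), tt))
        t_cf, o_cf = inline_wss_truth(a, f)
        assert t_cf == pytest.approx(t_num, rel=1e-9)
        assert o_cf == pytest.approx(o_num, abs=1e-9)

    def test_invalid_fraction_raises(self):
        with pytest.raises(ValueError):
            inline_wss_truth(1.0, 1.2)


class TestGenWSSField:
    def test_steady_field_trivial_truth(self):
        amp = {r: 2.0 for r in ("ascending", "arch", "descending")}
        f = {r: 0.0 for r in ("ascending", "arch", "descending")}
        series, sidecar = gen_wss_field(amplitude=amp, osc_fraction=f,
                                        amplitude_jitter=0.0, osc_jitter=0.0,
                                        seed=0)
        assert np.allclose(osi(series), 0.0, atol=1e-12)
        assert np.allclose(tawss(series), 2.0, rtol=1e-9)

    def test_pure_reversal_node_osi_half(self):
        amp = {r: 1.0 for r in ("ascending", "arch", "descending")}
        f = {r: 1.0 for r in ("ascending", "arch", "descending")}
        series, sidecar = gen_wss_field(amplitude=amp, osc_fraction=f,
                                        amplitude_jitter=0.0, osc_jitter=0.0,
                                        n_times=512, seed=0)
        assert np.allclose(osi(series), 0.5, atol=1e-6)
        assert np.allclose(sidecar["osi_truth"], 0.5)

    def test_sidecar_round_trip(self):
        series, sidecar = gen_wss_field(n_times=256, seed=3)
        assert np.allclose(tawss(series), sidecar["tawss_truth_pa"],
                           rtol=2e-3, atol=1e-4)
        assert np.allclose(osi(series), sidecar["osi_truth"], atol=2e-3)

    def test_rotational_component_dense_truth(self):
        series, sidecar = gen_wss_field(n_times=256, g_fraction=0.5, seed=4)
        assert sidecar["truth_kind"] == "dense_quadrature"
        assert np.allclose(tawss(series), sidecar["tawss_truth_pa"],
                           rtol=2e-3, atol=1e-4)
        assert np.allclose(osi(series), sidecar["osi_truth"], atol=2e-3)

    def test_cohort_mode_summaries_in_observed_ranges(self):
        series, _ = gen_wss_field(seed=0)  # cohort-emulation defaults
        t_field = tawss(series)
        o_field = osi(series)
        o_mean = field_summary(o_field, "mean").value
        t_max = field_summary(t_field, "max").value
        t_mean = field_summary(t_field, "mean").value
        assert BIOMARKER_RANGES["OSI_mean"][0] <= o_mean \
            <= BIOMARKER_RANGES["OSI_mean"][1]
        assert BIOMARKER_RANGES["TAWSS_max"][0] <= t_max \
            <= BIOMARKER_RANGES["TAWSS_max"][1]
        assert BIOMARKER_RANGES["TAWSS_mean"][0] <= t_mean \
            <= BIOMARKER_RANGES["TAWSS_mean"][1]

    def test_osi_bounds_everywhere(self):
        series, _ = gen_wss_field(seed=9, g_fraction=0.3)
        o = osi(series)
        assert np.all((o >= 0) & (o <= 0.5))

    def test_regions_labelled(self):
        series, _ = gen_wss_field(seed=0)
        assert set(series.regions) == {"ascending", "arch", "descending"}

    def test_invalid_fraction_rejected(self):
        f = {"ascending": 1.4, "arch": 0.5, "descending": 0.5}
        with pytest.raises(ValueError):
            gen_wss_field(osc_fraction=f)

    def test_seed_reproducibility(self, tmp_path):
        digests = []
        for _ in range(2):
            series, _ = gen_wss_field(seed=11)
            ataa_io.write_wss_bundle(series, tmp_path / "wss", seed=11)
            digests.append(hashlib.sha256(
                (tmp_path / "wss" / "wss.csv").read_bytes()).hexdigest())
        assert digests[0] == digests[1]


class TestGenVessel:
    def test_zero_perturbation_straight(self):
        cl, sidecar = gen_vessel(tortuosity_amplitude=0.0)
        assert tortuosity_index(cl) == pytest.approx(0.0, abs=1e-9)
        assert sidecar["ati"] == pytest.approx(0.0, abs=1e-9)

    def test_measured_ati_matches_sidecar(self):
        cl, sidecar = gen_vessel(tortuosity_amplitude=0.8, n_points=400)
        assert tortuosity_index(cl) == pytest.approx(sidecar["ati"], rel=0.01)

    def test_bulge_peak_recovered(self):
        cl, sidecar = gen_vessel(bulge_peak_mm=3.3)
        assert max_diameter(cl) == pytest.approx(3.3, abs=1e-3)
        assert sidecar["d_max_mm"] == pytest.approx(3.3, abs=1e-6)

    def test_amplitude_spans_observed_ati_range(self):
        # generated geometries cover the observed 22.8-59.5 window
        lo = tortuosity_index(gen_vessel(tortuosity_amplitude=1.2)[0])
        mid = tortuosity_index(gen_vessel()[0])
        hi = tortuosity_index(gen_vessel(tortuosity_amplitude=2.4)[0])
        assert lo <= 22.8 <= hi
        assert hi >= 59.5
        assert 22.8 <= mid <= 59.5

    def test_voxelized_ati_within_5_percent(self):
        cl, sidecar = gen_vessel(tortuosity_amplitude=0.8, n_points=400)
        stack = voxelize_centerline(cl)
        measured = tortuosity_index(centerline_from_masks(stack))
        assert measured == pytest.approx(sidecar["ati"], rel=0.05)

    def test_bulge_below_base_rejected(self):
        with pytest.raises(ValueError):
            gen_vessel(bulge_peak_mm=1.0, base_diameter_mm=1.4)


class TestGenInflow:
    def test_periodicity(self):
        wf = gen_inflow()
        assert wf.q[0] == pytest.approx(wf.q[-1])

    def test_stroke_volume_consistency(self):
        wf = gen_inflow(peak_flow=900.0)
        assert wf.stroke_volume == pytest.approx(
            np.trapezoid(wf.q, wf.times))

    def test_c1_continuity_at_systole_end(self):
        wf = gen_inflow(n_samples=2001)
        dq = np.gradient(wf.q, wf.times)
        # derivative stays bounded by the interior systolic slope scale
        assert np.max(np.abs(dq)) < 1.2 * np.pi * 800 / (0.35 * 0.1)

    def test_windkessel_mean_invariant(self):
        wf = gen_inflow()
        wk = WindkesselParams(19.58, 5.5e-4, 286.2)
        res = windkessel_pressure(wf, wk, n_cycles=300, tol_pa=1e-8,
                                  n_steps_per_cycle=2000)
        expected = wf.mean_flow * (wk.r_p + wk.r_d)
        assert res.p_mean == pytest.approx(expected, rel=5e-3)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            gen_inflow(systole_fraction=1.2)


class TestGenCohort:
    def test_null_model_low_r2(self):
        cfg = GeneratorConfig(seed=1, cohort_size=500, tobit_beta1=0.0,
                              tobit_beta0=23.0)
        _, six, sidecar = gen_cohort(cfg)
        df = six.df
        fit = tobit_fit(df[cfg.predictor], df["lifespan_months"],
                        df["censored"])
        assert fit.pseudo_r2 < 0.05

    def test_strong_signal_high_r2(self):
        cfg = GeneratorConfig(seed=2, cohort_size=200, tobit_sigma=0.1)
        _, six, _ = gen_cohort(cfg)
        df = six.df
        fit = tobit_fit(df[cfg.predictor], df["lifespan_months"],
                        df["censored"])
        assert fit.pseudo_r2 > 0.95

    def test_biomarkers_within_observed_ranges(self):
        cfg = GeneratorConfig(seed=3, cohort_size=50)
        _, six, _ = gen_cohort(cfg)
        for name, (lo, hi) in BIOMARKER_RANGES.items():
            vals = six.df[name]
            assert vals.between(lo, hi).all(), name

    def test_small_cohort_shape_like_study(self):
        # ten subjects, four censored at 25 months (seed chosen for shape)
        for seed in range(50):
            cfg = GeneratorConfig(seed=seed, cohort_size=10)
            _, six, sidecar = gen_cohort(cfg)
            if sidecar["n_censored"] == 4:
                df = six.df
                assert (df["lifespan_months"] <= 25.0).all()
                assert df["censored"].sum() == 4
                break
        else:
            pytest.fail("no seed in 0..49 yields a 4-of-10 censored cohort")

    def test_two_timepoints_share_subjects(self):
        cfg = GeneratorConfig(seed=4, cohort_size=20)
        two, six, _ = gen_cohort(cfg)
        assert list(two.df["subject_id"]) == list(six.df["subject_id"])

    def test_seed_reproducibility(self):
        cfg = GeneratorConfig(seed=5, cohort_size=30)
        _, a, _ = gen_cohort(cfg)
        _, b, _ = gen_cohort(cfg)
        assert a.df.equals(b.df)
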