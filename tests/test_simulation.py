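"""Monte Carlo engine: noise model, PD statistics, CNR, sweeps."""

import dataclasses

import numpy as np
import pytest

from legatos.kinetics import KineticParams
from legatos.simulation import (ACQ_HS, ACQ_HT, NL_HS_DEFAULT, NL_HT_DEFAULT,
                                NoiseSpec, PopulationVIFModel, SamplingScheme,
                                SimulationConfig, add_rician_noise,
                                compute_cnr_hs, percent_deviation,
                                run_ktrans_sweep, run_noise_comparison,
                                synthesize_dtr_si)


class TestPercentDeviation:
    @pytest.mark.parametrize("measured,true,want", [
        (0.26, 0.26, 0.0),
        (0.13, 0.26, -50.0),
        (0.286, 0.26, 10.0),
    ])
    def test_exact_formula(self, measured, true, want):
        assert percent_deviation(measured, true) == pytest.approx(want, abs=1e-12)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            percent_deviation(1.0, 0.0)


class TestNoiseSpec:
    def test_protocol_noise_levels_consistent_with_baseline_stats(self):
        # the defaults must satisfy NL = SD/mean baseline to two decimals
        assert round(NL_HT_DEFAULT.baseline_sd / NL_HT_DEFAULT.baseline_mean, 2) == 0.04
        assert round(NL_HS_DEFAULT.baseline_sd / NL_HS_DEFAULT.baseline_mean, 2) == 0.15

    def test_inconsistent_stats_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            NoiseSpec(nl=0.10, baseline_mean=371.1, baseline_sd=15.2)


class TestRicianNoise:
    def test_zero_level_is_identity(self):
        si = np.linspace(10, 400, 50)
        out = add_rician_noise(si, NoiseSpec(nl=0.0, baseline_mean=100.0), 0)
        np.testing.assert_array_equal(out, si)

    def test_zero_signal_gives_rayleigh_mean(self):
        spec = NoiseSpec(nl=1.0, baseline_mean=1.0)  # sigma = 1
        out = add_rician_noise(np.zeros(10**6), spec, np.random.default_rng(0))
        assert out.mean() == pytest.approx(np.sqrt(np.pi / 2), rel=5e-3)

    def test_high_snr_limit_is_unbiased(self):
        spec = NoiseSpec(nl=1.0, baseline_mean=1.0)
        s = 100.0
        out = add_rician_noise(np.full(10**5, s), spec, np.random.default_rng(1))
        assert out.mean() == pytest.approx(s, rel=1e-3)

    def test_seeded_reproducibility(self):
        si = np.linspace(50, 400, 64)
        spec = NoiseSpec(nl=0.15, baseline_mean=84.4)
        a = add_rician_noise(si, spec, np.random.default_rng(7))
        b = add_rician_noise(si, spec, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestSamplingScheme:
    def test_default_axes_match_protocol(self):
        s = SamplingScheme()
        assert s.concat_time_s == pytest.approx(50 * 1.46)
        assert s.ht_arterial_times.size == 50
        assert s.hs_parenchymal_times.size == 12 * 5
        assert s.total_duration_s == pytest.approx(751.0, abs=1.0)

    def test_time_axes_strictly_increasing_and_disjoint(self):
        s = SamplingScheme()
        for axis in (s.ht_times, s.hs_times):
            assert np.all(np.diff(axis) > 0)
        assert not set(np.round(s.ht_times, 6)) & set(np.round(s.hs_times, 6))


class TestSynthesizeDtrSi:
    def test_zero_kinetics_gives_flat_baselines(self):
        params = KineticParams(ktrans=0.0, vp=0.0, ve=0.5)
        out = synthesize_dtr_si(params, PopulationVIFModel(), SamplingScheme())
        np.testing.assert_allclose(out["ht"][1], 371.1, rtol=1e-10)
        np.testing.assert_allclose(out["hs"][1], 84.4, rtol=1e-10)

    def test_baseline_frames_hit_configured_means_exactly(self, vs_truth):
        out = synthesize_dtr_si(vs_truth, PopulationVIFModel(), SamplingScheme())
        hs_t, hs_si = out["hs"]
        np.testing.assert_allclose(hs_si[hs_t < 0], 84.4, rtol=1e-12)

    def test_shared_times_come_from_one_concentration(self, vs_truth):
        """HT and HS samples at equal times must encode equal concentration."""
        from legatos.signal_model import (RelaxationState,
                                          si_to_concentration)
        cfg = SimulationConfig()
        scheme = SamplingScheme()
        out = synthesize_dtr_si(vs_truth, PopulationVIFModel(), scheme, cfg)
        ht_t, ht_si = out["ht"]
        hs_t, hs_si = out["hs"]
        conc_ht, _ = si_to_concentration(ht_si, 1, cfg.tissue_state("HT"),
                                         cfg.agent, ACQ_HT, estimate_m0=False)
        conc_hs, _ = si_to_concentration(hs_si, 1, cfg.tissue_state("HS"),
                                         cfg.agent, ACQ_HS, estimate_m0=False)
        # compare concentrations interpolated to the HS parenchymal times
        sel = hs_t > 0
        interp = np.interp(hs_t[sel], ht_t, conc_ht)
        np.testing.assert_allclose(conc_hs[sel], interp, rtol=0.02, atol=5e-3)


class TestCnr:
    def test_printed_example_values(self):
# baseline with mean 84.4 and SD 12.6 exactly (n=2, ddof=1)
        base = np.array([84.4 - 12.6 / np.sqrt(2), 84.4 + 12.6 / np.sqrt(2)])
        si = np.concatenate([base, [100.0, 210.4]])
        assert compute_cnr_hs(si, 2) == pytest.approx((210.4 - 84.4) / 12.6, rel=1e-9)

    def test_flat_series_is_zero(self):
        assert compute_cnr_hs(np.full(20, 84.4), 4) == 0.0

    def test_strictly_increasing_in_parenchymal_max(self):
        base = np.array([80.0, 90.0, 84.0])
        vals = [compute_cnr_hs(np.concatenate([base, [m]]), 3) for m in (100, 150, 200)]
        assert vals[0] < vals[1] < vals[2]


class TestRunNoiseComparison:
    def test_noiseless_single_rep_recovers_truth(self):
        cfg = SimulationConfig(
            noise_ht=NoiseSpec(nl=0.0, baseline_mean=371.1),
            noise_hs=NoiseSpec(nl=0.0, baseline_mean=84.4))
        res = run_noise_comparison(reps=1, seed=0, cfg=cfg)
        for st in res.values():
            for p in ("ktrans", "vp", "ve"):
                assert abs(st.mean_pd[p]) < 0.5

    def test_seeded_determinism(self):
        a = run_noise_comparison(reps=20, seed=123)
        b = run_noise_comparison(reps=20, seed=123)
        assert a == b

    def test_sd_pd_nondecreasing_in_noise_level(self, vs_truth):
        """Precision degrades monotonically with the noise level."""
        sds = []
        for nl in (0.01, 0.05, 0.10):
            cfg = SimulationConfig(
                noise_ht=NoiseSpec(nl=nl, baseline_mean=371.1),
                noise_hs=NoiseSpec(nl=nl, baseline_mean=84.4))
            res = run_noise_comparison(reps=150, seed=9, cfg=cfg)
            sds.append(res["NL_HT-HS"].sd_pd["ktrans"])
        assert sds[0] < sds[1] < sds[2]

    def test_mean_pd_vanishes_as_noise_vanishes(self):
        means = []
        for nl_ht, nl_hs in ((0.04, 0.15), (0.01, 0.0375), (0.0, 0.0)):
            cfg = SimulationConfig(
                noise_ht=NoiseSpec(nl=nl_ht, baseline_mean=371.1),
                noise_hs=NoiseSpec(nl=nl_hs, baseline_mean=84.4))
            res = run_noise_comparison(reps=150, seed=2, cfg=cfg)
            means.append(max(abs(v) for v in res["NL_HT-HS"].mean_pd.values()))
        assert means[-1] < 0.05
        assert means[-1] < means[0]

    def test_mixed_ktrans_accuracy_between_pure_conditions(self):
        res = run_noise_comparison(reps=400, seed=4)
        assert (res["NL_HT"].mean_abs_pd["ktrans"]
                < res["NL_HT-HS"].mean_abs_pd["ktrans"]
                < res["NL_HS"].mean_abs_pd["ktrans"])


class TestKtransSweep:
    def test_noiseless_sweep_has_zero_mean_pd(self):
        cfg = SimulationConfig(
            noise_ht=NoiseSpec(nl=0.0, baseline_mean=371.1),
            noise_hs=NoiseSpec(nl=0.0, baseline_mean=84.4))
        table, _ = run_ktrans_sweep([0.05, 0.20, 0.35], reps=1, seed=0, cfg=cfg)
        assert np.all(np.abs(table["mean_pd_ktrans"]) < 0.5)

    def test_too_few_sweep_points_rejected(self):
        with pytest.raises(ValueError):
            run_ktrans_sweep([0.1, 0.2], reps=1, seed=0)

    def test_cnr_increases_with_ktrans_and_correlations_negative(self):
        table, corr = run_ktrans_sweep(reps=150, seed=5)
        cnr = table["cnr_hs_parenchymal"].to_numpy()
        assert np.all(np.diff(cnr) > 0)
        assert corr["r_cnr_sd_pd"] < -0.85
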