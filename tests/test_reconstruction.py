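"""Merged dual-rate curves, calibration-ratio rescaling, voxelwise mapping."""

import numpy as np
import pytest

from legatos.kinetics import FitConfig, TissueCurve, etm_forward, fit_etm
from legatos.reconstruction import (MergedCurve, ReconConfig,
                                    calibration_ratio, fit_voxelwise,
                                    merge_dtr, rescale_arterial)


def _ht(values, dt=1.46):
    n = len(values)
    return TissueCurve(times=(np.arange(n) + 1) * dt, ct=np.asarray(values, float))


def _hs(values, start=73.0, dt=6.04):
    n = len(values)
    return TissueCurve(times=start + (np.arange(n) + 1) * dt,
                       ct=np.asarray(values, float))


class TestMergeDtr:
    def test_default_scheme_lengths_and_concat_index(self):
        ht = _ht(np.ones(50))
        hs = _hs(np.ones(12))
        merged = merge_dtr(ht, hs, 73.0)
        assert merged.times.size == 62
        assert merged.concat_index == 50
        assert np.all(np.diff(merged.times) > 0)

    def test_too_few_hs_frames_rejected(self):
        with pytest.raises(ValueError, match="HS frames"):
            merge_dtr(_ht(np.ones(50)), _hs(np.ones(4)), 73.0)

    def test_too_few_ht_frames_rejected(self):
        with pytest.raises(ValueError, match="HT frames"):
            merge_dtr(_ht(np.ones(3)), _hs(np.ones(12)), 73.0)

    def test_ht_extending_past_concat_point_rejected(self):
        late_ht = TissueCurve(times=np.arange(1, 101) * 1.46, ct=np.ones(100))
        with pytest.raises(ValueError, match="precede"):
            merge_dtr(late_ht, _hs(np.ones(12), start=146.0), 73.0)

    def test_pre_concat_hs_frames_dropped(self):
        hs = TissueCurve(times=np.concatenate([[10.0], 73.0 + (np.arange(6) + 1) * 6.04]),
                         ct=np.arange(7.0))
        merged = merge_dtr(_ht(np.ones(50)), hs, 73.0)
        assert merged.times.size == 56


class TestCalibrationRatio:
    def _merged(self, ht_tail, hs_head):
        ht = np.concatenate([np.zeros(6), ht_tail])
        conc = np.concatenate([ht, hs_head])
        n_ht = ht.size
        times = np.concatenate([(np.arange(n_ht) + 1) * 1.46,
                                73.0 + (np.arange(len(hs_head)) + 1) * 6.04])
        return MergedCurve(times=times, conc=conc, concat_index=n_ht)

    def test_two_to_one_ratio(self):
        m = self._merged([1, 1, 1, 1], [2, 2, 2, 2, 2])
        assert calibration_ratio(m) == (2.0, False)

    def test_identical_levels_give_unity(self):
        m = self._merged([1, 1, 1, 1], [1, 1, 1, 1, 1])
        assert calibration_ratio(m) == (1.0, False)

    def test_hand_computed_ratio(self):
        m = self._merged([0.8, 1.0, 1.2, 1.0], [1.5, 1.4, 1.6, 1.5, 1.5])
        r, flagged = calibration_ratio(m)
        assert r == pytest.approx(1.5)
        assert not flagged

    def test_nonpositive_ht_mean_flagged_unity(self):
        m = self._merged([0.0, 0.0, 0.0, 0.0], [1, 1, 1, 1, 1])
        assert calibration_ratio(m) == (1.0, True)


class TestRescaleArterial:
    def _flat(self, ht_level, hs_level):
        conc = np.concatenate([np.full(10, ht_level), np.full(8, hs_level)])
        times = np.concatenate([(np.arange(10) + 1) * 1.46,
                                73.0 + (np.arange(8) + 1) * 6.04])
        return MergedCurve(times=times, conc=conc, concat_index=10)

    def test_unity_ratio_is_identity(self):
        m = self._flat(1.0, 1.0)
        out = rescale_arterial(m)
        np.testing.assert_array_equal(out.conc, m.conc)
        assert out.ratio_calib == 1.0

    def test_flat_phases_rescaled_to_hs_level(self):
        out = rescale_arterial(self._flat(1.0, 2.0))
        assert out.ratio_calib == pytest.approx(2.0)
        np.testing.assert_allclose(out.conc[:10], 2.0)
        np.testing.assert_allclose(out.conc[10:], 2.0)

    def test_junction_gap_closes_exactly(self):
        rng = np.random.default_rng(0)
        conc = np.concatenate([rng.uniform(0.5, 1.5, 12), rng.uniform(1.0, 3.0, 9)])
        times = np.concatenate([(np.arange(12) + 1) * 1.46,
                                73.0 + (np.arange(9) + 1) * 6.04])
        out = rescale_arterial(MergedCurve(times=times, conc=conc, concat_index=12))
        i = out.concat_index
        gap = out.conc[i - 4:i].mean() - out.conc[i:i + 5].mean()
        assert gap == pytest.approx(0.0, abs=1e-14)

    def test_rescaling_idempotent_on_flat_phases(self):
        once = rescale_arterial(self._flat(1.0, 2.0))
        r2, _ = calibration_ratio(once)
        assert r2 == pytest.approx(1.0)
        twice = rescale_arterial(once)
        np.testing.assert_allclose(twice.conc, once.conc)


class TestFitVoxelwise:
    def _setup(self, phantom):
        from legatos.signal_model import (ContrastAgentSpec, RelaxationState,
                                          si_to_concentration)
        from legatos.simulation import ACQ_HT
        from legatos.vif import extract_vif

        ht = phantom["ht"]
        agent = ContrastAgentSpec()
        state = RelaxationState(r1_0=0.7, m0=1.0)
        conc, _ = si_to_concentration(ht["si"], 6, state, agent, ACQ_HT)
        vif = extract_vif(conc, ht["times"], ht["vessel"],
                          n_select=min(10, int(ht["vessel"].sum())))
        return agent, vif

    def test_noiseless_phantom_parameters_consistent_across_voxels(self, noiseless_phantom):
        """The noiseless pipeline gives essentially one value per region."""
        from legatos.simulation import ACQ_HS, ACQ_HT

        ph = noiseless_phantom
        agent, vif = self._setup(ph)
        maps, qc = fit_voxelwise(
            (ph["ht"]["si"], ph["ht"]["affine"]),
            (ph["hs"]["si"], ph["hs"]["affine"]),
            ph["ht"]["times"], ph["hs"]["times"], vif,
            ph["hs"]["r1_map"], ph["hs"]["tumour"], agent, ACQ_HT, ACQ_HS,
            FitConfig(bat_grid_s=(0.0,), n_starts=1), ReconConfig())
        m = ph["hs"]["tumour"]
        assert qc["n_fitted"] == int(m.sum())
        assert qc["n_failed"] == 0
        for name in ("ktrans", "vp", "ve"):
            vals = getattr(maps, name)[m]
            assert np.nanstd(vals) / np.nanmean(vals) < 0.01
        assert np.isnan(maps.ktrans[~m]).all()

    def test_all_background_mask_stays_at_sentinel(self, noiseless_phantom):
        from legatos.simulation import ACQ_HS, ACQ_HT

        ph = noiseless_phantom
        agent, vif = self._setup(ph)
        empty = np.zeros_like(ph["hs"]["tumour"])
        maps, qc = fit_voxelwise(
            (ph["ht"]["si"], ph["ht"]["affine"]),
            (ph["hs"]["si"], ph["hs"]["affine"]),
            ph["ht"]["times"], ph["hs"]["times"], vif,
            ph["hs"]["r1_map"], empty, agent, ACQ_HT, ACQ_HS,
            FitConfig(bat_grid_s=(0.0,), n_starts=1), ReconConfig())
        assert qc["n_fitted"] == 0
        assert np.isnan(maps.ktrans).all()

    def test_unity_ratio_path_equals_plain_etm_fit(self, population_vif, vs_truth):
        """With identical HT and HS concentration levels the reconstruction
        reduces to a single-resolution fit of the concatenated curve."""
        ht_times = (np.arange(50) + 1) * 1.46
        hs_times = 73.0 + (np.arange(20) + 1) * 6.04
        ht = etm_forward(vs_truth, population_vif, ht_times)
        hs = etm_forward(vs_truth, population_vif, hs_times)
        merged = merge_dtr(ht, hs, 73.0)
        recon = rescale_arterial(merged, ratio=1.0)
        cfg = FitConfig(bat_grid_s=(0.0,), n_starts=1)
        fit_recon = fit_etm(recon.as_tissue_curve(), population_vif, cfg)
        plain = TissueCurve(times=np.concatenate([ht_times, hs_times]),
                            ct=np.concatenate([ht.ct, hs.ct]))
        fit_plain = fit_etm(plain, population_vif, cfg)
        assert fit_recon.params.ktrans == pytest.approx(fit_plain.params.ktrans, rel=1e-9)
        assert fit_recon.params.vp == pytest.approx(fit_plain.params.vp, rel=1e-9)
        assert fit_recon.params.ve == pytest.approx(fit_plain.params.ve, rel=1e-9)
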