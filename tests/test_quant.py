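"""Decay arithmetic, SUV conversion and VOI statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualpet.meta import F18_HALF_LIFE_MIN, ProtocolTiming, ScanMeta
from dualpet.quant import (
    UptakeStats,
    act_to_suv,
    cov_percent,
    decay_factor,
    elapsed_half_lives,
    place_block_voi,
    place_cylinder_voi,
    suv_to_act_factor,
    tlr,
    voi_stats,
)
from dualpet.volume import VOI, ActivityVolume, Grid


def _meta(weight=70.0, dose=35.0, uptake=60.0, tracer="FDG"):
    return ScanMeta(tracer, F18_HALF_LIFE_MIN, dose, weight, 0.0, uptake, uptake + 10.0)


class TestDecay:
    @pytest.mark.parametrize(
        "dt, half_life, expected",
        [
            (0.0, 109.8, 1.0),
            (109.8, 109.8, 0.5),
            (298.0, 109.8, 0.15240419285683654),
            (3.1 * 109.8, 109.8, 2.0**-3.1),
        ],
    )
    def test_values(self, dt, half_life, expected):
        assert decay_factor(dt, half_life) == pytest.approx(expected, rel=1e-12)

    def test_shortest_interval_rounds_to_15_percent(self):
        # worst-case residual of the one-day protocol: 298 min between scans
        assert round(100 * decay_factor(298.0, 109.8)) == 15

    def test_mean_elapsed_half_lives_round_to_12_percent(self):
        assert round(100 * decay_factor(3.1 * 109.8, 109.8)) == 12

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            decay_factor(-1.0, 109.8)

    @given(a=st.floats(0, 500), b=st.floats(0, 500))
    @settings(max_examples=50, deadline=None)
    def test_multiplicative(self, a, b):
        f = decay_factor
        assert f(a + b, 109.8) == pytest.approx(f(a, 109.8) * f(b, 109.8), rel=1e-9)

    def test_strictly_decreasing(self):
        ts = np.linspace(0, 600, 50)
        vals = [decay_factor(t, 109.8) for t in ts]
        assert np.all(np.diff(vals) < 0)


class TestElapsedHalfLives:
    def test_protocol_timing_reproduces_reported_value(self):
        # 4.2 h after scan-1 completion + 90 min uptake = 342 min -> 3.1
        meta1, meta2 = ProtocolTiming().scan_metas(70.0)
        assert elapsed_half_lives(meta1, meta2) == pytest.approx(342.0 / 109.8)
        assert round(elapsed_half_lives(meta1, meta2), 1) == 3.1

    def test_one_half_life(self):
        meta1 = _meta()
        meta2 = ScanMeta("SSTR", 109.8, 210.0, 70.0, 100.0, meta1.t_acq_end_min + 109.8,
                         meta1.t_acq_end_min + 114.8)
        assert elapsed_half_lives(meta1, meta2) == pytest.approx(1.0)

    def test_298_min_interval(self):
        meta1 = _meta()
        meta2 = ScanMeta("SSTR", 109.8, 210.0, 70.0, 100.0, meta1.t_acq_end_min + 298.0,
                         meta1.t_acq_end_min + 303.0)
        assert elapsed_half_lives(meta1, meta2) == pytest.approx(298.0 / 109.8, abs=5e-3)

    def test_non_positive_interval_rejected(self):
        meta1 = _meta()
        with pytest.raises(ValueError):
            elapsed_half_lives(meta1, meta1)


class TestActToSuv:
    def test_hand_computed_example(self, small_grid):
        vol = ActivityVolume(np.full(small_grid.shape, 3000.0), small_grid)
        suv = act_to_suv(vol, _meta(weight=70.0, dose=70.0))
        expected = 3000.0 * 70000.0 / (70e6 * 2.0 ** (-60.0 / 109.8))
        assert suv[0, 0, 0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(4.38, abs=0.005)

    def test_definition_gives_unit_suv(self, small_grid):
        meta = _meta()
        vol = ActivityVolume(np.full(small_grid.shape, suv_to_act_factor(meta)), small_grid)
        assert np.allclose(act_to_suv(vol, meta), 1.0)

    def test_linear_in_body_weight(self, small_grid):
        vol = ActivityVolume(np.full(small_grid.shape, 1000.0), small_grid)
        s1 = act_to_suv(vol, _meta(weight=70.0))
        s2 = act_to_suv(vol, _meta(weight=140.0))
        assert np.allclose(s2, 2.0 * s1)

    def test_invalid_dose_rejected(self):
        with pytest.raises(ValueError):
            _meta(dose=0.0)


class TestVoiPlacement:
    def test_blood_pool_cylinder_3cc(self, clinical_grid):
        voi = place_cylinder_voi(clinical_grid, (0, 0, 0), 8.0, 14.9)
        assert 2.7 <= voi.volume_mL <= 3.3

    def test_myocardial_cylinder_1cc(self, clinical_grid):
        voi = place_cylinder_voi(clinical_grid, (0, 0, 0), 5.0, 12.7)
        assert 0.9 <= voi.volume_mL <= 1.1

    def test_cylinder_outside_grid(self, clinical_grid):
        with pytest.raises(ValueError):
            place_cylinder_voi(clinical_grid, (500, 0, 0), 8.0, 14.9)

    def test_liver_block_14mL(self, small_grid):
        voi = place_block_voi(small_grid, (0, 0, 0), 14.0)
        assert 12.6 <= voi.volume_mL <= 15.4
        assert voi.volume_mL == pytest.approx(voi.n_voxels * small_grid.voxel_volume_mL)

    def test_block_smaller_than_voxel(self, small_grid):
        with pytest.raises(ValueError):
            place_block_voi(small_grid, (0, 0, 0), 0.001)


class TestVoiStats:
    def test_uniform_region(self, small_grid):
        meta = _meta()
        vol = ActivityVolume(np.full(small_grid.shape, 2.0 * suv_to_act_factor(meta)),
                             small_grid)
        voi = place_block_voi(small_grid, (0, 0, 0), 14.0)
        s = voi_stats(vol, voi, meta)
        assert s.suv_mean == pytest.approx(2.0)
        assert s.suv_sd == pytest.approx(0.0, abs=1e-12)
        assert s.suv_peak == pytest.approx(2.0)
        assert s.suv_max == pytest.approx(2.0)

    def test_two_voxel_population_sd(self, small_grid):
        meta = _meta()
        f = suv_to_act_factor(meta)
        values = np.zeros(small_grid.shape)
        mask = np.zeros(small_grid.shape, bool)
        values[20, 20, 20], values[20, 20, 21] = 1.0 * f, 3.0 * f
        mask[20, 20, 20] = mask[20, 20, 21] = True
        s = voi_stats(ActivityVolume(values, small_grid), VOI(mask, small_grid, "t"), meta)
        assert s.suv_mean == pytest.approx(2.0)
        assert s.suv_sd == pytest.approx(1.0)  # population (n) denominator

    def test_single_hot_voxel_peak_below_max(self, small_grid):
        meta = _meta()
        values = np.full(small_grid.shape, 0.1 * suv_to_act_factor(meta))
        values[20, 20, 20] = 50.0 * suv_to_act_factor(meta)
        mask = np.zeros(small_grid.shape, bool)
        mask[18:23, 18:23, 18:23] = True
        s = voi_stats(ActivityVolume(values, small_grid), VOI(mask, small_grid, "t"), meta)
        assert s.suv_peak < s.suv_max
        assert s.suv_peak > 0.1

    def test_grid_mismatch_rejected(self, small_grid, clinical_grid):
        meta = _meta()
        vol = ActivityVolume(np.ones(small_grid.shape), small_grid)
        voi = VOI(np.ones(clinical_grid.shape, bool), clinical_grid, "t")
        with pytest.raises(ValueError):
            voi_stats(vol, voi, meta)

    def test_translation_invariance(self):
        """Shifting volume and VOI together leaves every statistic unchanged."""
        meta = _meta()
        rng = np.random.default_rng(7)
        base = rng.uniform(100, 2000, size=(30, 30, 30))
        mask = np.zeros((30, 30, 30), bool)
        mask[10:16, 10:16, 10:16] = True
        g1 = Grid.centered((30, 30, 30), 2.0)
        s1 = voi_stats(ActivityVolume(base, g1), VOI(mask, g1, "a"), meta)
        shifted = np.roll(base, (3, -2, 4), axis=(0, 1, 2))
        mshift = np.roll(mask, (3, -2, 4), axis=(0, 1, 2))
        s2 = voi_stats(ActivityVolume(shifted, g1), VOI(mshift, g1, "a"), meta)
        for f in ("act_mean", "suv_mean", "suv_sd", "suv_max", "suv_peak"):
            assert getattr(s1, f) == pytest.approx(getattr(s2, f), rel=1e-12)


class TestCovAndTlr:
    def _stats(self, mean, sd):
        return UptakeStats(mean * 300, mean, sd, mean + 2 * sd, mean + sd, 14.0, 1750)

    def test_cov_direct_ratio(self):
        assert cov_percent(self._stats(2.0, 0.26)) == pytest.approx(13.0)

    def test_cov_zero_sd(self):
        assert cov_percent(self._stats(2.0, 0.0)) == 0.0

    def test_cov_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cov_percent(self._stats(0.0, 0.1))

    def test_tlr_values(self):
        lesion, liver = self._stats(6.8, 0.0), self._stats(2.0, 0.0)
        t_mean, t_peak = tlr(lesion, liver)
        assert t_mean == pytest.approx(3.4)
        assert t_peak == pytest.approx(6.8 / 2.0)
        assert tlr(liver, liver)[0] == pytest.approx(1.0)
        assert tlr(self._stats(1e-9, 0.0), liver)[0] == pytest.approx(0.0, abs=1e-8)

    def test_tlr_zero_liver_rejected(self):
        with pytest.raises(ValueError):
            tlr(self._stats(2.0, 0.1), self._stats(0.0, 0.0))
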