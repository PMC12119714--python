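"""Phantom construction, acquisition simulation and the cohort generator."""

import numpy as np
import pytest

from dualpet.meta import ProtocolTiming
from dualpet.phantom import (
    CLASS_PROBS,
    NO_NOISE,
    LesionSpec,
    NoiseModel,
    OrganSpec,
    PhantomSpec,
    build_phantom,
    default_grid,
    default_spec,
    paper_like_cohort,
    simulate_acquisition,
    simulate_dual_study,
)
from dualpet.quant import act_to_suv, suv_to_act_factor
from dualpet.volume import Ellipsoid, Grid


def _liver_only_spec(grid):
    return PhantomSpec(
        grid=grid,
        organs=(OrganSpec("liver", Ellipsoid((0, 0, 0), (30, 25, 25)),
                          {"FDG": 2.0, "SSTR": 2.9}),),
    )


class TestBuildPhantom:
    def test_piecewise_constant_single_organ(self, small_grid):
        suv, labels = build_phantom(_liver_only_spec(small_grid))
        inside = labels == 2
        assert inside.any()
        assert np.all(suv["FDG"][inside] == 2.0)
        assert np.all(suv["FDG"][~inside] == 0.0)

    def test_voxelized_ellipsoid_volume(self):
        # 6 mm sphere: 4/3 pi 0.6^3 = 0.905 mL, recovered within 5% at 1.65 mm
        grid = Grid.centered((24, 24, 24), 1.65)
        lesion = Ellipsoid((0, 0, 0), (6.0, 6.0, 6.0))
        n = int(lesion.mask(grid).sum())
        assert lesion.volume_mL == pytest.approx(0.905, abs=0.001)
        assert n * grid.voxel_volume_mL == pytest.approx(lesion.volume_mL, rel=0.05)

    @pytest.mark.parametrize("radii", [(6, 6, 6), (9, 7, 5), (12, 8, 8)])
    def test_voxelization_error_bound(self, radii):
        """Masks with >= 100 voxels match the analytic volume within 5%."""
        grid = Grid.centered((40, 40, 40), 2.0)
        el = Ellipsoid((0.7, -0.3, 0.1), radii)  # off-lattice center
        n = int(el.mask(grid).sum())
        assert n >= 100
        assert n * grid.voxel_volume_mL == pytest.approx(el.volume_mL, rel=0.05)

    def test_lesion_locality(self, small_grid):
        spec = _liver_only_spec(small_grid)
        lesion = LesionSpec("liver", (0, 0, 0), (6, 6, 6), 8.0, 0.0, "FDG+/SSTR-")
        hot = PhantomSpec(small_grid, spec.organs, (lesion,))
        cold = PhantomSpec(
            small_grid, spec.organs,
            (LesionSpec("liver", (0, 0, 0), (6, 6, 6), 0.0, 0.0, "FDG-/SSTR+"),))
        suv_hot, labels = build_phantom(hot)
        suv_cold, _ = build_phantom(cold)
        diff = suv_hot["FDG"] != suv_cold["FDG"]
        assert diff.any()
        assert np.all(labels[diff] >= 100)  # only lesion voxels differ

    def test_overlapping_organs_rejected(self, small_grid):
        spec = PhantomSpec(
            grid=small_grid,
            organs=(
                OrganSpec("liver", Ellipsoid((0, 0, 0), (20, 20, 20)), {"FDG": 2.0}),
                OrganSpec("brain", Ellipsoid((10, 0, 0), (20, 20, 20)), {"FDG": 6.0}),
            ),
        )
        with pytest.raises(ValueError, match="overlap"):
            build_phantom(spec)

    def test_lesion_outside_host_rejected(self, small_grid):
        spec = _liver_only_spec(small_grid)
        bad = PhantomSpec(
            small_grid, spec.organs,
            (LesionSpec("liver", (28, 0, 0), (8, 8, 8), 8.0, 0.0, "FDG+/SSTR-"),))
        with pytest.raises(ValueError, match="outside its host"):
            build_phantom(bad)


class TestSimulateAcquisition:
    def test_noiseless_round_trip(self, small_grid, meta_pair, rng):
        meta1, _ = meta_pair
        suv = rng.uniform(0, 8, size=small_grid.shape)
        acq = simulate_acquisition(suv, small_grid, meta1, NO_NOISE, seed=0)
        assert np.allclose(act_to_suv(acq, meta1), suv, rtol=1e-12)

    def test_same_seed_bit_identical(self, small_grid, meta_pair):
        meta1, _ = meta_pair
        suv = np.full(small_grid.shape, 2.0)
        a = simulate_acquisition(suv, small_grid, meta1, NoiseModel(scale=4.0), seed=5)
        b = simulate_acquisition(suv, small_grid, meta1, NoiseModel(scale=4.0), seed=5)
        assert np.array_equal(a.values, b.values)

    def test_noise_cov_matches_closed_form(self, small_grid, meta_pair):
        """gaussian_sqrt noise: empirical CoV ~ k / sqrt(mean ACT)."""
        meta1, _ = meta_pair
        k = 4.0
        suv = np.full(small_grid.shape, 2.0)
        acq = simulate_acquisition(suv, small_grid, meta1, NoiseModel(scale=k), seed=3)
        mean_act = 2.0 * suv_to_act_factor(meta1)
        expected_cov = k / np.sqrt(mean_act)
        observed = acq.values.std() / acq.values.mean()
        # 64000 voxels: sampling error on CoV is ~ CoV/sqrt(2n) ~ 0.3%
        assert observed == pytest.approx(expected_cov, rel=0.02)


class TestSimulateDualStudy:
    def test_planted_fraction_from_shortest_interval(self, small_grid):
        # 298 min between acquisitions -> 15% residual
        proto = ProtocolTiming(interval_after_scan1_min=298.0 - 90.0)
        study = simulate_dual_study(_liver_only_spec(small_grid), proto, seed=0)
        assert study.truth.residual_fraction == pytest.approx(0.152, abs=5e-4)
        assert round(100 * study.truth.residual_fraction) == 15

    def test_zero_residual_gives_pure_second_tracer(self, small_grid):
        spec = _liver_only_spec(small_grid)
        study = simulate_dual_study(spec, seed=0, residual_fraction=0.0)
        suv, _ = build_phantom(spec)
        f2 = suv_to_act_factor(study.meta2)
        assert np.allclose(study.scan2.values, suv["SSTR"] * f2, rtol=1e-12)

    def test_brain_activity_scales_with_planted_fraction(self, noiseless_study):
        """No second-tracer brain uptake: scan2 brain ACT = f * scan1 brain ACT."""
        study = noiseless_study
        brain = study.truth.labels == 3
        ratio = study.scan2.values[brain].mean() / study.scan1.values[brain].mean()
        assert ratio == pytest.approx(study.truth.residual_fraction, rel=1e-12)

    def test_reproducible(self, small_grid):
        spec = _liver_only_spec(small_grid)
        a = simulate_dual_study(spec, noise=NoiseModel(), seed=9)
        b = simulate_dual_study(spec, noise=NoiseModel(), seed=9)
        assert np.array_equal(a.scan1.values, b.scan1.values)
        assert np.array_equal(a.scan2.values, b.scan2.values)
        assert a.truth.residual_fraction == b.truth.residual_fraction


class TestCohortGenerator:
    def test_class_mixture(self):
        assert CLASS_PROBS["FDG+/SSTR+"] == pytest.approx(25 / 125)
        assert CLASS_PROBS["FDG+/SSTR-"] == pytest.approx(55 / 125)
        assert CLASS_PROBS["FDG-/SSTR+"] == pytest.approx(45 / 125)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            paper_like_cohort(0, seed=1)

    def test_class_frequencies_within_three_se(self, coarse_grid):
        """>= 500 planted lesions: class frequencies near the 20/44/36 mixture."""
        studies = paper_like_cohort(85, seed=21, noise=NO_NOISE, grid=coarse_grid)
        classes = [l.true_class for s in studies for l in s.truth.lesions]
        n = len(classes)
        assert n >= 500
        for cls, p in CLASS_PROBS.items():
            freq = sum(c == cls for c in classes) / n
            se = np.sqrt(p * (1 - p) / n)
            assert abs(freq - p) <= 3 * se, f"{cls}: {freq:.3f} vs {p:.3f}"

    def test_per_organ_lesion_cap(self, coarse_grid):
        studies = paper_like_cohort(10, seed=3, noise=NO_NOISE, grid=coarse_grid)
        for s in studies:
            for organ in ("liver", "body"):
                assert sum(l.organ == organ for l in s.truth.lesions) <= 5

    def test_lesion_volumes_pass_filter_threshold(self, coarse_grid):
        studies = paper_like_cohort(5, seed=4, noise=NO_NOISE, grid=coarse_grid)
        for s in studies:
            for l in s.truth.lesions:
                assert l.volume_mL >= 0.5
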