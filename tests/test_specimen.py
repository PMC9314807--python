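"""Agar shell construction, external-field fit, and sin^2(theta) fits."""

import numpy as np
import pytest

from oriqsm import (
    B0Direction,
    FiberDirection,
    MultiOrientationStudy,
    PhantomSpec,
    VolumeGrid,
    build_agar_shell_mask,
    fiber_b0_angle,
    field_noise_sd_ppb,
    fit_external_field,
    fit_r2star_orientation,
    fit_sin2,
    mean_fiber_direction,
    residual_internal_field,
    simulate_study,
)
from oriqsm.specimen import SpecimenModel

from .oracles import city_block_distance_to_mask


def _noisy_fields(study, sd, rng, support):
    """Fresh field volumes with Gaussian noise added on the support voxels.

    The external fit reads only agar voxels and the residual only specimen
    voxels, so perturbing just their union is statistically identical to
    full-volume noise for every quantity under test.
    """
    out = []
    for f in study.fields:
        data = f.data.copy()
        data[support] += rng.normal(0.0, sd, int(support.sum()))
        out.append(f.like(data))
    return MultiOrientationStudy(fields=out, b0s=study.b0s, mask=study.mask)


class TestAgarShellMask:
    def test_cube_specimen_matches_distance_transform_oracle(self):
        shape = (21, 21, 21)
        spec = np.zeros(shape, dtype=bool)
        spec[8:13, 8:13, 8:13] = True  # 5^3 cube, centered
        shell = build_agar_shell_mask(VolumeGrid(spec.astype(float)), 1, 5)
        d = city_block_distance_to_mask(spec)
        expected = (d > 1) & (d <= 5)
        assert np.array_equal(shell.data > 0, expected)

    def test_single_voxel_specimen_enumeration(self):
        shape = (9, 9, 9)
        spec = np.zeros(shape)
        spec[4, 4, 4] = 1.0
        shell = build_agar_shell_mask(VolumeGrid(spec), 1, 2)
        d = city_block_distance_to_mask(spec > 0)
        assert np.array_equal(shell.data > 0, d == 2)
        # |{x : |x|_1 = 2}| in 3D is 18
        assert int(shell.data.sum()) == 18

    def test_inner_equal_outer_rejected(self):
        spec = np.zeros((9, 9, 9))
        spec[4, 4, 4] = 1.0
        with pytest.raises(ValueError):
            build_agar_shell_mask(VolumeGrid(spec), 2, 2)

    def test_exclusion_of_other_masks(self):
        shape = (15, 15, 15)
        spec = np.zeros(shape)
        spec[7, 7, 7] = 1.0
        other = np.zeros(shape)
        other[7, 7, 9:12] = 1.0
        shell = build_agar_shell_mask(VolumeGrid(spec), 1, 3, exclude=other)
        assert not np.any((shell.data > 0) & (other > 0))


class TestFiberB0Angle:
    @pytest.mark.parametrize(
        "fiber,b0,expected",
        [
            ((0, 0, 1), (0, 0, 1), 0.0),
            ((1, 0, 0), (0, 0, 1), 90.0),
            ((0, 0, -1), (0, 0, 1), 0.0),  # antipodal equivalence
        ],
    )
    def test_reference_angles(self, fiber, b0, expected):
        assert fiber_b0_angle(FiberDirection(fiber), B0Direction(b0)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_mean_fiber_direction_handles_sign_flips(self, rng):
        base = np.array([0.6, 0.0, 0.8])
        samples = base + rng.normal(0, 0.02, size=(50, 3))
        signs = rng.choice([-1.0, 1.0], size=(50, 1))
        mean = mean_fiber_direction(samples * signs)
        assert abs(np.dot(mean.vector, base)) > 0.999


class TestExternalFieldFit:
    def test_noiseless_recovery_of_generator_parameters(self, small_phantom):
        spec, study, model, truth = small_phantom
        fit = fit_external_field(study, model, responses=truth.responses)
        assert fit.chi_i == pytest.approx(spec.chi_i_ppb, abs=1e-6)
        assert fit.chi_a == pytest.approx(spec.chi_a_ppb, abs=1e-6)
        assert np.abs(fit.baselines - truth.baselines_ppb).max() < 1e-8
        assert fit.r2 > 1 - 1e-12
        assert fit.dof == sum(int((model.agar_mask.data > 0).sum()) for _ in range(10)) - 12

    def test_baseline_columns_absorb_added_constants(self, small_phantom):
        _, study, model, truth = small_phantom
        offsets = np.linspace(-3.0, 3.0, study.n_orientations)
        shifted = MultiOrientationStudy(
            fields=[f.like(f.data + c) for f, c in zip(study.fields, offsets)],
            b0s=study.b0s,
            mask=study.mask,
        )
        base = fit_external_field(study, model, responses=truth.responses)
        fit = fit_external_field(shifted, model, responses=truth.responses)
        assert fit.chi_i == pytest.approx(base.chi_i, abs=1e-10)
        assert fit.chi_a == pytest.approx(base.chi_a, abs=1e-10)
        assert np.allclose(fit.baselines, base.baselines + offsets, atol=1e-10)

    def test_null_chi_a_calibration(self):
        # chi_a = 0 generator at SNR 100: the estimate stays within +-2 SE of
        # zero at the nominal rate, and is unbiased across 200 replicates
        spec = PhantomSpec(grid_shape=(48, 48, 48), radius_voxels=3.0,
                           length_voxels=24.0, chi_a_ppb=0.0, seed=11)
        study, model, truth = simulate_study(spec, keep_responses=True)
        sd = field_noise_sd_ppb(100.0)
        support = (model.agar_mask.data > 0) | (model.specimen_mask.data > 0)
        rng = np.random.default_rng(42)
        estimates, ses = [], []
        for _ in range(200):
            noisy = _noisy_fields(study, sd, rng, support)
            fit = fit_external_field(noisy, model, responses=truth.responses)
            estimates.append(fit.chi_a)
            ses.append(fit.chi_a_se)
        estimates = np.asarray(estimates)
        covered = np.mean(np.abs(estimates) <= 2 * np.asarray(ses))
        assert covered > 0.9
        assert abs(estimates.mean()) < 3 * estimates.std(ddof=1) / np.sqrt(200)

    def test_identical_angles_rejected(self, small_phantom):
        _, study, model, _ = small_phantom
        b0s = study.b0s
        same = MultiOrientationStudy(
            fields=study.fields[:3],
            b0s=type(b0s)([B0Direction([0.5, 0, np.sqrt(3) / 2]),
                           B0Direction([0, 0.5, np.sqrt(3) / 2]),
                           B0Direction([-0.5, 0, np.sqrt(3) / 2])]),
            mask=study.mask,
        )
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_external_field(same, model)

    def test_halving_orientations_inflates_chi_a_se(self, small_phantom):
        spec, study, model, truth = small_phantom
        sd = field_noise_sd_ppb(50.0)
        support = (model.agar_mask.data > 0) | (model.specimen_mask.data > 0)
        noisy = _noisy_fields(study, sd, np.random.default_rng(1), support)
        full = fit_external_field(noisy, model, responses=truth.responses)
        half = MultiOrientationStudy(fields=noisy.fields[:5],
                                     b0s=type(study.b0s)(study.b0s.b0s[:5]),
                                     mask=study.mask)
        half_fit = fit_external_field(half, model, responses=truth.responses[:5])
        assert half_fit.chi_a_se / full.chi_a_se >= np.sqrt(2) * 0.8


class TestResidualInternalField:
    def test_construction_oracle_recovers_internal_offset(self, small_phantom):
        spec, study, model, truth = small_phantom
        fit = fit_external_field(study, model, responses=truth.responses)
        f_r = residual_internal_field(study, model, fit, responses=truth.responses)
        expected = spec.A_ppb * np.sin(np.radians(truth.theta_deg)) ** 2 + spec.B_ppb
        assert np.abs(f_r - expected).max() < 1e-8

    def test_no_offset_generator_gives_zero_residuals(self):
        spec = PhantomSpec(grid_shape=(48, 48, 48), radius_voxels=3.0,
                           length_voxels=24.0, A_ppb=0.0, B_ppb=0.0, seed=3)
        study, model, truth = simulate_study(spec, keep_responses=True)
        fit = fit_external_field(study, model, responses=truth.responses)
        f_r = residual_internal_field(study, model, fit, responses=truth.responses)
        assert np.abs(f_r).max() < 1e-8

    def test_chi_estimates_orthogonal_to_internal_offset(self, small_phantom):
        # the compartmental offset lives strictly inside the specimen, which
        # is disjoint from the agar shell the chi fit reads
        spec, study, model, truth = small_phantom
        boosted = MultiOrientationStudy(
            fields=[f.like(f.data + 5.0 * (model.specimen_mask.data > 0))
                    for f in study.fields],
            b0s=study.b0s,
            mask=study.mask,
        )
        base = fit_external_field(study, model, responses=truth.responses)
        fit = fit_external_field(boosted, model, responses=truth.responses)
        assert fit.chi_i == pytest.approx(base.chi_i, abs=1e-10)
        assert fit.chi_a == pytest.approx(base.chi_a, abs=1e-10)

    def test_residual_sd_matches_clt(self, small_phantom):
        spec, study, model, truth = small_phantom
        sd = 1.0
        n_spec = int((model.specimen_mask.data > 0).sum())
        support = (model.agar_mask.data > 0) | (model.specimen_mask.data > 0)
        rng = np.random.default_rng(8)
        samples = []
        for _ in range(100):
            noisy = _noisy_fields(study, sd, rng, support)
            fit = fit_external_field(noisy, model, responses=truth.responses)
            samples.append(residual_internal_field(noisy, model, fit,
                                                   responses=truth.responses))
        sds = np.asarray(samples).std(axis=0, ddof=1)
        assert np.median(sds) == pytest.approx(sd / np.sqrt(n_spec), rel=0.2)


class TestSin2Fits:
    def test_two_point_interpolation_exact(self):
        fit = fit_sin2([0.0, 90.0], [-2.0, 1.5])
        assert fit.B == pytest.approx(-2.0, abs=1e-12)
        assert fit.A == pytest.approx(3.5, abs=1e-12)
        assert fit.predict(0.0) == pytest.approx(fit.B)
        assert fit.predict(90.0) == pytest.approx(fit.A + fit.B)
        assert np.isinf(fit.A_ci[1])  # zero residual dof -> unbounded CI

    def test_exact_recovery_at_printed_angles(self):
        theta = np.array([50, 60, 9, 66, 39, 0, 18, 31, 81, 88], dtype=float)
        y = 1.46 * np.sin(np.radians(theta)) ** 2 - 2.75
        fit = fit_sin2(theta, y)
        assert fit.A == pytest.approx(1.46, abs=1e-10)
        assert fit.B == pytest.approx(-2.75, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_confidence_interval_coverage(self):
        theta = np.array([50, 60, 9, 66, 39, 0, 18, 31, 81, 88], dtype=float)
        s2 = np.sin(np.radians(theta)) ** 2
        a_true, b_true, sigma = 1.46, -2.75, 0.5
        rng = np.random.default_rng(314)
        hits = 0
        reps = 1000
        for _ in range(reps):
            y = a_true * s2 + b_true + rng.normal(0, sigma, len(theta))
            fit = fit_sin2(theta, y)
            hits += fit.A_ci[0] <= a_true <= fit.A_ci[1]
        assert 0.93 <= hits / reps <= 0.97

    def test_all_angles_identical_rejected(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_sin2([30.0, 30.0, 30.0], [1.0, 2.0, 3.0])

    def test_r2star_orientation_two_point(self):
        fit = fit_r2star_orientation([0.0, 90.0], [20.0, 23.0])
        assert fit.A == pytest.approx(3.0, abs=1e-12)
        assert fit.B == pytest.approx(20.0, abs=1e-12)

    def test_r2star_orientation_exact_recovery(self):
        # mean orientation dependence of R2* in fixed white matter: ~1.3 Hz
        theta = np.array([50, 60, 9, 66, 39, 0, 18, 31, 81, 88], dtype=float)
        r2s = 1.31 * np.sin(np.radians(theta)) ** 2 + 20.0
        fit = fit_r2star_orientation(theta, r2s)
        assert fit.A == pytest.approx(1.31, abs=1e-10)
        assert fit.B == pytest.approx(20.0, abs=1e-10)

    def test_constant_r2star_gives_zero_slope_within_ci(self, rng):
        theta = np.array([50, 60, 9, 66, 39, 0, 18, 31, 81, 88], dtype=float)
        r2s = np.full(10, 21.0) + rng.normal(0, 0.05, 10)
        fit = fit_r2star_orientation(theta, r2s)
        assert fit.A_ci[0] <= 0.0 <= fit.A_ci[1]


def test_specimen_model_requires_disjoint_masks():
    spec = np.zeros((9, 9, 9))
    spec[4, 4, 4] = 1.0
    overlapping = spec.copy()
    with pytest.raises(ValueError, match="disjoint"):
        SpecimenModel(specimen_mask=VolumeGrid(spec),
                      fiber=FiberDirection([0, 0, 1]),
                      agar_mask=VolumeGrid(overlapping))
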