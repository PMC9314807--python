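"""COSMOS and QUASAR multi-orientation inversions: exactness and identifiability."""

import numpy as np
import pytest

from oriqsm import (
    B0Direction,
    MultiOrientationStudy,
    OrientationSet,
    VolumeGrid,
    cosmos,
    forward_field,
    quasar,
)
from oriqsm.dipole import unit_dipole_kernel
from oriqsm.inversion import (
    DegenerateGeometryError,
    InsufficientOrientationsError,
)
from oriqsm.synthetic import make_orientation_set, smooth_random_map

SHAPE = (32, 32, 32)


def _study(fields, b0s, mask=None):
    mask = mask if mask is not None else VolumeGrid(np.ones(SHAPE))
    return MultiOrientationStudy(fields=fields, b0s=b0s, mask=mask)


@pytest.fixture(scope="module")
def smooth_chi():
    return smooth_random_map(SHAPE, 2.0, np.random.default_rng(0))


@pytest.fixture(scope="module")
def forward_fields(smooth_chi, whole_brain_b0s):
    return [forward_field(VolumeGrid(smooth_chi), b0, pad=1)
            for b0 in whole_brain_b0s]


def _coeff_rel_rmse(recovered, truth, well):
    xr, xt = np.fft.fftn(recovered), np.fft.fftn(truth)
    w = well.copy()
    w[0, 0, 0] = False  # the spatial mean carries no dipole information
    return np.linalg.norm(xr[w] - xt[w]) / np.linalg.norm(xt[w])


class TestCosmos:
    def test_noiseless_exact_recovery(self, smooth_chi, forward_fields, whole_brain_b0s):
        res = cosmos(_study(forward_fields, whole_brain_b0s))
        assert _coeff_rel_rmse(res.chi.data, smooth_chi, res.well_conditioned) < 1e-6
        assert np.sqrt(np.mean(res.residual_mean.data ** 2)) < 1e-8

    def test_residuals_consistent_by_construction(self, forward_fields, whole_brain_b0s):
        res = cosmos(_study(forward_fields, whole_brain_b0s))
        for f, b0, r in zip(forward_fields, whole_brain_b0s, res.residual_fields):
            reproj = forward_field(res.chi, b0, pad=1)
            assert np.abs(r.data - (f.data - reproj.data)).max() < 1e-10

    def test_impulse_peak_recovered(self, whole_brain_b0s):
        chi = np.zeros(SHAPE)
        chi[16, 16, 16] = 10.0
        fields = [forward_field(VolumeGrid(chi), b0, pad=1) for b0 in whole_brain_b0s]
        res = cosmos(_study(fields, whole_brain_b0s))
        # the unobservable spatial mean shifts the whole map; the peak height
        # relative to the background is the physical quantity
        background = np.median(res.chi.data)
        assert res.chi.data[16, 16, 16] - background == pytest.approx(10.0, abs=1e-6)

    def test_orientation_invariant_map_lands_in_residuals(
        self, smooth_chi, forward_fields, whole_brain_b0s
    ):
        # fields[n] = forward(chi) + g: the estimator absorbs the dipole-
        # explained part of g, D_n * (X_true - X_hat); what remains in every
        # orientation's residual is g minus that leakage -- all residual maps
        # are strongly correlated with g
        g = smooth_random_map(SHAPE, 3.0, np.random.default_rng(5))
        fields = [VolumeGrid(f.data + g) for f in forward_fields]
        res = cosmos(_study(fields, whole_brain_b0s))
        for b0, r in zip(whole_brain_b0s, res.residual_fields):
            d = unit_dipole_kernel(SHAPE, np.ones(3), b0).values
            leak = np.real(np.fft.ifftn(
                d * (np.fft.fftn(smooth_chi) - np.fft.fftn(res.chi.data))
            ))
            assert np.abs(r.data - (g + leak)).max() < 1e-9
            corr = np.corrcoef(r.data.ravel(), g.ravel())[0, 1]
            assert corr > 0.9

    def test_estimator_is_least_squares_minimizer(self, forward_fields, whole_brain_b0s):
        g = smooth_random_map(SHAPE, 3.0, np.random.default_rng(11))
        fields = [VolumeGrid(f.data + g) for f in forward_fields]
        res = cosmos(_study(fields, whole_brain_b0s))

        def objective(chi_map):
            return sum(
                np.sum((f.data - forward_field(chi_map, b0, pad=1).data) ** 2)
                for f, b0 in zip(fields, whole_brain_b0s)
            )

        base = objective(res.chi)
        rng = np.random.default_rng(3)
        for _ in range(3):
            bump = np.zeros(SHAPE)
            bump[tuple(rng.integers(0, 32, size=3))] = 1e-3
            assert objective(res.chi.like(res.chi.data + bump)) >= base - 1e-9

    def test_noise_error_scales_with_sigma(self, smooth_chi, whole_brain_b0s):
        rng = np.random.default_rng(77)
        errors = []
        for sigma in (0.5, 1.0):
            reps = []
            for _ in range(3):
                fields = [
                    VolumeGrid(forward_field(VolumeGrid(smooth_chi), b0, pad=1).data
                               + rng.normal(0, sigma, SHAPE))
                    for b0 in whole_brain_b0s
                ]
                res = cosmos(_study(fields, whole_brain_b0s))
                reps.append(np.sqrt(np.mean((res.chi.data - smooth_chi) ** 2)))
            errors.append(np.mean(reps))
        assert errors[1] / errors[0] == pytest.approx(2.0, rel=0.15)

    def test_insufficient_orientations_rejected(self, forward_fields, whole_brain_b0s):
        sub = OrientationSet(whole_brain_b0s.b0s[:2])
        with pytest.raises(InsufficientOrientationsError):
            cosmos(_study(forward_fields[:2], sub))

    def test_collinear_geometry_rejected(self):
        # antipodal directions are physically identical for dipole physics,
        # so an all-collinear set must be refused
        with pytest.raises(DegenerateGeometryError):
            MultiOrientationStudy(
                fields=[VolumeGrid(np.zeros(SHAPE))] * 3,
                b0s=OrientationSet([B0Direction([0, 0, 1]),
                                    B0Direction([0, 0, -1]),
                                    B0Direction([0, 0, 1])]),
                mask=VolumeGrid(np.ones(SHAPE)),
            )


class TestQuasar:
    def test_joint_recovery_of_chi_and_f_rho(self, smooth_chi, forward_fields,
                                             whole_brain_b0s):
        f_rho = smooth_random_map(SHAPE, 3.0, np.random.default_rng(7))
        fields = [VolumeGrid(f.data + f_rho) for f in forward_fields]
        res = quasar(_study(fields, whole_brain_b0s))
        assert _coeff_rel_rmse(res.chi.data, smooth_chi, res.well_conditioned) < 1e-3
        assert _coeff_rel_rmse(res.f_rho.data, f_rho, res.well_conditioned) < 1e-3

    def test_collapses_to_cosmos_without_f_rho(self, smooth_chi, forward_fields,
                                               whole_brain_b0s):
        study = _study(forward_fields, whole_brain_b0s)
        q = quasar(study)
        c = cosmos(study)
        both = q.well_conditioned & c.well_conditioned
        assert _coeff_rel_rmse(q.chi.data, c.chi.data, both) < 1e-6

    def test_pure_f_rho_yields_no_susceptibility(self, whole_brain_b0s):
        f_rho = smooth_random_map(SHAPE, 3.0, np.random.default_rng(9))
        fields = [VolumeGrid(f_rho.copy()) for _ in whole_brain_b0s]
        res = quasar(_study(fields, whole_brain_b0s))
        chi_rms = np.sqrt(np.mean(res.chi.data ** 2))
        rho_rms = np.sqrt(np.mean(f_rho ** 2))
        assert chi_rms < 0.01 * rho_rms

    def test_residual_norm_bound_invariant(self, smooth_chi, forward_fields,
                                           whole_brain_b0s, rng):
        fields = [VolumeGrid(f.data + rng.normal(0, 0.3, SHAPE)) for f in forward_fields]
        study = _study(fields, whole_brain_b0s)
        res = quasar(study)
        nvox = int(np.sum(study.mask.data > 0))
        for f, b0 in zip(fields, whole_brain_b0s):
            resid = f.data - forward_field(res.chi, b0, pad=1).data - res.f_rho.data
            assert np.linalg.norm(resid) <= res.fit_residual_rms * np.sqrt(nvox) * (1 + 1e-6)

    def test_insufficient_orientations_rejected(self, forward_fields, whole_brain_b0s):
        sub = OrientationSet(whole_brain_b0s.b0s[:3])
        with pytest.raises(InsufficientOrientationsError):
            quasar(_study(forward_fields[:3], sub))

    def test_cosmos_residual_mean_tracks_f_rho(self, forward_fields, whole_brain_b0s):
        # a known empirical signature, here as a synthetic property: the mean COSMOS
        # residual shares contrast and scale with the QUASAR non-susceptibility
        # map, up to the dipole-model leakage of g into chi
        f_rho = smooth_random_map(SHAPE, 3.0, np.random.default_rng(7))
        fields = [VolumeGrid(f.data + f_rho) for f in forward_fields]
        study = _study(fields, whole_brain_b0s)
        res_c = cosmos(study)
        res_q = quasar(study)
        diff = res_c.residual_mean.data - res_q.f_rho.data
        rel = np.sqrt(np.mean(diff ** 2) / np.mean(res_q.f_rho.data ** 2))
        corr = np.corrcoef(res_c.residual_mean.data.ravel(),
                           res_q.f_rho.data.ravel())[0, 1]
        assert rel < 0.2
        assert corr > 0.97


class TestGeometryChecks:
    def test_min_pairwise_angle_folds_antipodes(self):
        s = OrientationSet([B0Direction([0, 0, 1]), B0Direction([0, 1, 0])])
        assert s.min_pairwise_angle() == pytest.approx(90.0)

    def test_printed_specimen_angles_have_unique_geometry(self):
        s = make_orientation_set("specimen")
        assert s.min_pairwise_angle() > 1.0
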