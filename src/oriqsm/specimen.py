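"""Excised-specimen workflow: agar-shell external-field fit and sin^2(theta) fits.

An excised white-matter specimen embedded in agar perturbs the field in the
agar around it in proportion to its isotropic (chi_i) and anisotropic
(chi_a) susceptibility.  Fitting the measured field on an agar shell around
the specimen, jointly over all acquisition orientations,

    min over chi_i, chi_a, {C_N}  sum_N || M_agar (f_N - chi_i df_i,N
                                         - chi_a df_a,N - C_N) ||^2

separates the susceptibility of the tissue from non-susceptibility
microstructural contributions, which cannot leak outside the tissue.  C_N is
a per-orientation baseline absorbing chemical-exchange offsets in the agar
and residual background fields.  The mean residual field inside the specimen
after subtracting the fitted susceptibility field,

    f_R,N = mean over M_specimen of (f_N - chi_i df_i,N - chi_a df_a,N),

isolates the compartmental (microstructure) frequency offset, modelled as
A sin^2(theta_N) + B with theta_N the angle between the specimen's fiber
axis and B0.  The same A sin^2(theta) + B form applies to orientation-
dependent R2*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import statsmodels.api as sm

from .dipole import UnitResponsePair, anisotropic_unit_responses
from .grids import B0Direction, FiberDirection, VolumeGrid
from .inversion import MultiOrientationStudy

__all__ = [
    "SpecimenModel",
    "ExternalFieldFit",
    "Sin2Fit",
    "build_agar_shell_mask",
    "fiber_b0_angle",
    "compute_unit_responses",
    "fit_external_field",
    "residual_internal_field",
    "fit_sin2",
    "fit_r2star_orientation",
]


@dataclass
class SpecimenModel:
    """Specimen mask, mean fiber axis, and the agar shell mask around it."""

    specimen_mask: VolumeGrid
    fiber: FiberDirection
    agar_mask: VolumeGrid

    def __post_init__(self) -> None:
        if np.any((self.specimen_mask.data > 0) & (self.agar_mask.data > 0)):
            raise ValueError("specimen and agar masks must be disjoint")


@dataclass
class ExternalFieldFit:
    """chi_i, chi_a and per-orientation baselines from the agar-shell fit."""

    chi_i: float  # ppb
    chi_i_se: float
    chi_a: float  # ppb
    chi_a_se: float
    baselines: np.ndarray  # C_N, ppb
    baseline_se: np.ndarray
    theta_deg: np.ndarray
    r2: float
    dof: int
    n_orientations: int
    cov_chi: np.ndarray = None  # type: ignore[assignment]  # 2x2 cov of (chi_i, chi_a)
    sigma2: float = np.nan  # residual field-noise variance [ppb^2]


@dataclass
class Sin2Fit:
    """Linear fit y = A sin^2(theta) + B with t-based confidence intervals."""

    A: float
    A_ci: tuple[float, float]
    B: float
    B_ci: tuple[float, float]
    r2: float
    theta_deg: np.ndarray
    y: np.ndarray

    @property
    def A_ci_halfwidth(self) -> float:
        return 0.5 * (self.A_ci[1] - self.A_ci[0])

    def predict(self, theta_deg) -> np.ndarray:
        s2 = np.sin(np.radians(np.asarray(theta_deg, dtype=float))) ** 2
        return self.A * s2 + self.B


def build_agar_shell_mask(
    specimen_mask: VolumeGrid,
    inner_voxels: int = 1,
    outer_voxels: int = 5,
    exclude: np.ndarray | None = None,
) -> VolumeGrid:
    """Agar shell with inner/outer boundaries ``inner``/``outer`` voxels out.

    The shell is ``dilate(specimen, outer) \\ dilate(specimen, inner)`` with a
    6-connected (city-block) structuring element applied iteratively, i.e.
    the voxels whose city-block distance to the specimen lies in
    ``(inner, outer]``.  Voxels in ``exclude`` (e.g. other specimens' masks)
    are removed.
    """
    spec = np.asarray(specimen_mask.data) > 0
    if not np.any(spec):
        raise ValueError("specimen mask is empty")
    if inner_voxels < 1 or outer_voxels <= inner_voxels:
        raise ValueError("need outer_voxels > inner_voxels >= 1")
    structure = ndi.generate_binary_structure(3, 1)
    outer = ndi.binary_dilation(spec, structure=structure, iterations=outer_voxels)
    inner = ndi.binary_dilation(spec, structure=structure, iterations=inner_voxels)
    shell = outer & ~inner
    if exclude is not None:
        shell &= ~(np.asarray(exclude) > 0)
    if not np.any(shell):
        raise ValueError("agar shell mask is empty")
    return specimen_mask.like(shell.astype(float))


def fiber_b0_angle(fiber: FiberDirection, b0: B0Direction) -> float:
    """Angle [deg] between fiber axis and B0, folded to [0, 90]."""
    if not isinstance(fiber, FiberDirection):
        fiber = FiberDirection(fiber)
    if not isinstance(b0, B0Direction):
        b0 = B0Direction(b0)
    c = abs(float(np.dot(fiber.vector, b0.vector)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def compute_unit_responses(
    model: SpecimenModel, b0s, pad: int = 2
) -> list[UnitResponsePair]:
    """Per-orientation unit responses (df_i,N, df_a,N) of a specimen."""
    return [anisotropic_unit_responses(model.specimen_mask, model.fiber, b0, pad=pad)
            for b0 in b0s]


def fit_external_field(
    study: MultiOrientationStudy,
    model: SpecimenModel,
    responses: list[UnitResponsePair] | None = None,
) -> ExternalFieldFit:
    """Pooled OLS of the agar-shell field over all orientations.

    Design columns are [df_i,N, df_a,N, per-orientation indicator baselines]
    evaluated at every agar voxel of every orientation; the pooled fit is the
    exact minimiser of the summed squared norm over orientations.

    ``responses`` may carry precomputed unit responses (one per orientation)
    to avoid repeating the forward model, e.g. across Monte-Carlo replicates.
    """
    if not model.specimen_mask.same_geometry(study.mask):
        raise ValueError("specimen model and study must share one grid")
    n = study.n_orientations
    theta = np.array([fiber_b0_angle(model.fiber, b0) for b0 in study.b0s])
    if len(np.unique(np.round(theta, 6))) < 2:
        raise ValueError(
            "chi_a is unidentifiable: all orientations have the same "
            f"fiber-to-B0 angle ({theta[0]:.2f} deg)"
        )
    if responses is None:
        responses = compute_unit_responses(model, study.b0s)
    agar = model.agar_mask.data > 0
    m = int(agar.sum())
    y = np.concatenate([f.data[agar] for f in study.fields])
    col_i = np.concatenate([r.delta_f_i.data[agar] for r in responses])
    col_a = np.concatenate([r.delta_f_a.data[agar] for r in responses])
    design = np.zeros((n * m, 2 + n))
    design[:, 0] = col_i
    design[:, 1] = col_a
    for j in range(n):
        design[j * m:(j + 1) * m, 2 + j] = 1.0
    res = sm.OLS(y, design).fit()
    # centred R^2 (statsmodels reports uncentred R^2 without a single intercept)
    ss_res = float(np.sum(res.resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ExternalFieldFit(
        chi_i=float(res.params[0]),
        chi_i_se=float(res.bse[0]),
        chi_a=float(res.params[1]),
        chi_a_se=float(res.bse[1]),
        baselines=np.asarray(res.params[2:]),
        baseline_se=np.asarray(res.bse[2:]),
        theta_deg=theta,
        r2=r2,
        dof=int(res.df_resid),
        n_orientations=n,
        cov_chi=np.asarray(res.cov_params())[:2, :2],
        sigma2=float(res.mse_resid),
    )


def residual_internal_field(
    study: MultiOrientationStudy,
    model: SpecimenModel,
    fit: ExternalFieldFit,
    responses: list[UnitResponsePair] | None = None,
    subtract_baseline: bool = False,
) -> np.ndarray:
    """Per-orientation mean residual field f_R,N inside the specimen [ppb].

    Subtracts the fitted susceptibility-induced field chi_i df_i,N +
    chi_a df_a,N from each orientation's field and averages over the specimen
    mask.  The agar baseline C_N is a property of the agar reference and is
    not subtracted by default; ``subtract_baseline=True`` removes it too, for
    data whose per-orientation offset is global rather than agar-specific.
    """
    if responses is None:
        responses = compute_unit_responses(model, study.b0s)
    spec = model.specimen_mask.data > 0
    out = np.empty(study.n_orientations)
    for j, (f, r) in enumerate(zip(study.fields, responses)):
        resid = f.data - fit.chi_i * r.delta_f_i.data - fit.chi_a * r.delta_f_a.data
        if subtract_baseline:
            resid = resid - fit.baselines[j]
        out[j] = float(resid[spec].mean())
    return out


def fit_sin2(theta_deg, y, level: float = 0.95) -> Sin2Fit:
    """OLS of y on sin^2(theta): slope A, intercept B, t-based CIs, R^2.

    Two points with distinct angles interpolate exactly (zero residual
    degrees of freedom; CI half-widths are +inf in that case).
    """
    theta = np.asarray(theta_deg, dtype=float)
    y = np.asarray(y, dtype=float)
    if theta.shape != y.shape or theta.ndim != 1 or len(theta) < 2:
        raise ValueError("need >= 2 paired (theta, y) samples")
    s2 = np.sin(np.radians(theta)) ** 2
    if len(np.unique(np.round(s2, 12))) < 2:
        raise ValueError("slope unidentifiable: all sin^2(theta) values equal")
    design = sm.add_constant(s2)
    res = sm.OLS(y, design).fit()
    if res.df_resid > 0:
        ci = res.conf_int(alpha=1.0 - level)
        b_ci, a_ci = tuple(ci[0]), tuple(ci[1])
    else:
        a_ci = (-np.inf, np.inf)
        b_ci = (-np.inf, np.inf)
    ss_res = float(np.sum(res.resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return Sin2Fit(
        A=float(res.params[1]),
        A_ci=(float(a_ci[0]), float(a_ci[1])),
        B=float(res.params[0]),
        B_ci=(float(b_ci[0]), float(b_ci[1])),
        r2=r2,
        theta_deg=theta,
        y=y,
    )


def fit_residual_sin2(
    fit: ExternalFieldFit,
    f_r,
    model: SpecimenModel,
    responses: list[UnitResponsePair],
    level: float = 0.95,
) -> Sin2Fit:
    """sin^2(theta) fit of the internal residual means with error propagation.

    The residual means f_R,N inherit two error sources: the specimen-mean of
    the field noise (variance sigma^2 / n_specimen, independent across
    orientations) and the estimation error of (chi_i, chi_a) from the agar
    fit, which enters every orientation through the loadings
    L_N = (mean delta_f_i,N, mean delta_f_a,N) and is strongly correlated
    with sin^2(theta).  An ordinary sin^2 regression ignores the second
    source and understates the uncertainty of A, so this fit solves the
    generalised least-squares problem with

        Omega = (sigma^2 / n_specimen) I + L Cov(chi_hat) L^T

    and reports normal-quantile confidence intervals (the covariance is
    estimated from the very large agar-voxel sample, so Student corrections
    are negligible).
    """
    from scipy.stats import norm

    f_r = np.asarray(f_r, dtype=float)
    theta = np.asarray(fit.theta_deg, dtype=float)
    spec = model.specimen_mask.data > 0
    n_spec = int(spec.sum())
    loadings = np.column_stack([
        [r.delta_f_i.data[spec].mean() for r in responses],
        [r.delta_f_a.data[spec].mean() for r in responses],
    ])
    omega = (fit.sigma2 / n_spec) * np.eye(len(theta))
    omega += loadings @ fit.cov_chi @ loadings.T
    s2 = np.sin(np.radians(theta)) ** 2
    design = np.column_stack([np.ones_like(s2), s2])
    w = np.linalg.inv(omega)
    normal = design.T @ w @ design
    beta = np.linalg.solve(normal, design.T @ w @ f_r)
    cov_beta = np.linalg.inv(normal)
    z = norm.ppf(0.5 + level / 2.0)
    halfwidths = z * np.sqrt(np.diag(cov_beta))
    resid = f_r - design @ beta
    ss_tot = float(np.sum((f_r - f_r.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return Sin2Fit(
        A=float(beta[1]),
        A_ci=(float(beta[1] - halfwidths[1]), float(beta[1] + halfwidths[1])),
        B=float(beta[0]),
        B_ci=(float(beta[0] - halfwidths[0]), float(beta[0] + halfwidths[0])),
        r2=r2,
        theta_deg=theta,
        y=f_r,
    )


def fit_r2star_orientation(theta_deg, r2star_hz, level: float = 0.95) -> Sin2Fit:
    """R2*(theta) = A sin^2(theta) + B on per-orientation mean R2* [Hz].

    Identical contract to :func:`fit_sin2`; A is the maximum orientation
    dependence of R2* (R2*_perp - R2*_par) in Hz.
    """
    return fit_sin2(theta_deg, r2star_hz, level=level)
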