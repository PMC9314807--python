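"""Multi-orientation dipole inversions: COSMOS and QUASAR.

With tissue fields f_N acquired at several object orientations relative to
B0, each Fourier coefficient of the susceptibility map is overdetermined:

* COSMOS solves, per coefficient k,  X(k) = sum_N D_N(k) F_N(k) / sum_N D_N(k)^2,
  the exact least-squares minimiser of sum_N |F_N(k) - D_N(k) X(k)|^2.
  Where the conditioning sum_N D_N^2 falls below a threshold tau the
  coefficient is Tikhonov-damped (denominator + tau) instead of truncated,
  which avoids ringing.
* QUASAR jointly estimates the susceptibility X(k) and an orientation-
  invariant non-susceptibility field contribution R(k) from
  F_N(k) = D_N(k) X(k) + R(k), a per-coefficient 2x2 least-squares problem,
  ridge-stabilised where the normal matrix is ill-conditioned.

Inversions operate on the periodic DFT lattice by default (``pad=1``, the
standard COSMOS convention); passing ``pad`` > 1 matches the zero-padded
forward operator instead.  Fields are assumed referenced upstream (the
background-removal stage demeans over the mask); no demeaning happens here,
so that the inversion is the exact algebraic inverse of the forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dipole import forward_field, unit_dipole_kernel
from .grids import B0Direction, VolumeGrid

__all__ = [
    "OrientationSet",
    "MultiOrientationStudy",
    "CosmosResult",
    "QuasarResult",
    "DegenerateGeometryError",
    "InsufficientOrientationsError",
    "cosmos",
    "quasar",
]


class InsufficientOrientationsError(ValueError):
    pass


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class OrientationSet:
    """N unit B0 directions in the common frame, with provenance angles [deg].

    ``angles_deg`` records the rotation angle of each acquisition relative to
    the reference axis as registered; it is provenance only — all physics
    uses the vectors.
    """

    b0s: list[B0Direction]
    angles_deg: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.b0s = [b if isinstance(b, B0Direction) else B0Direction(b) for b in self.b0s]
        if self.angles_deg is not None:
            self.angles_deg = np.asarray(self.angles_deg, dtype=float)
            if len(self.angles_deg) != len(self.b0s):
                raise ValueError("one provenance angle per direction")

    def __len__(self) -> int:
        return len(self.b0s)

    def __iter__(self):
        return iter(self.b0s)

    def vectors(self) -> np.ndarray:
        return np.stack([b.vector for b in self.b0s])

    def min_pairwise_angle(self) -> float:
        """Smallest pairwise angular separation [deg], folded to [0, 90]."""
        best = 90.0
        for i in range(len(self.b0s)):
            for j in range(i + 1, len(self.b0s)):
                best = min(best, self.b0s[i].angle_to(self.b0s[j]))
        return best


@dataclass
class MultiOrientationStudy:
    """Per-orientation tissue fields [ppb] on one grid, plus a shared mask."""

    fields: list[VolumeGrid]
    b0s: OrientationSet
    mask: VolumeGrid

    def __post_init__(self) -> None:
        if len(self.fields) != len(self.b0s):
            raise ValueError("one field volume per orientation")
        for f in self.fields:
            if not f.same_geometry(self.mask):
                raise ValueError("all volumes must share one grid")
        if self.b0s.min_pairwise_angle() <= 1.0:
            raise DegenerateGeometryError(
                "orientation set contains directions closer than 1 degree"
            )

    @property
    def n_orientations(self) -> int:
        return len(self.fields)


@dataclass
class CosmosResult:
    chi: VolumeGrid  # ppb
    residual_fields: list[VolumeGrid]
    residual_mean: VolumeGrid
    residual_sd: VolumeGrid
    kspace_condition: np.ndarray  # sum_N D_N(k)^2 on the (padded) lattice
    well_conditioned: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass
class QuasarResult:
    chi: VolumeGrid  # ppb
    f_rho: VolumeGrid  # ppb, orientation-invariant non-susceptibility field
    fit_residual_rms: float
    well_conditioned: np.ndarray = field(default=None)  # type: ignore[assignment]


def _check_geometry(b0s: OrientationSet, n_min: int, joint: bool) -> None:
    n = len(b0s)
    if n < n_min:
        raise InsufficientOrientationsError(
            f"need >= {n_min} orientations, got {n}"
        )
    # probe the stacked per-orientation design at a few k directions; for
    # collinear orientation sets every row is identical and the design drops rank
    rng = np.random.default_rng(0)
    probes = rng.normal(size=(8, 3))
    probes /= np.linalg.norm(probes, axis=1, keepdims=True)
    vecs = b0s.vectors()
    worst = 0.0
    for khat in probes:
        d = 1.0 / 3.0 - (vecs @ khat) ** 2
        design = np.column_stack([d, np.ones(n)]) if joint else (d - d.mean())[:, None]
        worst = max(worst, float(np.linalg.svd(design, compute_uv=False).min()))
    if worst <= 1e-3:
        raise DegenerateGeometryError(
            "B0 orientation set is (near-)degenerate: the dipole coefficients "
            "do not vary across orientations"
        )


def _stacked_kernels(study: MultiOrientationStudy, pad: int):
    shape = study.mask.shape
    pshape = tuple(pad * n for n in shape)
    kernels = [
        unit_dipole_kernel(pshape, study.mask.voxel_size, b0).values for b0 in study.b0s
    ]
    spectra = []
    for f in study.fields:
        src = np.zeros(pshape, dtype=complex)
        src[: shape[0], : shape[1], : shape[2]] = f.data * (study.mask.data > 0)
        spectra.append(np.fft.fftn(src))
    return kernels, spectra, pshape


def _crop(arr: np.ndarray, shape) -> np.ndarray:
    return arr[: shape[0], : shape[1], : shape[2]]


def cosmos(study: MultiOrientationStudy, tau: float = 0.01, pad: int = 1) -> CosmosResult:
    """Per-Fourier-coefficient least-squares susceptibility inversion.

    Parameters
    ----------
    tau:
        Conditioning threshold on sum_N D_N(k)^2; coefficients below it are
        Tikhonov-damped: X = sum(D F) / (sum(D^2) + tau).
    pad:
        Zero-padding factor of the inversion lattice; 1 (periodic) matches
        the usual COSMOS convention and is the exact inverse of
        ``forward_field(..., pad=1)``.
    """
    _check_geometry(study.b0s, n_min=3, joint=False)
    kernels, spectra, _ = _stacked_kernels(study, pad)
    sum_d2 = np.zeros(kernels[0].shape)
    sum_df = np.zeros(kernels[0].shape, dtype=complex)
    for d, f in zip(kernels, spectra):
        sum_d2 += d**2
        sum_df += d * f
    well = sum_d2 >= tau
    denom = np.where(well, sum_d2, sum_d2 + tau)
    # k = 0 carries no dipole information at all; the mean is not recoverable
    denom[0, 0, 0] = np.inf
    x = sum_df / denom
    shape = study.mask.shape
    chi = study.mask.like(_crop(np.real(np.fft.ifftn(x)), shape) * (study.mask.data > 0))
    residuals = [
        study.mask.like(
            (f.data - forward_field(chi, b0, pad=pad).data) * (study.mask.data > 0)
        )
        for f, b0 in zip(study.fields, study.b0s)
    ]
    stack = np.stack([r.data for r in residuals])
    return CosmosResult(
        chi=chi,
        residual_fields=residuals,
        residual_mean=study.mask.like(stack.mean(axis=0)),
        residual_sd=study.mask.like(stack.std(axis=0)),
        kspace_condition=sum_d2,
        well_conditioned=well,
    )


def quasar(
    study: MultiOrientationStudy,
    ridge_fraction: float = 1e-3,
    cond_threshold: float = 1e-3,
    pad: int = 1,
) -> QuasarResult:
    """Joint susceptibility + non-susceptibility field inversion.

    Solves, per Fourier coefficient, the 2x2 least-squares system for
    (X(k), R(k)) in F_N(k) = D_N(k) X(k) + R(k).  Where the smallest
    eigenvalue of the normal matrix falls below ``cond_threshold`` times its
    trace, a ridge ``ridge_fraction * trace`` is added to the diagonal.
    """
    _check_geometry(study.b0s, n_min=4, joint=True)
    kernels, spectra, _ = _stacked_kernels(study, pad)
    n = len(kernels)
    a11 = np.zeros(kernels[0].shape)
    a12 = np.zeros(kernels[0].shape)
    b1 = np.zeros(kernels[0].shape, dtype=complex)
    b2 = np.zeros(kernels[0].shape, dtype=complex)
    for d, f in zip(kernels, spectra):
        a11 += d**2
        a12 += d
        b1 += d * f
        b2 += f
    a22 = float(n)
    trace = a11 + a22
    det = a11 * a22 - a12**2
    # smallest eigenvalue of the symmetric 2x2 normal matrix
    lam_min = 0.5 * (trace - np.sqrt(np.maximum(trace**2 - 4.0 * det, 0.0)))
    well = lam_min > cond_threshold * trace
    ridge = np.where(well, 0.0, ridge_fraction * trace)
    r11 = a11 + ridge
    r22 = a22 + ridge
    det_r = r11 * r22 - a12**2
    x = (r22 * b1 - a12 * b2) / det_r
    r = (r11 * b2 - a12 * b1) / det_r
    shape = study.mask.shape
    maskbin = study.mask.data > 0
    chi = study.mask.like(_crop(np.real(np.fft.ifftn(x)), shape) * maskbin)
    f_rho = study.mask.like(_crop(np.real(np.fft.ifftn(r)), shape) * maskbin)
    rms = 0.0
    nvox = int(maskbin.sum())
    for f, b0 in zip(study.fields, study.b0s):
        res = (f.data - forward_field(chi, b0, pad=pad).data - f_rho.data) * maskbin
        rms = max(rms, float(np.sqrt((res**2).sum() / nvox)))
    return QuasarResult(chi=chi, f_rho=f_rho, fit_residual_rms=rms, well_conditioned=well)
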