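"""Fourier-domain magnetostatic forward models.

The field perturbation (in ppb, Lorentz-sphere corrected) produced by a
susceptibility distribution chi is, in the continuous k-space convention,

    f(k) = D(k) chi(k),      D(k) = 1/3 - (k . b)^2 / |k|^2,

with b the unit B0 direction.  D is bounded in [-2/3, 1/3], vanishes on the
magic-angle cone 3 cos^2(psi) = 1 and its k = 0 entry is set to 0 (mean-free
field convention), making forward fields reference-free like demodulated
phase.  For a cylindrically symmetric susceptibility tensor

    chi_hat = chi_i I + chi_a (f f^T - I/3)       (chi_a = chi_par - chi_perp)

the field of the anisotropic part follows the tensor forward model

    f(k) = (1/3) b^T chi_hat(k) b - (k . b) (k^T chi_hat(k) b) / |k|^2 .

Convolutions are evaluated by FFT with zero-padding (default 2x per axis) to
suppress circular wrap-around; ``pad=1`` selects the plain periodic lattice,
which is the convention the multi-orientation inversions use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import B0Direction, FiberDirection, VolumeGrid

__all__ = [
    "DipoleKernel",
    "UnitResponsePair",
    "unit_dipole_kernel",
    "forward_field",
    "anisotropic_unit_responses",
    "ppb_to_hz",
    "hz_to_ppb",
]

GYROMAGNETIC_RATIO_MHZ_PER_T = 42.577  # reduced gyromagnetic ratio of 1H


def ppb_to_hz(f_ppb, b0_tesla: float = 3.0):
    """Convert a relative field shift [ppb] to frequency [Hz]."""
    return np.asarray(f_ppb) * 1e-9 * GYROMAGNETIC_RATIO_MHZ_PER_T * 1e6 * b0_tesla


def hz_to_ppb(f_hz, b0_tesla: float = 3.0):
    return np.asarray(f_hz) / (1e-9 * GYROMAGNETIC_RATIO_MHZ_PER_T * 1e6 * b0_tesla)


def _k_lattice(shape, voxel_size):
    """Sparse broadcastable k coordinates [cycles/mm] of the DFT lattice."""
    freqs = [np.fft.fftfreq(n, d=dx) for n, dx in zip(shape, voxel_size)]
    return np.meshgrid(*freqs, indexing="ij", sparse=True)


def _symmetrize(values: np.ndarray) -> np.ndarray:
    """Average a k-space kernel with its point reflection k -> -k.

    On even grids the Nyquist frequency is its own negative, so a kernel
    evaluated naively from fftfreq coordinates is not point-symmetric on
    Nyquist planes; the convolution of a real map would then come out
    complex and the forward operator would not be diagonal in k.  Averaging
    over the lattice's +-k identification restores exact symmetry (a no-op
    away from Nyquist planes).
    """
    mirror = values
    for axis, n in enumerate(values.shape):
        mirror = np.take(mirror, (-np.arange(n)) % n, axis=axis)
    return 0.5 * (values + mirror)


@dataclass
class DipoleKernel:
    """The unit dipole response D(k) sampled on a discrete Fourier lattice."""

    values: np.ndarray
    b0: B0Direction
    grid_shape: tuple[int, int, int]
    dc_value: float = 0.0


def unit_dipole_kernel(grid_shape, voxel_size, b0: B0Direction) -> DipoleKernel:
    """D(k) = 1/3 - (k.b)^2/|k|^2 on the DFT lattice of ``grid_shape``.

    The k = 0 coefficient is set to ``0`` (mean-free convention): a uniform
    susceptibility offset produces no observable demodulated field.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if len(grid_shape) != 3 or min(grid_shape) < 4:
        raise ValueError(f"grid_shape must be 3 dims >= 4, got {grid_shape}")
    if not isinstance(b0, B0Direction):
        b0 = B0Direction(b0)
    kx, ky, kz = _k_lattice(grid_shape, np.asarray(voxel_size, dtype=float))
    k2 = kx**2 + ky**2 + kz**2
    kb = kx * b0.vector[0] + ky * b0.vector[1] + kz * b0.vector[2]
    with np.errstate(invalid="ignore", divide="ignore"):
        values = 1.0 / 3.0 - (kb**2) / k2
    values[0, 0, 0] = 0.0
    values = _symmetrize(values)
    return DipoleKernel(values=values, b0=b0, grid_shape=grid_shape, dc_value=0.0)


def _padded_shape(shape, pad: int):
    if pad < 1 or int(pad) != pad:
        raise ValueError("pad must be a positive integer factor")
    return tuple(int(pad) * n for n in shape)


def _fft_convolve(source: np.ndarray, kernel_values: np.ndarray, shape) -> np.ndarray:
    """Multiply FFT(source zero-padded to kernel shape) by a k-space kernel."""
    src = np.zeros(kernel_values.shape, dtype=complex)
    src[: shape[0], : shape[1], : shape[2]] = source
    out = np.fft.ifftn(kernel_values * np.fft.fftn(src))
    return np.real(out[: shape[0], : shape[1], : shape[2]])


def forward_field(chi: VolumeGrid, b0: B0Direction, pad: int = 2) -> VolumeGrid:
    """Field perturbation [ppb] of a scalar susceptibility map [ppb].

    Computes the Lorentz-sphere-corrected dipole convolution ``d * chi`` by
    FFT on a lattice zero-padded by ``pad`` per axis (cropped back after).
    """
    chi.require_finite("susceptibility map")
    if not isinstance(b0, B0Direction):
        b0 = B0Direction(b0)
    pshape = _padded_shape(chi.shape, pad)
    kernel = unit_dipole_kernel(pshape, chi.voxel_size, b0)
    return chi.like(_fft_convolve(chi.data, kernel.values, chi.shape))


@dataclass
class UnitResponsePair:
    """Frequency perturbations per unit chi_i and per unit chi_a.

    ``delta_f_i`` is the field of the mask with unit isotropic susceptibility;
    ``delta_f_a`` is the field of the unit traceless anisotropic tensor
    ``f f^T - I/3`` supported on the mask.  Both vanish far from the specimen.
    """

    delta_f_i: VolumeGrid
    delta_f_a: VolumeGrid
    b0: B0Direction
    fiber: FiberDirection


def anisotropic_tensor_kernel(grid_shape, voxel_size, b0: B0Direction,
                              fiber: FiberDirection) -> np.ndarray:
    """k-space response of the unit anisotropic tensor T = f f^T - I/3.

    For chi_hat(k) = M(k) T the tensor forward model reduces to a scalar
    kernel multiplying the mask spectrum M(k):

        K_a(k) = (1/3)(c^2 - 1/3) - (k.b) [ (k.f) c - (k.b)/3 ] / |k|^2

    with c = f.b.  For fiber parallel to b0 this is (2/3) D(k).
    """
    kx, ky, kz = _k_lattice(grid_shape, np.asarray(voxel_size, dtype=float))
    f, b = fiber.vector, b0.vector
    c = float(np.dot(f, b))
    k2 = kx**2 + ky**2 + kz**2
    kb = kx * b[0] + ky * b[1] + kz * b[2]
    kf = kx * f[0] + ky * f[1] + kz * f[2]
    with np.errstate(invalid="ignore", divide="ignore"):
        values = (c**2 - 1.0 / 3.0) / 3.0 - kb * (kf * c - kb / 3.0) / k2
    values[0, 0, 0] = 0.0
    return _symmetrize(values)


def anisotropic_unit_responses(
    specimen_mask: VolumeGrid,
    fiber: FiberDirection,
    b0: B0Direction,
    pad: int = 2,
) -> UnitResponsePair:
    """Unit-susceptibility responses delta_f_i and delta_f_a of a specimen.

    delta_f_i is ``forward_field`` of the binary mask (unit isotropic chi);
    delta_f_a is the field of the cylindrically symmetric tensor's traceless
    part ``f f^T - I/3`` restricted to the mask, via the tensor forward model.
    Antipodal fiber flips leave the pair unchanged.
    """
    mask = np.asarray(specimen_mask.data)
    if not np.all((mask == 0) | (mask == 1)):
        raise ValueError("specimen mask must be binary")
    if not np.any(mask):
        raise ValueError("specimen mask is empty")
    if not isinstance(b0, B0Direction):
        b0 = B0Direction(b0)
    if not isinstance(fiber, FiberDirection):
        fiber = FiberDirection(fiber)
    mask = mask.astype(float)
    pshape = _padded_shape(specimen_mask.shape, pad)
    iso_kernel = unit_dipole_kernel(pshape, specimen_mask.voxel_size, b0).values
    aniso_kernel = anisotropic_tensor_kernel(pshape, specimen_mask.voxel_size, b0, fiber)

    # one forward FFT of the padded mask shared by both responses
    src = np.zeros(pshape, dtype=complex)
    src[: mask.shape[0], : mask.shape[1], : mask.shape[2]] = mask
    mk = np.fft.fftn(src)
    sl = tuple(slice(0, n) for n in mask.shape)
    delta_f_i = np.real(np.fft.ifftn(iso_kernel * mk))[sl]
    delta_f_a = np.real(np.fft.ifftn(aniso_kernel * mk))[sl]
    return UnitResponsePair(
        delta_f_i=specimen_mask.like(delta_f_i),
        delta_f_a=specimen_mask.like(delta_f_a),
        b0=b0,
        fiber=fiber,
    )
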