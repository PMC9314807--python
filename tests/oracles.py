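"""Independent brute-force oracles used by the tests.

These deliberately avoid numpy.fft: Fourier transforms are computed by dense
DFT matrix multiplication and convolutions by explicit spatial summation
over shifted copies of the kernel, so they share no code path with the
package's FFT-based forward models.
"""

from __future__ import annotations

import numpy as np


def _dft_matrix(n: int, sign: int) -> np.ndarray:
    j = np.arange(n)
    m = np.exp(sign * 2j * np.pi * np.outer(j, j) / n)
    return m / n if sign > 0 else m


def slow_spatial_kernel(kernel_k: np.ndarray) -> np.ndarray:
    """Spatial-domain kernel via slow (matrix) inverse DFT of a k-kernel."""
    out = kernel_k.astype(complex)
    for axis in range(3):
        m = _dft_matrix(kernel_k.shape[axis], +1)
        out = np.moveaxis(np.tensordot(m, np.moveaxis(out, axis, 0), axes=(1, 0)), 0, axis)
    return np.real(out)


def brute_force_convolve(source: np.ndarray, kernel_k: np.ndarray) -> np.ndarray:
    """Direct spatial dipole summation on the zero-padded periodic lattice.

    Builds the spatial kernel by slow inverse DFT, zero-pads the source to
    the kernel's lattice, and sums shifted kernel copies voxel by voxel.
    Returns the field cropped back to the source's shape.
    """
    pshape = kernel_k.shape
    ker = slow_spatial_kernel(kernel_k)
    out = np.zeros(pshape)
    for (i, j, k) in np.argwhere(source != 0):
        out += source[i, j, k] * np.roll(ker, (i, j, k), axis=(0, 1, 2))
    sl = tuple(slice(0, n) for n in source.shape)
    return out[sl]


def city_block_distance_to_mask(mask: np.ndarray) -> np.ndarray:
    """Exhaustive city-block (L1) distance from every voxel to a mask."""
    pts = np.argwhere(mask)
    coords = np.indices(mask.shape).reshape(3, -1).T
    d = np.abs(coords[:, None, :] - pts[None, :, :]).sum(axis=2).min(axis=1)
    return d.reshape(mask.shape)
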