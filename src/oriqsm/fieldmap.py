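"""Field-map estimation from multi-echo GRE data and background-field removal.

Two stages of the phase pipeline live here:

* ``combine_echoes`` — per-voxel weighted least-squares slope of (temporally
  unwrapped) phase against 2*pi*TE, with weights proportional to the squared
  magnitude, i.e. inverse phase variance.  Returns the total field in Hz.
* ``remove_background_field`` — removes the harmonic field component caused
  by susceptibility sources outside the mask, by solving the Laplace
  boundary-value problem on the mask interior (7-point finite-difference
  Laplacian, Dirichlet boundary values taken from the total field) and
  subtracting the harmonic solution.  The result is demeaned over the mask:
  the absolute field reference inside a mask is not an observable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grids import VolumeGrid

__all__ = [
    "MultiEchoVolume",
    "FieldMap",
    "BackgroundRemovalError",
    "temporal_unwrap",
    "combine_echoes",
    "remove_background_field",
]


class BackgroundRemovalError(RuntimeError):
    """Iterative Laplace solver failed to converge; carries the residual norm."""

    def __init__(self, message: str, residual_norm: float):
        super().__init__(message)
        self.residual_norm = residual_norm


@dataclass
class MultiEchoVolume:
    """Multi-echo magnitude/phase volumes with their echo times.

    ``magnitude`` and ``phase`` are 4D (x, y, z, echo); phase is wrapped to
    (-pi, pi]; ``echo_times_ms`` is strictly increasing with >= 2 entries.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    echo_times_ms: np.ndarray
    voxel_size: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        self.echo_times_ms = np.asarray(self.echo_times_ms, dtype=float)
        if self.magnitude.ndim != 4 or self.phase.shape != self.magnitude.shape:
            raise ValueError("magnitude and phase must be matching 4D arrays")
        n_echo = self.magnitude.shape[3]
        if n_echo < 2 or self.echo_times_ms.shape != (n_echo,):
            raise ValueError("need >= 2 echoes with one echo time per echo")
        if np.any(np.diff(self.echo_times_ms) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitudes must be non-negative")
        if self.voxel_size is None:
            self.voxel_size = np.ones(3)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)


@dataclass
class FieldMap:
    """Total and tissue field with the mask they are defined on."""

    total_field: VolumeGrid  # Hz
    tissue_field: VolumeGrid | None
    mask: VolumeGrid
    reliability: VolumeGrid | None = None


def temporal_unwrap(phase: np.ndarray, axis: int = -1) -> np.ndarray:
    """Cumulative nearest-multiple-of-2*pi correction along the echo axis."""
    return np.unwrap(np.asarray(phase, dtype=float), axis=axis)


def combine_echoes(data: MultiEchoVolume, mask: np.ndarray | None = None):
    """Optimum weighted combination of echo phases into a field map [Hz].

    Fits, per voxel, ``phase(TE) = 2 pi f TE + phi0`` by weighted least
    squares with weights ``magnitude**2`` (proportional to the inverse phase
    variance at a given thermal noise level).  The phase is temporally
    unwrapped first.  Voxels whose magnitude is identically zero get field 0
    and are flagged 0 in the reliability map.

    Returns
    -------
    (total_field, reliability):
        ``total_field`` is a :class:`VolumeGrid` in Hz; ``reliability`` is 1
        where the fit used valid weights and 0 where it was degenerate.
    """
    phase = temporal_unwrap(data.phase, axis=-1)
    t = data.echo_times_ms[None, None, None, :] * 1e-3  # s
    w = data.magnitude**2
    wsum = w.sum(axis=-1)
    degenerate = wsum <= 0
    # uniform weights in degenerate voxels keep the algebra finite; flagged after
    w = np.where(degenerate[..., None], 1.0, w)
    wsum = w.sum(axis=-1)
    t_bar = (w * t).sum(axis=-1) / wsum
    p_bar = (w * phase).sum(axis=-1) / wsum
    t_c = t - t_bar[..., None]
    num = (w * t_c * phase).sum(axis=-1)
    den = (w * t_c**2).sum(axis=-1)
    slope = num / den  # rad/s
    field = slope / (2.0 * np.pi)
    field[degenerate] = 0.0
    del p_bar  # intercept (phase at TE=0) absorbed, not reported
    if mask is not None:
        field = field * (np.asarray(mask) > 0)
    reliability = (~degenerate).astype(float)
    total = VolumeGrid(field, voxel_size=data.voxel_size)
    return total, VolumeGrid(reliability, voxel_size=data.voxel_size)


def _interior_laplace_system(mask: np.ndarray, boundary_values: np.ndarray,
                             voxel_size: np.ndarray):
    """Sparse 7-point Laplace system for the harmonic interior problem.

    Unknowns are the interior voxels (mask eroded by one 6-connected step);
    Dirichlet data on the remaining mask ring comes from ``boundary_values``.
    """
    structure = ndi.generate_binary_structure(3, 1)
    interior = ndi.binary_erosion(mask, structure=structure, border_value=0)
    n = int(interior.sum())
    if n == 0:
        raise ValueError("mask has no interior voxels after erosion")
    index = -np.ones(mask.shape, dtype=np.int64)
    index[interior] = np.arange(n)
    inv_h2 = 1.0 / np.asarray(voxel_size, dtype=float) ** 2

    rows, cols, vals = [], [], []
    b = np.zeros(n)
    ii, jj, kk = np.nonzero(interior)
    center = np.zeros(n)
    for axis in range(3):
        for step in (-1, 1):
            neigh = [ii, jj, kk]
            neigh[axis] = neigh[axis] + step
            ni, nj, nk = neigh
            w = inv_h2[axis]
            center -= w
            neigh_idx = index[ni, nj, nk]
            inside = neigh_idx >= 0
            rows.append(index[ii, jj, kk][inside])
            cols.append(neigh_idx[inside])
            vals.append(np.full(inside.sum(), w))
            # neighbours on the boundary ring carry Dirichlet data
            ring = ~inside
            b[index[ii, jj, kk][ring]] -= w * boundary_values[ni[ring], nj[ring], nk[ring]]
    diag = np.arange(n)
    rows.append(diag)
    cols.append(diag)
    vals.append(center)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return A, b, interior, index


def remove_background_field(
    total_field: VolumeGrid,
    mask: np.ndarray | VolumeGrid,
    tol: float = 1e-6,
    maxiter: int = 2000,
) -> VolumeGrid:
    """Remove the harmonic (external-source) field component inside a mask.

    Solves the Laplace boundary-value problem on the mask interior with the
    measured total field as Dirichlet data, subtracts the harmonic solution,
    and demeans the remainder over the mask.  Fields from sources strictly
    outside the mask are harmonic inside it and are removed up to
    discretisation error; fields from internal sources are preserved.
    """
    if isinstance(mask, VolumeGrid):
        mask = mask.data
    mask = np.asarray(mask) > 0
    if not np.any(mask):
        raise ValueError("mask is empty")
    field = np.asarray(total_field.data, dtype=float)
    A, b, interior, index = _interior_laplace_system(mask, field, total_field.voxel_size)

    # -A is symmetric positive definite (Dirichlet Laplacian)
    u, info = spla.cg(-A, -b, rtol=tol, maxiter=maxiter)
    residual = float(np.linalg.norm(A @ u - b))
    if info != 0:
        raise BackgroundRemovalError(
            f"Laplace solver did not converge in {maxiter} iterations "
            f"(residual norm {residual:.3e})",
            residual_norm=residual,
        )
    harmonic = field.copy()
    harmonic[interior] = u
    tissue = np.where(mask, field - harmonic, 0.0)
    tissue[mask] -= tissue[mask].mean()
    return total_field.like(tissue)
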