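"""Closed-form R2* estimation from multi-echo GRE magnitude data.

The monoexponential decay S(TE) = S0 exp(-R2* TE) becomes linear in the log,
ln S = ln S0 - R2* TE, and is solved per voxel by weighted least squares with
weights magnitude^2 (the noise of ln S scales as 1/S), giving a closed-form
estimate with no iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import VolumeGrid

__all__ = ["R2StarMap", "r2star_closed_form"]


@dataclass
class R2StarMap:
    r2star: VolumeGrid  # 1/s
    s0: VolumeGrid  # a.u.
    reliability: VolumeGrid  # 1 where all echoes usable, 0 where excluded


def r2star_closed_form(magnitude: np.ndarray, echo_times_ms,
                       mask: np.ndarray | None = None,
                       voxel_size=None) -> R2StarMap:
    """Log-linear weighted least-squares R2* [1/s] and S0 from magnitudes.

    Voxels with any non-positive magnitude cannot enter the log fit; they are
    flagged 0 in the reliability map and get r2star = 0, s0 = 0.  Multiplying
    all magnitudes by c > 0 leaves r2star unchanged and scales s0 by c.
    """
    mag = np.asarray(magnitude, dtype=float)
    if mag.ndim != 4:
        raise ValueError("magnitude must be 4D (x, y, z, echo)")
    te = np.asarray(echo_times_ms, dtype=float) * 1e-3  # s
    if te.ndim != 1 or len(te) != mag.shape[3] or len(te) < 2:
        raise ValueError("need >= 2 echo times matching the echo dimension")
    if np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be strictly increasing")
    if np.any(mag < 0):
        raise ValueError("magnitudes must be non-negative")
    valid = np.all(mag > 0, axis=-1)
    if mask is not None:
        region = np.asarray(mask) > 0
    else:
        region = np.ones(mag.shape[:3], dtype=bool)
    usable = valid & region

    safe = np.where(mag > 0, mag, 1.0)
    logs = np.log(safe)
    w = mag**2
    t = te[None, None, None, :]
    wsum = np.where(usable[..., None], w, 1.0).sum(axis=-1)
    w = np.where(usable[..., None], w, 1.0)
    t_bar = (w * t).sum(axis=-1) / wsum
    l_bar = (w * logs).sum(axis=-1) / wsum
    t_c = t - t_bar[..., None]
    slope = (w * t_c * logs).sum(axis=-1) / (w * t_c**2).sum(axis=-1)
    intercept = l_bar - slope * t_bar
    r2s = np.where(usable, -slope, 0.0)
    s0 = np.where(usable, np.exp(intercept), 0.0)
    vs = voxel_size if voxel_size is not None else np.ones(3)
    return R2StarMap(
        r2star=VolumeGrid(r2s, voxel_size=vs),
        s0=VolumeGrid(s0, voxel_size=vs),
        reliability=VolumeGrid(usable.astype(float), voxel_size=vs),
    )
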