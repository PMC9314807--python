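"""Ground-truth phantom generator for multi-orientation susceptibility studies.

Emulates an excised, diamagnetic white-matter specimen with a cylindrically
symmetric susceptibility tensor embedded in a homogeneous agar reference
medium and scanned at ~10 rotations relative to B0.  The generative model
for the tissue field at orientation N (in ppb) is

    f_N = chi_i df_i,N + chi_a df_a,N                (susceptibility field)
        + M_specimen (A sin^2(theta_N) + B)          (compartmental offset)
        + C_N on the agar shell                      (per-orientation baseline)
        + background_N (+ noise)                     (external sources, noise)

computed with the package's own dipole forward chain, so every analysis
stage can be scored by parameter recovery.  The two experimental rotation
sets are built in: the 10-orientation specimen-session geometry
(angles to the reference axis [50, 60, 9, 66, 39, 0, 18, 31, 81, 88] deg, in
acquisition order) and the 10-orientation whole-brain-session geometry
(reference plus [12, 12, 36, 46, 61, 62, 75, 77, 78] deg).  Only the polar
angles to the reference are experimental; azimuths are not published and are
spread evenly over [0, 360) in acquisition order.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.ndimage as ndi

from .dipole import anisotropic_unit_responses, forward_field, ppb_to_hz
from .fieldmap import MultiEchoVolume
from .grids import B0Direction, FiberDirection, VolumeGrid
from .inversion import MultiOrientationStudy, OrientationSet
from .specimen import SpecimenModel, build_agar_shell_mask, fiber_b0_angle

__all__ = [
    "SPECIMEN_SESSION_ANGLES_DEG",
    "WHOLE_BRAIN_SESSION_ANGLES_DEG",
    "PhantomSpec",
    "GroundTruth",
    "make_orientation_set",
    "cylinder_mask",
    "sphere_mask",
    "smooth_random_map",
    "field_noise_sd_ppb",
    "simulate_study",
    "simulate_multiecho",
]

# rotation angles to the reference axis, in acquisition order, as registered
SPECIMEN_SESSION_ANGLES_DEG = (50.0, 60.0, 9.0, 66.0, 39.0, 0.0, 18.0, 31.0, 81.0, 88.0)
# whole-brain session: the reference orientation plus nine rotations
WHOLE_BRAIN_SESSION_ANGLES_DEG = (0.0, 12.0, 12.0, 36.0, 46.0, 61.0, 62.0, 75.0, 77.0, 78.0)

# specimen-session GRE echo times: TE1 2.05 ms, dTE 4.23 ms, 9 echoes
SPECIMEN_SESSION_TE_MS = tuple(2.05 + 4.23 * k for k in range(9))
# whole-brain session GRE echo times: TE1 3.45 ms, dTE 6.27 ms, 6 echoes
WHOLE_BRAIN_SESSION_TE_MS = tuple(3.45 + 6.27 * k for k in range(6))


def make_orientation_set(source: str = "specimen", n: int | None = None) -> OrientationSet:
    """B0 direction sets: the two experimental geometries or a Fibonacci set.

    ``"specimen"`` and ``"whole_brain"`` reproduce the registered polar
    angles of the two scanning sessions (azimuths spread evenly over
    [0, 360) in acquisition order; only the angle to the reference axis +z is
    experimental).  ``"fibonacci"`` returns ``n`` >= 3 near-uniform
    directions on the sphere for geometry experiments.
    """
    if source == "specimen":
        polar = np.asarray(SPECIMEN_SESSION_ANGLES_DEG)
    elif source == "whole_brain":
        polar = np.asarray(WHOLE_BRAIN_SESSION_ANGLES_DEG)
    elif source == "fibonacci":
        if n is None or n < 3:
            raise ValueError("fibonacci mode needs n >= 3")
        # hemisphere lattice: b0 and -b0 are equivalent for dipole physics,
        # so antipodal pairs would be redundant orientations
        golden = np.pi * (3.0 - np.sqrt(5.0))
        j = np.arange(n)
        z = (j + 0.5) / n
        r = np.sqrt(np.maximum(1.0 - z**2, 0.0))
        az = golden * j
        vecs = np.column_stack([r * np.cos(az), r * np.sin(az), z])
        angles = np.degrees(np.arccos(np.clip(np.abs(vecs[:, 2]), -1, 1)))
        return OrientationSet([B0Direction(v) for v in vecs], angles_deg=angles)
    else:
        raise ValueError(f"unknown orientation source {source!r}")
    m = len(polar)
    azimuth = np.radians(np.arange(m) * 360.0 / m)
    th = np.radians(polar)
    vecs = np.column_stack(
        [np.sin(th) * np.cos(azimuth), np.sin(th) * np.sin(azimuth), np.cos(th)]
    )
    return OrientationSet([B0Direction(v) for v in vecs], angles_deg=polar)


def cylinder_mask(grid_shape, center, axis, radius: float, length: float,
                  voxel_size=None) -> np.ndarray:
    """Binary mask of a finite cylinder (voxel units) around ``center``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    coords = np.indices(grid_shape).astype(float)
    rel = coords - np.asarray(center, dtype=float).reshape(3, 1, 1, 1)
    proj = sum(rel[i] * axis[i] for i in range(3))
    perp2 = sum((rel[i] - proj * axis[i]) ** 2 for i in range(3))
    return (np.abs(proj) <= length / 2.0) & (perp2 <= radius**2)


def sphere_mask(grid_shape, center, radius: float) -> np.ndarray:
    coords = np.indices(grid_shape).astype(float)
    rel = coords - np.asarray(center, dtype=float).reshape(3, 1, 1, 1)
    return (rel**2).sum(axis=0) <= radius**2


def smooth_random_map(grid_shape, sigma_voxels: float, rng, demean: bool = True) -> np.ndarray:
    """Gaussian-filtered white noise, unit RMS: a generic smooth test map."""
    x = rng.standard_normal(grid_shape)
    x = ndi.gaussian_filter(x, sigma_voxels, mode="wrap")
    if demean:
        x -= x.mean()
    rms = np.sqrt((x**2).mean())
    return x / rms if rms > 0 else x


def field_noise_sd_ppb(snr: float, echo_times_ms=SPECIMEN_SESSION_TE_MS,
                       b0_tesla: float = 3.0) -> float:
    """Field-map noise SD [ppb] implied by a per-echo magnitude SNR.

    Propagates the per-echo phase noise 1/SNR rad through the unweighted
    least-squares slope of phase vs time: sd(f) = (1/SNR) / (2 pi sd_t)
    with sd_t the root sum of squared centred echo times.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    t = np.asarray(echo_times_ms, dtype=float) * 1e-3
    spread = np.sqrt(np.sum((t - t.mean()) ** 2))
    sd_hz = (1.0 / snr) / (2.0 * np.pi * spread)
    return float(sd_hz / ppb_to_hz(1.0, b0_tesla=b0_tesla))


@dataclass
class PhantomSpec:
    """Parameters of the cylinder-in-agar phantom and its generative model.

    Defaults mirror the specimen-session conditions: 0.7 mm isotropic voxels
    on a 96^3 grid, a cylinder of radius 6 and length 40 voxels whose axis is
    the fiber direction, and generator susceptibilities/offsets equal to the
    white-matter means measured ex vivo (chi_i = 1.17 ppb, chi_a = 4.03 ppb,
    A = 1.46 ppb, B = -2.75 ppb).  Baselines C_N default to seeded draws of
    SD 2 ppb, the few-ppb scale of agar baseline offsets.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: tuple[float, float, float] = (0.7, 0.7, 0.7)
    geometry: str = "cylinder"  # or "box"
    center: tuple[float, float, float] | None = None
    fiber: tuple[float, float, float] = (0.0, 0.0, 1.0)
    radius_voxels: float = 6.0
    length_voxels: float = 40.0
    chi_i_ppb: float = 1.17
    chi_a_ppb: float = 4.03
    A_ppb: float = 1.46
    B_ppb: float = -2.75
    baselines_ppb: tuple | None = None  # C_N; None -> seeded N(0, 2 ppb)
    baseline_sd_ppb: float = 2.0
    background_sources: tuple = ()  # (center, radius_voxels, chi_ppb) triples
    noise_sd_ppb: float = 0.0
    inner_voxels: int = 1
    outer_voxels: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_voxels < 2:
            raise ValueError("cylinder radius must be >= 2 voxels")
        if self.noise_sd_ppb < 0:
            raise ValueError("noise_sd must be >= 0")
        shape = np.asarray(self.grid_shape)
        center = np.asarray(self.center if self.center is not None else (shape - 1) / 2.0)
        margin = self.outer_voxels + 2
        axis = np.asarray(self.fiber, dtype=float)
        axis = axis / np.linalg.norm(axis)
        # bounding extent of the cylinder along each axis
        half = np.abs(axis) * self.length_voxels / 2.0 + self.radius_voxels
        if np.any(center - half < margin) or np.any(center + half > shape - 1 - margin):
            raise ValueError(
                "specimen must stay >= outer_voxels + 2 voxels inside the grid"
            )


@dataclass
class GroundTruth:
    """Everything a recovery test needs: parameters, angles, clean fields."""

    spec: PhantomSpec
    theta_deg: np.ndarray
    baselines_ppb: np.ndarray
    noiseless_fields: list[np.ndarray]
    responses: list = dc_field(default=None)  # type: ignore[assignment]


def _specimen_geometry(spec: PhantomSpec):
    shape = tuple(spec.grid_shape)
    center = np.asarray(spec.center if spec.center is not None else (np.asarray(shape) - 1) / 2.0)
    if spec.geometry == "cylinder":
        mask = cylinder_mask(shape, center, spec.fiber, spec.radius_voxels, spec.length_voxels)
    elif spec.geometry == "box":
        half = np.array([spec.radius_voxels, spec.radius_voxels, spec.length_voxels / 2.0])
        coords = np.indices(shape).astype(float)
        rel = np.abs(coords - center.reshape(3, 1, 1, 1))
        mask = np.all(rel <= half.reshape(3, 1, 1, 1), axis=0)
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")
    return mask


def simulate_study(
    spec: PhantomSpec,
    orientations: OrientationSet | None = None,
    keep_responses: bool = False,
):
    """Generate a multi-orientation study from a phantom specification.

    Returns ``(study, model, truth)``: the study bundles per-orientation
    tissue fields [ppb] and the union analysis mask; the model carries the
    specimen mask, fiber axis and the derived agar shell; the ground truth
    echoes every generator parameter plus the noiseless fields.  The same
    seed reproduces the fields bit-identically.
    """
    if orientations is None:
        orientations = make_orientation_set("specimen")
    rng = np.random.default_rng(spec.seed)
    vs = np.asarray(spec.voxel_size_mm, dtype=float)
    mask_arr = _specimen_geometry(spec)
    specimen_mask = VolumeGrid(mask_arr.astype(float), voxel_size=vs)
    fiber = FiberDirection(spec.fiber)
    agar_mask = build_agar_shell_mask(specimen_mask, spec.inner_voxels, spec.outer_voxels)
    model = SpecimenModel(specimen_mask=specimen_mask, fiber=fiber, agar_mask=agar_mask)

    n = len(orientations)
    if spec.baselines_ppb is not None:
        baselines = np.asarray(spec.baselines_ppb, dtype=float)
        if len(baselines) != n:
            raise ValueError("need one baseline C_N per orientation")
    else:
        baselines = rng.normal(0.0, spec.baseline_sd_ppb, size=n)
    theta = np.array([fiber_b0_angle(fiber, b0) for b0 in orientations])

    # background sources are anti-aliased (1-voxel Gaussian): the band-limited
    # field of a hard-edged voxel source carries Nyquist ringing that is not
    # harmonic inside the mask and would defeat harmonic background removal
    backgrounds = []
    for b0 in orientations:
        bg = np.zeros(mask_arr.shape)
        for center, radius, chi in spec.background_sources:
            src = sphere_mask(mask_arr.shape, center, radius).astype(float) * chi
            src = ndi.gaussian_filter(src, 1.0)
            bg += forward_field(VolumeGrid(src, voxel_size=vs), b0).data
        backgrounds.append(bg)

    agar_arr = agar_mask.data > 0
    fields, clean, responses = [], [], []
    for j, b0 in enumerate(orientations):
        resp = anisotropic_unit_responses(specimen_mask, fiber, b0)
        f = spec.chi_i_ppb * resp.delta_f_i.data + spec.chi_a_ppb * resp.delta_f_a.data
        f = f + mask_arr * (spec.A_ppb * np.sin(np.radians(theta[j])) ** 2 + spec.B_ppb)
        f = f + baselines[j] * agar_arr
        f = f + backgrounds[j]
        clean.append(f.copy())
        if spec.noise_sd_ppb > 0:
            f = f + rng.normal(0.0, spec.noise_sd_ppb, size=f.shape)
        fields.append(VolumeGrid(f, voxel_size=vs))
        if keep_responses:
            responses.append(resp)

    # solid analysis mask: specimen + the 1-voxel partial-volume ring + shell
    # (the ring is excluded from the agar fit but is still imaged agar)
    solid = ndi.binary_dilation(mask_arr, ndi.generate_binary_structure(3, 1),
                                iterations=spec.outer_voxels)
    union = VolumeGrid((solid | mask_arr).astype(float), voxel_size=vs)
    study = MultiOrientationStudy(fields=fields, b0s=orientations, mask=union)
    truth = GroundTruth(
        spec=spec,
        theta_deg=theta,
        baselines_ppb=baselines,
        noiseless_fields=clean,
        responses=responses if keep_responses else None,
    )
    return study, model, truth


def simulate_multiecho(
    field_hz: VolumeGrid,
    echo_times_ms=SPECIMEN_SESSION_TE_MS,
    snr: float = np.inf,
    s0: float = 100.0,
    r2star_s: float = 20.0,
    phi0: float = 0.0,
    seed: int = 0,
) -> MultiEchoVolume:
    """Complex multi-echo GRE signal for a given off-resonance field [Hz].

    S(TE) = s0 exp(-R2* TE) exp(i (phi0 + 2 pi f TE)) plus complex Gaussian
    noise of SD s0/snr per channel; phase is wrapped to (-pi, pi].
    """
    if not (snr > 0):
        raise ValueError("snr must be positive")
    te = np.asarray(echo_times_ms, dtype=float) * 1e-3
    f = np.asarray(field_hz.data, dtype=float)[..., None]
    decay = s0 * np.exp(-r2star_s * te)[None, None, None, :]
    signal = decay * np.exp(1j * (phi0 + 2.0 * np.pi * f * te))
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sd = s0 / snr
        signal = signal + sd * (
            rng.standard_normal(signal.shape) + 1j * rng.standard_normal(signal.shape)
        )
    phase = np.angle(signal)
    # np.angle returns (-pi, pi]; keep the convention explicit
    return MultiEchoVolume(
        magnitude=np.abs(signal),
        phase=phase,
        echo_times_ms=np.asarray(echo_times_ms, dtype=float),
        voxel_size=field_hz.voxel_size,
    )
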