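"""Configuration-driven pipelines with validation and a run manifest.

A pipeline config (YAML or dict) names an ordered list of stages with
per-stage parameter blocks:

.. code-block:: yaml

    seed: 0
    stages:
      - stage: simulate
        out_dir: scratch/sim
        params: {grid_shape: [48, 48, 48], radius_voxels: 4}
      - stage: specimen_fit
        sim_dir: scratch/sim
        out_csv: results/specimen_fit.csv

Unknown keys are rejected at validation time with every offending key named;
referenced input files must exist.  ``run_pipeline`` executes the stages in
order, never mutates inputs on disk, and writes a JSON manifest (input
checksums, parameters, package version) next to the outputs so a run can be
reproduced exactly: the same config and seed give byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import compare_estimates
from .fieldmap import combine_echoes, remove_background_field, MultiEchoVolume
from .grids import FiberDirection, VolumeGrid
from .inversion import cosmos, quasar
from .io import (
    load_study,
    read_echo_times,
    read_orientations,
    write_echo_times,
    write_orientations,
)
from .relaxometry import r2star_closed_form
from .specimen import (
    SpecimenModel,
    build_agar_shell_mask,
    fit_external_field,
    fit_residual_sin2,
    fit_sin2,
    residual_internal_field,
)
from .synthetic import PhantomSpec, make_orientation_set, simulate_study

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "specimen_fit_table"]


class ConfigError(ValueError):
    """Config validation failure; message lists every offending key/path."""


_STAGE_KEYS: dict[str, set[str]] = {
    "simulate": {"stage", "out_dir", "orientation_source", "params"},
    "fieldmap": {"stage", "magnitude", "phase", "echo_times", "mask", "out_field",
                 "out_reliability"},
    "bgremove": {"stage", "field", "mask", "out_field", "tol", "maxiter"},
    "cosmos": {"stage", "fields", "b0s", "mask", "out_prefix", "tau", "pad"},
    "quasar": {"stage", "fields", "b0s", "mask", "out_prefix", "pad"},
    "specimen_fit": {"stage", "sim_dir", "fields", "b0s", "mask", "specimen_mask",
                     "fiber", "inner", "outer", "specimen_id", "out_csv"},
    "r2star": {"stage", "magnitude", "echo_times", "mask", "out_r2star", "out_s0"},
    "compare": {"stage", "csv", "x_column", "y_column", "out_json"},
}

_PATH_KEYS = {"magnitude", "phase", "echo_times", "mask", "field", "b0s",
              "specimen_mask", "csv"}

_SIM_PARAM_KEYS = {f.name for f in PhantomSpec.__dataclass_fields__.values()}


@dataclass
class PipelineConfig:
    seed: int
    stages: list[dict]
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load and validate a YAML config; relative paths resolve against
        the current working directory (not the config file's location)."""
        payload = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(payload, base_dir=Path.cwd())

    @classmethod
    def from_dict(cls, payload: dict, base_dir: Path | None = None) -> "PipelineConfig":
        errors: list[str] = []
        if not isinstance(payload, dict):
            raise ConfigError("config must be a mapping")
        unknown_top = set(payload) - {"seed", "stages", "verbosity"}
        if unknown_top:
            errors.append(f"unknown top-level keys: {sorted(unknown_top)}")
        stages = payload.get("stages")
        if not isinstance(stages, list) or not stages:
            errors.append("config needs a non-empty 'stages' list")
            stages = []
        base = base_dir or Path(".")
        resolved: list[dict] = []
        for i, stage in enumerate(stages):
            if not isinstance(stage, dict) or "stage" not in stage:
                errors.append(f"stage #{i}: every stage needs a 'stage' name")
                continue
            name = stage["stage"]
            if name not in _STAGE_KEYS:
                errors.append(f"stage #{i}: unknown stage {name!r}")
                continue
            unknown = set(stage) - _STAGE_KEYS[name]
            if unknown:
                errors.append(f"stage #{i} ({name}): unknown keys {sorted(unknown)}")
            if name == "simulate":
                bad = set(stage.get("params", {}) or {}) - _SIM_PARAM_KEYS
                if bad:
                    errors.append(f"stage #{i} (simulate): unknown params {sorted(bad)}")
            stage = dict(stage)
            for key, value in list(stage.items()):
                if key in _PATH_KEYS and isinstance(value, str):
                    p = base / value
                    stage[key] = str(p)
                    if not p.exists():
                        errors.append(f"stage #{i} ({name}): missing input file "
                                      f"{key}={p}")
                if key == "fields" and isinstance(value, list):
                    paths = [base / v for v in value]
                    stage[key] = [str(p) for p in paths]
                    for p in paths:
                        if not p.exists():
                            errors.append(f"stage #{i} ({name}): missing field file {p}")
            for key in ("out_dir", "out_field", "out_reliability", "out_prefix",
                        "out_csv", "out_json", "out_r2star", "out_s0", "sim_dir"):
                if key in stage and isinstance(stage[key], str):
                    stage[key] = str(base / stage[key])
            resolved.append(stage)
        if errors:
            raise ConfigError("invalid pipeline config:\n  " + "\n  ".join(errors))
        return cls(seed=int(payload.get("seed", 0)), stages=resolved,
                   verbosity=int(payload.get("verbosity", 1)))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def specimen_fit_table(study, model, specimen_id: str = "specimen",
                       responses=None) -> pd.DataFrame:
    """External-field fit + sin^2 residual fit as a one-row results table."""
    if responses is None:
        from .specimen import compute_unit_responses

        responses = compute_unit_responses(model, study.b0s)
    fit = fit_external_field(study, model, responses=responses)
    f_r = residual_internal_field(study, model, fit, responses=responses)
    # propagated (GLS) confidence intervals need a non-degenerate noise
    # estimate; noiseless data falls back to the ordinary fit
    if np.isfinite(fit.sigma2) and fit.sigma2 > 1e-12:
        s2 = fit_residual_sin2(fit, f_r, model, responses)
    else:
        s2 = fit_sin2(fit.theta_deg, f_r)
    return pd.DataFrame(
        [{
            "specimen_id": specimen_id,
            "chi_i_ppb": fit.chi_i,
            "chi_i_se": fit.chi_i_se,
            "chi_a_ppb": fit.chi_a,
            "chi_a_se": fit.chi_a_se,
            "A_ppb": s2.A,
            "A_ci_lo": s2.A_ci[0],
            "A_ci_hi": s2.A_ci[1],
            "B_ppb": s2.B,
            "B_ci_lo": s2.B_ci[0],
            "B_ci_hi": s2.B_ci[1],
            "r2_external": fit.r2,
            "r2_sin2": s2.r2,
            "n_orientations": fit.n_orientations,
        }]
    )


def _run_simulate(stage: dict, seed: int, manifest: dict) -> None:
    params = dict(stage.get("params", {}) or {})
    params.setdefault("seed", seed)
    for key in ("grid_shape", "voxel_size_mm", "fiber", "center", "baselines_ppb"):
        if key in params and isinstance(params[key], list):
            params[key] = tuple(params[key])
    spec = PhantomSpec(**params)
    orientations = make_orientation_set(stage.get("orientation_source", "specimen"))
    study, model, truth = simulate_study(spec, orientations)
    out = Path(stage["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    for j, f in enumerate(study.fields):
        f.to_nifti(out / f"field_{j:02d}.nii")
    model.specimen_mask.to_nifti(out / "specimen_mask.nii")
    model.agar_mask.to_nifti(out / "agar_mask.nii")
    study.mask.to_nifti(out / "analysis_mask.nii")
    write_orientations(out / "orientations.json", orientations)
    gt = {
        "chi_i_ppb": spec.chi_i_ppb, "chi_a_ppb": spec.chi_a_ppb,
        "A_ppb": spec.A_ppb, "B_ppb": spec.B_ppb,
        "baselines_ppb": [float(c) for c in truth.baselines_ppb],
        "theta_deg": [float(t) for t in truth.theta_deg],
        "fiber": [float(v) for v in model.fiber.vector],
        "noise_sd_ppb": spec.noise_sd_ppb, "seed": spec.seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=2) + "\n")
    manifest["outputs"].append(str(out))


def _run_specimen_fit(stage: dict, manifest: dict) -> None:
    if "sim_dir" in stage:
        sim = Path(stage["sim_dir"])
        field_paths = sorted(sim.glob("field_*.nii"))
        study = load_study(field_paths, sim / "orientations.json", sim / "analysis_mask.nii")
        specimen_mask = VolumeGrid.from_nifti(sim / "specimen_mask.nii")
        fiber = FiberDirection(json.loads((sim / "ground_truth.json").read_text())["fiber"])
    else:
        study = load_study(stage["fields"], stage["b0s"], stage["mask"])
        specimen_mask = VolumeGrid.from_nifti(stage["specimen_mask"])
        fiber = FiberDirection(np.asarray(stage["fiber"], dtype=float))
    agar = build_agar_shell_mask(specimen_mask, stage.get("inner", 1), stage.get("outer", 5))
    model = SpecimenModel(specimen_mask=specimen_mask, fiber=fiber, agar_mask=agar)
    table = specimen_fit_table(study, model, stage.get("specimen_id", "specimen"))
    out_csv = Path(stage["out_csv"])
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_csv, index=False)
    manifest["outputs"].append(str(out_csv))


def _run_fieldmap(stage: dict, manifest: dict) -> None:
    import nibabel as nib

    mag_img = nib.load(stage["magnitude"])
    phase_img = nib.load(stage["phase"])
    te = read_echo_times(stage["echo_times"])
    data = MultiEchoVolume(
        magnitude=np.asanyarray(mag_img.dataobj),
        phase=np.asanyarray(phase_img.dataobj),
        echo_times_ms=te,
        voxel_size=np.asarray(mag_img.header.get_zooms()[:3]),
    )
    mask = VolumeGrid.from_nifti(stage["mask"]).data if "mask" in stage else None
    total, reliability = combine_echoes(data, mask=mask)
    total.to_nifti(stage["out_field"])
    manifest["outputs"].append(stage["out_field"])
    if "out_reliability" in stage:
        reliability.to_nifti(stage["out_reliability"])
        manifest["outputs"].append(stage["out_reliability"])


def _run_bgremove(stage: dict, manifest: dict) -> None:
    field = VolumeGrid.from_nifti(stage["field"])
    mask = VolumeGrid.from_nifti(stage["mask"])
    tissue = remove_background_field(field, mask, tol=stage.get("tol", 1e-6),
                                     maxiter=stage.get("maxiter", 2000))
    tissue.to_nifti(stage["out_field"])
    manifest["outputs"].append(stage["out_field"])


def _run_inversion(stage: dict, manifest: dict, kind: str) -> None:
    study = load_study(stage["fields"], stage["b0s"], stage["mask"])
    prefix = Path(stage["out_prefix"])
    prefix.parent.mkdir(parents=True, exist_ok=True)
    diagnostics: dict = {"method": kind, "n_orientations": study.n_orientations}
    if kind == "cosmos":
        result = cosmos(study, tau=stage.get("tau", 0.01), pad=stage.get("pad", 1))
        result.chi.to_nifti(f"{prefix}_chi.nii")
        result.residual_mean.to_nifti(f"{prefix}_residual_mean.nii")
        result.residual_sd.to_nifti(f"{prefix}_residual_sd.nii")
        diagnostics["well_conditioned_fraction"] = float(result.well_conditioned.mean())
    else:
        result = quasar(study, pad=stage.get("pad", 1))
        result.chi.to_nifti(f"{prefix}_chi.nii")
        result.f_rho.to_nifti(f"{prefix}_f_rho.nii")
        diagnostics["fit_residual_rms_ppb"] = result.fit_residual_rms
    diag_path = f"{prefix}_diagnostics.json"
    Path(diag_path).write_text(json.dumps(diagnostics, indent=2) + "\n")
    manifest["outputs"].extend([f"{prefix}_chi.nii", diag_path])


def _run_r2star(stage: dict, manifest: dict) -> None:
    import nibabel as nib

    mag_img = nib.load(stage["magnitude"])
    te = read_echo_times(stage["echo_times"])
    mask = VolumeGrid.from_nifti(stage["mask"]).data if "mask" in stage else None
    result = r2star_closed_form(np.asanyarray(mag_img.dataobj), te, mask=mask,
                                voxel_size=np.asarray(mag_img.header.get_zooms()[:3]))
    result.r2star.to_nifti(stage["out_r2star"])
    manifest["outputs"].append(stage["out_r2star"])
    if "out_s0" in stage:
        result.s0.to_nifti(stage["out_s0"])
        manifest["outputs"].append(stage["out_s0"])


def _run_compare(stage: dict, manifest: dict) -> None:
    table = pd.read_csv(stage["csv"])
    x = table[stage.get("x_column", "x")].to_numpy()
    y = table[stage.get("y_column", "y")].to_numpy()
    result = compare_estimates(x, y)
    out = Path(stage["out_json"])
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(result.to_dict(), indent=2) + "\n")
    manifest["outputs"].append(str(out))


def run_pipeline(config: PipelineConfig, manifest_path: str | Path | None = None) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    manifest: dict = {
        "oriqsm_version": __version__,
        "seed": config.seed,
        "stages": [],
        "inputs": {},
        "outputs": [],
    }
    for stage in config.stages:
        for key, value in stage.items():
            paths = value if isinstance(value, list) else [value]
            for p in paths:
                if key in _PATH_KEYS | {"fields"} and isinstance(p, str) and Path(p).is_file():
                    manifest["inputs"][p] = _sha256(Path(p))
        name = stage["stage"]
        manifest["stages"].append({k: v for k, v in stage.items()})
        if name == "simulate":
            _run_simulate(stage, config.seed, manifest)
        elif name == "specimen_fit":
            _run_specimen_fit(stage, manifest)
        elif name == "fieldmap":
            _run_fieldmap(stage, manifest)
        elif name == "bgremove":
            _run_bgremove(stage, manifest)
        elif name in ("cosmos", "quasar"):
            _run_inversion(stage, manifest, name)
        elif name == "r2star":
            _run_r2star(stage, manifest)
        elif name == "compare":
            _run_compare(stage, manifest)
    if manifest_path is not None:
        Path(manifest_path).parent.mkdir(parents=True, exist_ok=True)
        Path(manifest_path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
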