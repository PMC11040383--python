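"""Reading and writing run artifacts: TIFF stacks, CSV tables, YAML configs.

Scenes and run configurations round-trip through YAML; complex numbers are
stored as two-element ``[re, im]`` lists.  Image stacks go through
:mod:`tifffile`; complex maps are written as paired real/imaginary
floating-point TIFF pages.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .pipeline import RunParams, RunResult
from .synthetic import CellSpec, SceneSpec, SimulatedExperiment

__all__ = [
    "scene_to_yaml",
    "scene_from_yaml",
    "export_waveform",
    "write_simulation",
    "load_run_config",
    "write_run_outputs",
]


def _encode(value):
    if isinstance(value, (complex, np.complexfloating)):
        return [float(value.real), float(value.imag)]
    if isinstance(value, tuple):
        return [_encode(v) for v in value]
    if isinstance(value, np.generic):
        return value.item()
    return value


def _decode_complex(value):
    if isinstance(value, (list, tuple)) and len(value) == 2:
        return complex(value[0], value[1])
    return complex(value)


def scene_to_yaml(scene: SceneSpec, path: str | Path) -> None:
    data = {k: _encode(v) for k, v in asdict(scene).items() if k != "cells"}
    data["cells"] = [{k: _encode(v) for k, v in asdict(c).items()} for c in scene.cells]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def scene_from_yaml(path: str | Path) -> SceneSpec:
    data = yaml.safe_load(Path(path).read_text())
    cells = []
    for c in data.pop("cells", []):
        c["center"] = tuple(c["center"])
        c["modulus"] = _decode_complex(c["modulus"])
        cells.append(CellSpec(**c))
    for key in ("shape", "fluo_offset_px"):
        if key in data:
            data[key] = tuple(data[key])
    if "flow_velocity" in data:
        data["flow_velocity"] = tuple(_decode_complex(v) for v in data["flow_velocity"])
    if "flow_ramp" in data:
        data["flow_ramp"] = tuple(data["flow_ramp"])
    return SceneSpec(cells=tuple(cells), **data)


def export_waveform(config, path: str | Path, n_periods: int = 1) -> None:
    """Drive waveform as a (t, value) CSV sampled at the drive rate."""
    from .signals import synth_pulse

    t = np.arange(0, n_periods / config.f_repet, 1.0 / config.drive_sampling)
    pd.DataFrame({"t": t, "value": synth_pulse(config, t)}).to_csv(path, index=False)


def write_complex_tiff(field: np.ndarray, path: str | Path) -> None:
    """Complex map as a two-page float32 TIFF (real, imaginary)."""
    tifffile.imwrite(
        path, np.stack([field.real, field.imag]).astype(np.float32), photometric="minisblack"
    )


def write_simulation(sim: SimulatedExperiment, outdir: str | Path) -> Path:
    """Write a rendered synthetic experiment plus a run manifest.

    The manifest (``run.yaml``) is directly consumable by the ``run`` CLI
    command and by :func:`load_run_config`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "strobe.tif", sim.strobe_stack)
    manifest: dict = {
        "paths": {"strobe": "strobe.tif"},
        "acquisition": {
            "f0_hz": sim.config.f0,
            "alpha_hz": sim.config.alpha,
            "n_pulses": sim.config.n_pulses,
            "f_repet_hz": sim.config.f_repet,
            "n_frames": sim.config.n_frames,
            "pixel_pitch_um": sim.scene.pixel_pitch_um,
            "fluo_pixel_pitch_um": sim.scene.fluo_pixel_pitch_um,
            "affine": [float(v) for v in np.asarray(sim.affine).ravel()],
        },
        "physics": {
            "viscosity_pa_s": sim.scene.viscosity_pa_s,
            "bead_radius_um": sim.scene.bead_radius_um,
        },
        "seed": sim.scene.seed,
    }
    if sim.bead_stack is not None:
        tifffile.imwrite(outdir / "beads.tif", sim.bead_stack)
        manifest["paths"]["beads"] = "beads.tif"
    fluo_paths = {}
    for channel, stack in sim.fluorescence.items():
        name = f"fluo_{channel}.tif"
        tifffile.imwrite(outdir / name, stack)
        fluo_paths[channel] = name
    if fluo_paths:
        manifest["paths"]["fluorescence"] = fluo_paths
    tifffile.imwrite(outdir / "instance_labels.tif", sim.labels.astype(np.int32))
    manifest["paths"]["instance_labels"] = "instance_labels.tif"
    write_complex_tiff(sim.delta_field[0], outdir / "truth_delta_x.tif")
    write_complex_tiff(sim.delta_field[1], outdir / "truth_delta_y.tif")
    sim.bead_tracks.to_csv(outdir / "truth_bead_tracks.csv", index=False)
    scene_to_yaml(sim.scene, outdir / "scene.yaml")
    (outdir / "run.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return outdir / "run.yaml"


def load_run_config(path: str | Path):
    """Load a run manifest: returns (arrays dict, RunParams, affine, seed)."""
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    base = path.parent
    paths = cfg["paths"]
    arrays: dict = {"strobe": tifffile.imread(base / paths["strobe"])}
    arrays["beads"] = tifffile.imread(base / paths["beads"]) if "beads" in paths else None
    arrays["fluorescence"] = (
        {ch: tifffile.imread(base / p) for ch, p in paths["fluorescence"].items()}
        if "fluorescence" in paths
        else None
    )
    arrays["instance_labels"] = (
        tifffile.imread(base / paths["instance_labels"])
        if "instance_labels" in paths
        else None
    )
    acq = cfg["acquisition"]
    phys = cfg.get("physics", {})
    analysis = cfg.get("analysis", {})
    params = RunParams(
        f0=acq["f0_hz"],
        alpha=acq["alpha_hz"],
        n_pulses=acq["n_pulses"],
        f_repet=acq["f_repet_hz"],
        n_frames=acq.get("n_frames"),
        pixel_pitch_um=acq.get("pixel_pitch_um", 0.514),
        fluo_pixel_pitch_um=acq.get("fluo_pixel_pitch_um", 0.3),
        viscosity_pa_s=phys.get("viscosity_pa_s", 1.0e-3),
        bead_radius_um=phys.get("bead_radius_um", 1.5),
        **analysis,
    )
    affine = np.asarray(acq.get("affine", [1, 0, 0, 0, 1, 0]), dtype=float).reshape(2, 3)
    return arrays, params, affine, cfg.get("seed")


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_run_outputs(result: RunResult, outdir: str | Path) -> None:
    """Write the box table, report and modulus maps of a finished run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = ["report.json", "boxes.csv"]
    result.table.to_csv(outdir / "boxes.csv", index=False)
    if result.moduli is not None:
        from .mechanics import modulus_ratio_map

        tifffile.imwrite(
            outdir / "modulus_abs.tif", result.moduli.amplitude.astype(np.float32)
        )
        tifffile.imwrite(
            outdir / "modulus_storage.tif", result.moduli.storage.astype(np.float32)
        )
        tifffile.imwrite(outdir / "modulus_loss.tif", result.moduli.loss.astype(np.float32))
        tifffile.imwrite(
            outdir / "modulus_log_ratio.tif",
            modulus_ratio_map(result.moduli).astype(np.float32),
        )
        files += [
            "modulus_abs.tif",
            "modulus_storage.tif",
            "modulus_loss.tif",
            "modulus_log_ratio.tif",
        ]
    if result.displacement is not None:
        amp = result.displacement.amplitude.astype(np.float32)
        tifffile.imwrite(outdir / "displacement_amplitude.tif", amp)
        files.append("displacement_amplitude.tif")
    if result.tracks is not None:
        result.tracks.table.to_csv(outdir / "tracks.csv", index=False)
        files.append("tracks.csv")
    if result.stress is not None and result.flow is not None:
        write_complex_tiff(result.stress.sigma_x.astype(complex), outdir / "stress_x.tif")
        write_complex_tiff(result.stress.sigma_y.astype(complex), outdir / "stress_y.tif")
        meta = {
            "mu_pa_s": result.stress.mu,
            "bead_radius_m": result.stress.bead_radius_m,
            "f0_hz": result.flow.f0,
            "n_grid": int(result.flow.n_grid),
        }
        (outdir / "stress_meta.json").write_text(json.dumps(meta, indent=2))
        files += ["stress_x.tif", "stress_y.tif", "stress_meta.json"]
    report = dict(result.report)
    report["files"] = files
    (outdir / "report.json").write_text(json.dumps(_to_jsonable(report), indent=2))
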