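"""End-to-end orchestration: images in, modulus maps and statistics out.

Stage order mirrors the measurement chain: rest-reference construction,
bead tracking and homodyne stress estimation, DIC and homodyne displacement
maps, strain differentiation, modulus inversion, fluorescence segmentation
and box labelling, population statistics, and the error budget.  Mandatory
stage failures raise :class:`PipelineError` with a stage-specific code;
optional stages (e.g. no blank area large enough) are recorded as skipped in
the report.  Given identical inputs the pipeline is fully deterministic.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import dic as _dic
from . import mechanics, segmentation, stats, tracking
from .signals import PulseTrainConfig, strobe_schedule
from .synthetic import SimulatedExperiment

__all__ = ["RunParams", "RunResult", "PipelineError", "run_pipeline", "analyze_experiment"]


class PipelineError(RuntimeError):
    """A mandatory pipeline stage failed; ``code`` identifies the stage."""

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


@dataclass
class RunParams:
    """Every knob the analysis chain needs, with experiment-scale defaults."""

    f0: float = 30e3  # carrier frequency, Hz
    alpha: float = 10e3  # Gaussian envelope rate, Hz
    n_pulses: int = 1000
    f_repet: float = 1000.0
    n_frames: int | None = None  # acquired frames, default 3N/2
    pixel_pitch_um: float = 0.514  # fast camera
    fluo_pixel_pitch_um: float = 0.3
    viscosity_pa_s: float = 1.0e-3
    bead_radius_um: float = 1.5
    box_size: int = 5
    search_radius: int = 4  # px; displacements here are sub-px to few px
    min_contrast: float = 0.2
    stress_threshold: float = 0.1
    min_beads_per_subfov: int = 5
    n_grid: int | None = None  # force the sub-FOV grid order (None: auto)
    blank_margin_um: float = 15.0  # min distance from any mask for blank boxes
    depth_of_field_um: float = 0.87
    min_group_size: int = 20

    def pulse_config(self) -> PulseTrainConfig:
        return PulseTrainConfig(
            f0=self.f0,
            alpha=self.alpha,
            n_pulses=self.n_pulses,
            f_repet=self.f_repet,
            n_frames=self.n_frames,
        )


@dataclass
class RunResult:
    """Everything a run produces, plus the JSON-serializable report."""

    report: dict
    table: pd.DataFrame
    moduli: mechanics.ModulusMaps | None = None
    strains: mechanics.StrainMaps | None = None
    displacement: _dic.HomodyneDisplacementMap | None = None
    flow: tracking.HomodyneFlowField | None = None
    stress: tracking.StressField | None = None
    masks: segmentation.ChannelMasks | None = None
    blank_boxes: np.ndarray | None = None
    tracks: tracking.TrackSet | None = None


def _sample_at_boxes(field: np.ndarray, centers_x: np.ndarray, centers_y: np.ndarray):
    xi = np.clip(np.round(centers_x).astype(int), 0, field.shape[1] - 1)
    yi = np.clip(np.round(centers_y).astype(int), 0, field.shape[0] - 1)
    return field[np.ix_(yi, xi)]


def run_pipeline(
    strobe_stack: np.ndarray,
    params: RunParams,
    *,
    bead_stack: np.ndarray | None = None,
    fluorescence: dict[str, np.ndarray] | None = None,
    affine: np.ndarray | None = None,
    instance_labels: np.ndarray | None = None,
    seed: int | None = None,
) -> RunResult:
    """Run the full analysis chain on one experiment.

    ``bead_stack`` defaults to the strobe stack itself (tracers imaged in the
    same field of view); ``fluorescence`` maps channel names to image stacks
    on the fluorescence grid related to the fast camera by ``affine`` (2x3,
    fast (x, y) px -> fluorescence (x, y) px; identity when omitted).
    Without fluorescence the run stops after the modulus maps and statistics
    are marked skipped.
    """
    t_start = time.perf_counter()
    stages: list[dict] = []
    report: dict = {
        "schema_version": 1,
        "seed": seed,
        "params": asdict(params),
        "stages": stages,
    }

    def _stage(name: str, status: str, t0: float, **info):
        stages.append(
            {"name": name, "status": status, "seconds": round(time.perf_counter() - t0, 3), **info}
        )

    config = params.pulse_config()
    schedule = strobe_schedule(config)
    if strobe_stack.shape[0] < config.n_frames:
        raise PipelineError(
            "input", f"need {config.n_frames} frames, stack has {strobe_stack.shape[0]}"
        )
    if affine is None:
        affine = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])

    # --- reference image -------------------------------------------------
    t0 = time.perf_counter()
    reference = _dic.reference_image(strobe_stack[: config.n_frames], params.n_pulses)
    _stage("reference_image", "ok", t0, n_rest_frames=int(config.n_frames - params.n_pulses))

    # --- bead tracking and stress ----------------------------------------
    t0 = time.perf_counter()
    beads = bead_stack if bead_stack is not None else strobe_stack
    try:
        tracks = tracking.track_stack(
            beads[: params.n_pulses], radius_px=params.bead_radius_um / params.pixel_pitch_um
        )
        flow = tracking.homodyne_flow(
            tracks,
            schedule,
            params.f0,
            image_shape=strobe_stack.shape[1:],
            pixel_pitch_um=params.pixel_pitch_um,
            min_per_cell=params.min_beads_per_subfov,
            n_grid=params.n_grid,
        )
    except ValueError as exc:
        raise PipelineError("tracking", str(exc)) from exc
    stress = tracking.stress_field(flow, params.viscosity_pa_s, params.bead_radius_um * 1e-6)
    rel_flow_error, track_residuals = tracking.flow_residuals(tracks, flow, schedule)
    _stage(
        "bead_tracking",
        "ok",
        t0,
        n_tracks=int(tracks.ids.size),
        n_complete=int(tracks.complete_ids.size),
        n_grid=int(flow.n_grid),
        rel_flow_error=float(rel_flow_error),
    )

    # --- DIC and homodyne displacement -----------------------------------
    t0 = time.perf_counter()
    dstack = _dic.dic_displacements(
        strobe_stack[: params.n_pulses],
        reference,
        box_size=params.box_size,
        search_radius=params.search_radius,
        min_contrast=params.min_contrast,
    )
    disp = _dic.homodyne_displacement(
        dstack, schedule, params.f0, pixel_pitch_um=params.pixel_pitch_um
    )
    if not disp.valid.any():
        raise PipelineError("dic", "no valid DIC boxes (image may lack texture)")
    _stage("dic", "ok", t0, n_valid_boxes=int(disp.valid.sum()))

    # --- strains and moduli ----------------------------------------------
    t0 = time.perf_counter()
    spacing_um = params.box_size * params.pixel_pitch_um
    strains = mechanics.shear_strains(disp, spacing_um)
    sigma_x = _sample_at_boxes(stress.sigma_x, disp.box_centers_x, disp.box_centers_y)
    sigma_y = _sample_at_boxes(stress.sigma_y, disp.box_centers_x, disp.box_centers_y)
    moduli = mechanics.shear_moduli(
        strains, sigma_x, sigma_y, stress_threshold=params.stress_threshold
    )
    if not moduli.valid.any():
        raise PipelineError("mechanics", "no valid modulus boxes")
    _stage("mechanics", "ok", t0, n_valid_boxes=int(moduli.valid.sum()))

    # --- segmentation ------------------------------------------------------
    masks = None
    edge_maps = None
    if fluorescence:
        t0 = time.perf_counter()
        raw_masks = {ch: segmentation.segment_channel(stk) for ch, stk in fluorescence.items()}
        if len(raw_masks) >= 2:
            masks = segmentation.remove_overlaps(raw_masks)
        else:
            only = next(iter(raw_masks))
            masks = segmentation.ChannelMasks(
                masks={only: raw_masks[only]},
                overlap_removed=np.zeros_like(raw_masks[only]),
                overlap_fraction=0.0,
            )
        edge_maps = {}
        for ch, m in masks.masks.items():
            if m.any():
                edge_maps[ch] = segmentation.distance_to_edge(m, params.fluo_pixel_pitch_um)
        _stage(
            "segmentation",
            "ok",
            t0,
            overlap_fraction=float(masks.overlap_fraction),
            mask_areas={ch: int(m.sum()) for ch, m in masks.masks.items()},
        )

    # --- box table and statistics ----------------------------------------
    table = pd.DataFrame()
    statistics: dict = {}
    blank_boxes = None
    rel_strain_error = None
    if masks is not None:
        t0 = time.perf_counter()
        table = stats.build_box_table(
            moduli,
            disp.box_centers_x,
            disp.box_centers_y,
            params.box_size,
            affine,
            masks.masks,
            edge_maps,
            fluo_pixel_pitch_um=params.fluo_pixel_pitch_um,
            instance_labels=instance_labels,
        )
        statistics = stats.population_stats(table, min_group_size=params.min_group_size)
        _stage("statistics", "ok", t0, n_boxes=int(len(table)))

        # blank-area strain noise: boxes far from every mask
        t0 = time.perf_counter()
        union = np.zeros(next(iter(masks.masks.values())).shape, dtype=bool)
        for m in masks.masks.values():
            union |= m
        dist_px = ndimage.distance_transform_edt(~union)
        margin_px = params.blank_margin_um / params.fluo_pixel_pitch_um
        cx, cy = np.meshgrid(disp.box_centers_x, disp.box_centers_y)
        fx = affine[0, 0] * cx + affine[0, 1] * cy + affine[0, 2]
        fy = affine[1, 0] * cx + affine[1, 1] * cy + affine[1, 2]
        inside = (
            (fx >= 0) & (fx < union.shape[1]) & (fy >= 0) & (fy < union.shape[0])
        )
        blank_boxes = np.zeros(cx.shape, dtype=bool)
        xi = np.clip(np.round(fx).astype(int), 0, union.shape[1] - 1)
        yi = np.clip(np.round(fy).astype(int), 0, union.shape[0] - 1)
        blank_boxes[inside] = dist_px[yi, xi][inside] > margin_px
        cell_boxes = np.zeros(cx.shape, dtype=bool)
        if len(table):
            labelled = table[table["label"] != "unassigned"]
            cell_boxes[labelled["box_row"], labelled["box_col"]] = True
        try:
            rel_strain_error = stats.blank_strain_noise(strains, blank_boxes, cell_boxes)
            _stage("blank_noise", "ok", t0, rel_strain_error=float(rel_strain_error))
        except ValueError as exc:
            _stage("blank_noise", "skipped", t0, reason=str(exc))
    else:
        stages.append({"name": "statistics", "status": "skipped (no masks)", "seconds": 0.0})

    # --- error budget ------------------------------------------------------
    budget = stats.ErrorBudget(
        rel_flow_error=float(rel_flow_error),
        rel_strain_error=float(rel_strain_error) if rel_strain_error is not None else np.nan,
        rel_modulus_error=(
            stats.propagate_errors(rel_flow_error, rel_strain_error)
            if rel_strain_error is not None
            else np.nan
        ),
        systematic_stress_error_bound=stats.depth_of_field_bias(
            params.depth_of_field_um, params.bead_radius_um
        ),
    )
    report["error_budget"] = budget.as_dict()
    report["statistics"] = statistics
    report["n_boxes"] = int(len(table))
    report["total_seconds"] = round(time.perf_counter() - t_start, 3)
    return RunResult(
        report=report,
        table=table,
        moduli=moduli,
        strains=strains,
        displacement=disp,
        flow=flow,
        stress=stress,
        masks=masks,
        blank_boxes=blank_boxes,
        tracks=tracks,
    )


def analyze_experiment(
    sim: SimulatedExperiment,
    params: RunParams | None = None,
    *,
    use_instance_labels: bool = True,
    seed: int | None = None,
) -> RunResult:
    """Run the pipeline on an in-memory synthetic experiment.

    Acquisition and physical parameters are taken from the simulation's own
    configuration so the analysis sees exactly the conditions under which the
    data were rendered.
    """
    scene, config = sim.scene, sim.config
    if params is None:
        params = RunParams()
    params = RunParams(
        **{
            **asdict(params),
            "f0": config.f0,
            "alpha": config.alpha,
            "n_pulses": config.n_pulses,
            "f_repet": config.f_repet,
            "n_frames": config.n_frames,
            "pixel_pitch_um": scene.pixel_pitch_um,
            "fluo_pixel_pitch_um": scene.fluo_pixel_pitch_um,
            "viscosity_pa_s": scene.viscosity_pa_s,
            "bead_radius_um": scene.bead_radius_um,
        }
    )
    return run_pipeline(
        sim.strobe_stack,
        params,
        bead_stack=sim.bead_stack,
        fluorescence=sim.fluorescence,
        affine=sim.affine,
        instance_labels=sim.labels if use_instance_labels else None,
        seed=seed if seed is not None else scene.seed,
    )
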