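"""Forward model: synthetic stroboscopic experiments with known ground truth.

Generates everything the analysis chain consumes — a phase-contrast-like
stroboscopic image stack of oscillating cells, a synchronized tracer-bead
stack, fluorescence channel stacks — together with the ground truth it must
recover: the per-cell complex shear modulus, the complex displacement phasor
field, and the exact bead trajectories.

Construction of the displacement field
--------------------------------------
The oscillating fluid applies a shear-stress phasor ``sigma_k = mu * u_k / R_b``
per direction (u_k the velocity phasor at one bead radius above the dish).
For a target modulus field ``G(x, y)`` inside a cell we set

    delta_x = sigma_x * psi,    delta_y = sigma_y * psi,

with a scalar complex potential ``psi`` satisfying
``d(psi)/dx + d(psi)/dy = 1/G``.  Both the pure-shear sum
``(1/sigma_x) d(delta_x)/dx + (1/sigma_y) d(delta_y)/dy`` and the simple-shear
sum then equal ``1/G`` identically — including under *discrete* central
differences, because the cross-diagonal part of ``psi`` cancels between the
x- and y-stencils.  For a uniform per-cell G, ``psi`` is affine in position;
for a radially varying G it is obtained by integrating ``1/G`` along image
diagonals.  Outside each cell the field is extended unchanged for a few
pixels (so finite-difference stencils of boundary-adjacent boxes stay exact)
and then tapered smoothly to zero.

What is *not* modelled: the acoustic transducer physics (the flow phasor is
prescribed), optical point-spread functions, and 3-D cell geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .signals import PulseTrainConfig, StrobeSchedule, strobe_schedule

__all__ = [
    "CellSpec",
    "SceneSpec",
    "SimulatedExperiment",
    "label_image",
    "flow_phasor_at",
    "ground_truth_displacement",
    "render_strobe_stack",
    "render_fluorescence",
    "simulate_experiment",
    "two_population_scene",
]


@dataclass(frozen=True)
class CellSpec:
    """One synthetic cell: geometry, fluorescence channel and true modulus."""

    center: tuple[float, float]  # (row, col), fast-camera px
    radius_px: float
    channel: str = "green"
    modulus: complex = 5000.0 + 5000.0j  # Pa
    axis_ratio: float = 1.0  # minor/major axis
    angle_deg: float = 0.0
    soft_center: float = 0.0  # fractional |G| reduction at the cell centre

    def __post_init__(self) -> None:
        if abs(self.modulus) <= 0:
            raise ValueError("|G_true| must be positive inside a cell")
        if not 0.0 <= self.soft_center < 1.0:
            raise ValueError("soft_center must be in [0, 1)")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic field of view."""

    shape: tuple[int, int] = (512, 512)
    pixel_pitch_um: float = 0.514  # fast camera; a 5-px DIC box spans 2.57 um
    cells: tuple[CellSpec, ...] = ()
    n_beads: int = 140
    bead_radius_um: float = 1.5
    flow_velocity: tuple[complex, complex] = (0.4 + 0.0j, 0.28 + 0.0j)  # m/s phasors
    flow_ramp: tuple[float, float] = (0.0, 0.0)  # relative linear variation over FOV
    viscosity_pa_s: float = 1.0e-3  # water at room temperature
    noise_sigma: float = 2.0  # camera noise, gray levels (8-bit rendering)
    cell_texture: float = 25.0  # speckle contrast inside cells, gray levels
    background_texture: float = 12.0  # dish texture, ~half the cell contrast
    fluo_pixel_pitch_um: float = 0.3
    fluo_rotation_deg: float = 0.3
    fluo_offset_px: tuple[float, float] = (3.2, -2.1)
    taper_inner_px: float = 8.0  # field kept exact this far outside each cell
    taper_outer_px: float = 14.0  # field reaches zero here
    seed: int = 0  # scene content (geometry, texture, bead placement)
    noise_seed: int = 1  # camera noise only

    @property
    def bead_radius_px(self) -> float:
        return self.bead_radius_um / self.pixel_pitch_um


@dataclass
class SimulatedExperiment:
    """A rendered synthetic experiment plus all ground truth."""

    scene: SceneSpec
    config: PulseTrainConfig
    schedule: StrobeSchedule
    strobe_stack: np.ndarray  # (N_aq, H, W) uint8
    bead_stack: np.ndarray | None  # (N_aq, H, W) uint8
    fluorescence: dict[str, np.ndarray]  # channel -> (K, Hf, Wf) uint16
    affine: np.ndarray  # 2x3, fast-camera (x, y) px -> fluorescence (x, y) px
    fluo_shape: tuple[int, int]
    labels: np.ndarray  # (H, W) int32 instance labels on the fast grid, 0 = background
    delta_field: np.ndarray  # (2, H, W) complex displacement phasor, um
    bead_tracks: pd.DataFrame  # frame, id, x_px, y_px ground-truth positions
    cell_moduli: np.ndarray  # complex, per cell (Pa)


# ---------------------------------------------------------------------------
# geometry helpers


def _cell_patch(cell: CellSpec, shape: tuple[int, int], pad: float):
    """Bounding slice of a cell plus `pad` px, clipped to the image."""
    r0, c0 = cell.center
    extent = cell.radius_px + pad
    rlo = max(int(math.floor(r0 - extent)), 0)
    rhi = min(int(math.ceil(r0 + extent)) + 1, shape[0])
    clo = max(int(math.floor(c0 - extent)), 0)
    chi = min(int(math.ceil(c0 + extent)) + 1, shape[1])
    return slice(rlo, rhi), slice(clo, chi)


def _ellipse_r2(cell: CellSpec, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Squared normalized elliptical radius (<= 1 inside the cell)."""
    theta = math.radians(cell.angle_deg)
    dy = rows - cell.center[0]
    dx = cols - cell.center[1]
    xr = dx * math.cos(theta) + dy * math.sin(theta)
    yr = -dx * math.sin(theta) + dy * math.cos(theta)
    a = cell.radius_px
    b = cell.radius_px * cell.axis_ratio
    return (xr / a) ** 2 + (yr / b) ** 2


def label_image(scene: SceneSpec) -> np.ndarray:
    """Instance-label image on the fast-camera grid (0 = background)."""
    labels = np.zeros(scene.shape, dtype=np.int32)
    for idx, cell in enumerate(scene.cells, start=1):
        rs, cs = _cell_patch(cell, scene.shape, pad=1.0)
        rows, cols = np.mgrid[rs, cs]
        inside = _ellipse_r2(cell, rows, cols) <= 1.0
        labels[rs, cs][inside] = idx
    return labels


def flow_phasor_at(scene: SceneSpec, x_px: np.ndarray, y_px: np.ndarray):
    """Complex velocity phasors (u_x, u_y) in m/s at fast-camera positions."""
    h, w = scene.shape
    gx, gy = scene.flow_ramp
    factor = 1.0 + gx * (np.asarray(x_px) / w - 0.5) + gy * (np.asarray(y_px) / h - 0.5)
    ux0, uy0 = scene.flow_velocity
    return ux0 * factor, uy0 * factor


def _stress_at_cell(scene: SceneSpec, cell: CellSpec) -> tuple[complex, complex]:
    ux, uy = flow_phasor_at(scene, np.array(cell.center[1]), np.array(cell.center[0]))
    scale = scene.viscosity_pa_s / (scene.bead_radius_um * 1e-6)
    return complex(ux) * scale, complex(uy) * scale


# ---------------------------------------------------------------------------
# ground-truth displacement


def _taper_weight(inside: np.ndarray, inner: float, outer: float) -> np.ndarray:
    """1 inside the mask and up to `inner` px beyond it, cosine-ramped to 0 at `outer`."""
    dist = ndimage.distance_transform_edt(~inside)
    w = np.zeros(inside.shape, dtype=float)
    w[dist <= inner] = 1.0
    ramp = (dist > inner) & (dist < outer)
    w[ramp] = 0.5 * (1.0 + np.cos(np.pi * (dist[ramp] - inner) / (outer - inner)))
    return w


def _psi_affine(cell: CellSpec, rows, cols, pitch: float) -> np.ndarray:
    """Potential for uniform per-cell G: psi = ((x-xc) + (y-yc)) / (2 G) in um/Pa."""
    xc, yc = cell.center[1], cell.center[0]
    return ((cols - xc) + (rows - yc)) * pitch / (2.0 * cell.modulus)


def _psi_integrated(cell: CellSpec, rows, cols, pitch: float) -> np.ndarray:
    """Potential for radially varying G, by trapezoidal integration of 1/G
    along image diagonals (step (+1, +1) px adds pitch/G)."""
    r2 = _ellipse_r2(cell, rows, cols)
    inside = r2 <= 1.0
    g_local = cell.modulus * (1.0 - cell.soft_center * (1.0 - np.clip(r2, 0.0, 1.0)))
    inv_g = np.where(inside, 1.0 / g_local, 0.0)
    psi = np.zeros(rows.shape, dtype=complex)
    for i in range(1, rows.shape[0]):
        psi[i, 1:] = psi[i - 1, :-1] + pitch * 0.5 * (inv_g[i, 1:] + inv_g[i - 1, :-1])
    return psi


def ground_truth_displacement(scene: SceneSpec) -> np.ndarray:
    """Complex displacement phasor field (2, H, W) in um; index 0 is x, 1 is y.

    Inside every cell the field is built so that the homodyne strain sums
    recover the cell's true modulus exactly; outside it is extended unchanged
    for ``taper_inner_px`` and then tapered smoothly to zero.  Raises if a
    cell has nonzero modulus but the prescribed flow (hence stress) is zero.
    """
    delta = np.zeros((2,) + scene.shape, dtype=complex)
    pitch = scene.pixel_pitch_um
    for cell in scene.cells:
        sx, sy = _stress_at_cell(scene, cell)
        if sx == 0 and sy == 0:
            raise ValueError(
                "zero stress with a nonzero target modulus: prescribe a nonzero flow"
            )
        rs, cs = _cell_patch(cell, scene.shape, pad=scene.taper_outer_px + 2.0)
        rows, cols = np.mgrid[rs, cs].astype(float)
        if cell.soft_center == 0.0:
            psi = _psi_affine(cell, rows, cols, pitch)
        else:
            psi = _psi_integrated(cell, rows, cols, pitch)
        inside = _ellipse_r2(cell, rows, cols) <= 1.0
        w = _taper_weight(inside, scene.taper_inner_px, scene.taper_outer_px)
        delta[0, rs, cs] += sx * psi * w
        delta[1, rs, cs] += sy * psi * w
    return delta


# ---------------------------------------------------------------------------
# rendering


def _speckle(shape, rng: np.random.Generator, lo: float = 1.0, hi: float = 2.5):
    """Band-passed random speckle with unit standard deviation."""
    white = rng.standard_normal(shape)
    band = ndimage.gaussian_filter(white, lo) - ndimage.gaussian_filter(white, hi)
    return band / band.std()


def _rest_texture(scene: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Phase-contrast-like rest image: weak dish texture, stronger cell speckle."""
    speckle = _speckle(scene.shape, rng)
    mask = (label_image(scene) > 0).astype(float)
    soft = ndimage.gaussian_filter(mask, 1.0)
    contrast = scene.background_texture + soft * (scene.cell_texture - scene.background_texture)
    return 120.0 + speckle * contrast + 8.0 * soft


def _bead_positions(scene: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Rest positions (n, 2) as (x, y) px, dart-throwing with a minimum spacing."""
    h, w = scene.shape
    margin = 12.0
    min_sep = 22.0
    positions: list[tuple[float, float]] = []
    attempts = 0
    while len(positions) < scene.n_beads and attempts < 200 * scene.n_beads:
        attempts += 1
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in positions):
            positions.append((x, y))
    if len(positions) < scene.n_beads:
        raise ValueError("could not place the requested number of beads; reduce n_beads")
    return np.asarray(positions, dtype=float)


def _draw_bead(frame: np.ndarray, x: float, y: float, r0: float, depth: float) -> None:
    """Dark super-Gaussian disc at sub-pixel position (in place)."""
    extent = int(math.ceil(2.5 * r0)) + 1
    ic, jc = int(round(y)), int(round(x))
    rs = slice(max(ic - extent, 0), min(ic + extent + 1, frame.shape[0]))
    cs = slice(max(jc - extent, 0), min(jc + extent + 1, frame.shape[1]))
    rows, cols = np.mgrid[rs, cs]
    rr2 = (cols - x) ** 2 + (rows - y) ** 2
    frame[rs, cs] -= depth * np.exp(-((rr2 / r0**2) ** 2))


def _frame_phasor_factors(schedule: StrobeSchedule, config: PulseTrainConfig):
    """Per-frame complex factor e^{i w t} * envelope(t); zero for rest frames."""
    t = schedule.sample_times
    factors = np.exp(2j * np.pi * config.f0 * t) * np.exp(
        -(config.alpha**2) * (t - config.t0) ** 2
    )
    factors[config.n_pulses :] = 0.0
    return factors


def render_strobe_stack(
    scene: SceneSpec,
    schedule: StrobeSchedule | None = None,
    config: PulseTrainConfig | None = None,
    *,
    with_beads: bool = True,
):
    """Render the stroboscopic cell stack and the synchronized bead stack.

    Frame ``n`` shows the rest texture warped by
    ``Re[delta * exp(i 2 pi f0 t_n)] * envelope(t_n)`` (cubic sub-pixel
    interpolation); the trailing ``N_aq - N`` frames are at rest.  Beads are
    advected by the prescribed flow and rendered as dark discs on a separate
    stack.  Returns ``(stack, bead_stack, bead_tracks, delta_field)``.
    """
    config = config or PulseTrainConfig(f0=30e3, alpha=10e3)
    schedule = schedule or strobe_schedule(config)

    ss = np.random.SeedSequence(scene.seed)
    rng_texture, rng_beads = (np.random.default_rng(c) for c in ss.spawn(2))
    nss = np.random.SeedSequence(scene.noise_seed)
    rng_noise, rng_bead_noise = (np.random.default_rng(c) for c in nss.spawn(2))

    delta_um = ground_truth_displacement(scene)
    delta_px = delta_um / scene.pixel_pitch_um
    max_disp = float(np.abs(delta_px).max(initial=0.0))
    if max_disp > min(scene.shape) / 2:
        raise ValueError("displacement amplitude exceeds half the image size")

    texture = _rest_texture(scene, rng_texture)
    coeffs = ndimage.spline_filter(texture, order=3, mode="mirror")
    rows, cols = np.mgrid[0 : scene.shape[0], 0 : scene.shape[1]].astype(float)
    factors = _frame_phasor_factors(schedule, config)

    n_frames = int(config.n_frames)
    stack = np.empty((n_frames,) + scene.shape, dtype=np.uint8)
    for n in range(n_frames):
        fac = factors[n]
        if abs(fac) * max_disp > 1e-3:
            dx = (delta_px[0] * fac).real
            dy = (delta_px[1] * fac).real
            frame = ndimage.map_coordinates(
                coeffs, [rows - dy, cols - dx], order=3, prefilter=False, mode="mirror"
            )
        else:
            frame = texture.copy()
        if scene.noise_sigma > 0:
            frame += scene.noise_sigma * rng_noise.standard_normal(scene.shape)
        np.clip(frame, 0, 255, out=frame)
        stack[n] = frame.astype(np.uint8)

    bead_stack = None
    tracks = pd.DataFrame(columns=["frame", "id", "x_px", "y_px"])
    if with_beads and scene.n_beads > 0:
        rest = _bead_positions(scene, rng_beads)
        ux, uy = flow_phasor_at(scene, rest[:, 0], rest[:, 1])
        omega = 2.0 * np.pi * config.f0
        px_per_m = 1.0 / (scene.pixel_pitch_um * 1e-6)
        amp_x = ux / (1j * omega) * px_per_m  # displacement phasor, px
        amp_y = uy / (1j * omega) * px_per_m
        r0 = scene.bead_radius_px
        bead_stack = np.empty_like(stack)
        records = np.empty((n_frames * rest.shape[0], 4), dtype=float)
        for n in range(n_frames):
            fac = factors[n]
            xs = rest[:, 0] + (amp_x * fac).real
            ys = rest[:, 1] + (amp_y * fac).real
            frame = np.full(scene.shape, 140.0)
            for x, y in zip(xs, ys):
                _draw_bead(frame, x, y, r0, depth=90.0)
            if scene.noise_sigma > 0:
                frame += scene.noise_sigma * rng_bead_noise.standard_normal(scene.shape)
            np.clip(frame, 0, 255, out=frame)
            bead_stack[n] = frame.astype(np.uint8)
            block = slice(n * rest.shape[0], (n + 1) * rest.shape[0])
            records[block, 0] = n
            records[block, 1] = np.arange(rest.shape[0])
            records[block, 2] = xs
            records[block, 3] = ys
        tracks = pd.DataFrame(records, columns=["frame", "id", "x_px", "y_px"])
        tracks["frame"] = tracks["frame"].astype(int)
        tracks["id"] = tracks["id"].astype(int)

    return stack, bead_stack, tracks, delta_um


# ---------------------------------------------------------------------------
# fluorescence


def fluorescence_affine(scene: SceneSpec) -> tuple[np.ndarray, tuple[int, int]]:
    """2x3 affine mapping fast-camera (x, y) px to fluorescence (x, y) px,
    and the fluorescence image shape that contains the mapped field of view."""
    s = scene.pixel_pitch_um / scene.fluo_pixel_pitch_um
    th = math.radians(scene.fluo_rotation_deg)
    lin = s * np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    h, w = scene.shape
    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=float)
    mapped = corners @ lin.T
    offset = 10.0 - mapped.min(axis=0) + np.asarray(scene.fluo_offset_px, dtype=float)
    hi = mapped.max(axis=0) + offset
    shape_fluo = (int(math.ceil(hi[1])) + 11, int(math.ceil(hi[0])) + 11)
    affine = np.hstack([lin, offset[:, None]])
    return affine, shape_fluo


def _warp_mask_to_fluo(mask: np.ndarray, affine: np.ndarray, shape_fluo) -> np.ndarray:
    """Resample a fast-grid image onto the fluorescence grid (bilinear)."""
    lin = affine[:, :2]
    offset = affine[:, 2]
    inv = np.linalg.inv(lin)
    xf, yf = np.meshgrid(np.arange(shape_fluo[1]), np.arange(shape_fluo[0]))
    src = np.stack([xf.ravel() - offset[0], yf.ravel() - offset[1]])
    xs, ys = inv @ src
    out = ndimage.map_coordinates(
        mask.astype(float), [ys, xs], order=1, mode="constant", cval=0.0
    )
    return out.reshape(shape_fluo)


def render_fluorescence(
    scene: SceneSpec,
    n_images: int = 10,
    rng: np.random.Generator | None = None,
    *,
    background: bool = True,
    noise_sigma: float = 15.0,
):
    """Per-channel fluorescence stacks (12-bit) with long-range illumination
    background and independent per-image noise.  Returns ``(stacks, affine,
    shape)`` where ``stacks`` maps channel name to a (n_images, Hf, Wf) array.
    """
    if n_images < 1:
        raise ValueError("need at least one fluorescence image")
    rng = np.random.default_rng(np.random.SeedSequence(scene.noise_seed + 17)) if rng is None else rng
    affine, shape_fluo = fluorescence_affine(scene)
    channels = sorted({c.channel for c in scene.cells})
    yf, xf = np.mgrid[0 : shape_fluo[0], 0 : shape_fluo[1]].astype(float)
    if background:
        sig = 0.5 * min(shape_fluo)
        illum = 250.0 * np.exp(
            -((xf - 0.25 * shape_fluo[1]) ** 2 + (yf - 0.3 * shape_fluo[0]) ** 2)
            / (2.0 * sig**2)
        )
    else:
        illum = 0.0
    stacks: dict[str, np.ndarray] = {}
    for channel in channels:
        # per-cell ellipses, not instance labels: overlapping cells of
        # different channels must be bright in both
        mask = np.zeros(scene.shape, dtype=float)
        for cell in scene.cells:
            if cell.channel != channel:
                continue
            rs, cs = _cell_patch(cell, scene.shape, pad=1.0)
            rows, cols = np.mgrid[rs, cs]
            mask[rs, cs][_ellipse_r2(cell, rows, cols) <= 1.0] = 1.0
        bright = _warp_mask_to_fluo(mask, affine, shape_fluo)
        base = 100.0 + 900.0 * bright + illum
        stack = np.empty((n_images,) + shape_fluo, dtype=np.uint16)
        for k in range(n_images):
            img = base + noise_sigma * rng.standard_normal(shape_fluo)
            stack[k] = np.clip(img, 0, 4095).astype(np.uint16)
        stacks[channel] = stack
    return stacks, affine, shape_fluo


# ---------------------------------------------------------------------------
# scene builders and one-call simulation


def two_population_scene(
    seed: int = 0,
    *,
    shape: tuple[int, int] = (512, 512),
    n_cells: int = 72,
    medians_pa: tuple[float, float] = (4400.0, 6300.0),
    sigma_log: float = 0.35,
    loss_tangent: float = 1.0,
    channels: tuple[str, str] = ("green", "orange"),
    soft_center: float = 0.0,
    blank_block: int = 3,
    noise_seed: int | None = None,
    **scene_kwargs,
) -> SceneSpec:
    """Mixed co-culture scene: two cell populations on a jittered grid.

    Population moduli are lognormal between cells (``sigma_log`` in log space,
    loss tangent ~1 so storage and loss moduli are comparable) and rescaled so
    each population's realized median |G| equals its target exactly.  Cells
    share a single radius; the grid spacing keeps neighbouring displacement
    fields from overlapping each other's strain stencils.  A
    ``blank_block`` x ``blank_block`` corner of grid slots is left cell-free,
    emulating the empty dish area used for the blank strain-noise estimate.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    h, w = shape
    n_slots = n_cells + blank_block**2
    ncols = max(int(round(math.sqrt(n_slots * w / h))), 1)
    nrows = int(math.ceil(n_slots / ncols))
    sp_x, sp_y = w / ncols, h / nrows
    radius = 0.28 * min(sp_x, sp_y)
    positions = []
    for i in range(nrows):
        for j in range(ncols):
            if i < blank_block and j < blank_block:
                continue  # reserved blank area
            if len(positions) >= n_cells:
                break
            jitter = rng.uniform(-2.0, 2.0, size=2)
            # alternate channels by placement order: spatially interleaved
            # populations with an exactly balanced split for even n_cells
            positions.append(
                ((i + 0.5) * sp_y + jitter[0], (j + 0.5) * sp_x + jitter[1], len(positions) % 2)
            )
    if len(positions) < n_cells:
        raise ValueError("grid too small for the requested cell count")
    pop_idx = np.array([p[2] for p in positions])
    moduli = np.empty(len(positions), dtype=complex)
    for p, median in enumerate(medians_pa):
        sel = np.flatnonzero(pop_idx == p)
        mags = median * np.exp(sigma_log * rng.standard_normal(sel.size))
        mags *= median / np.median(mags)
        phases = math.atan(loss_tangent) + 0.05 * rng.standard_normal(sel.size)
        moduli[sel] = mags * np.exp(1j * phases)
    cells = tuple(
        CellSpec(
            center=(float(r), float(c)),
            radius_px=float(radius),
            channel=channels[p],
            modulus=complex(moduli[k]),
            soft_center=soft_center,
        )
        for k, (r, c, p) in enumerate(positions)
    )
    return SceneSpec(
        shape=shape,
        cells=cells,
        seed=seed,
        noise_seed=seed + 1000 if noise_seed is None else noise_seed,
        **scene_kwargs,
    )


def simulate_experiment(
    scene: SceneSpec,
    config: PulseTrainConfig | None = None,
    *,
    n_fluo_images: int = 10,
    with_beads: bool = True,
) -> SimulatedExperiment:
    """Render a complete synthetic experiment (strobe + beads + fluorescence)."""
    config = config or PulseTrainConfig(f0=30e3, alpha=10e3)
    schedule = strobe_schedule(config)
    stack, bead_stack, tracks, delta_um = render_strobe_stack(
        scene, schedule, config, with_beads=with_beads
    )
    fluo, affine, shape_fluo = render_fluorescence(scene, n_images=n_fluo_images)
    return SimulatedExperiment(
        scene=scene,
        config=config,
        schedule=schedule,
        strobe_stack=stack,
        bead_stack=bead_stack,
        fluorescence=fluo,
        affine=affine,
        fluo_shape=shape_fluo,
        labels=label_image(scene),
        delta_field=delta_um,
        bead_tracks=tracks,
        cell_moduli=np.array([c.modulus for c in scene.cells]),
    )
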