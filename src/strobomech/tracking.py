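"""Particle tracking velocimetry of tracer beads and homodyne stress estimation.

Tracer beads resting on the dish bottom are advected by the oscillating gap
flow.  Their tracked displacements, homodyne-detected at the carrier
frequency and averaged per sub-field-of-view, give the complex velocity
phasor field ``u_k(x, y)``; the wall shear stress the cells feel follows from
the vertical velocity gradient, ``sigma_k = mu * u_k(z = R_b) / R_b``.

The homodyne displacement phasor is converted to a velocity phasor by
multiplication with ``i * 2 * pi * f0`` (harmonic motion), which is what makes
the stress dimensionally a pressure and a purely elastic cell response give a
real modulus downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline
from scipy.spatial import cKDTree

from .signals import StrobeSchedule, homodyne_coefficient

__all__ = [
    "TrackSet",
    "HomodyneFlowField",
    "StressField",
    "detect_beads",
    "link_tracks",
    "track_stack",
    "homodyne_flow",
    "stress_field",
    "flow_residuals",
]


@dataclass
class TrackSet:
    """Linked particle tracks.

    ``table`` has columns (frame, id, x_px, y_px); ``n_frames`` is the number
    of frames the linker saw.  A track is *complete* when it has one position
    in every frame — only complete tracks enter sub-FOV averages.
    """

    table: pd.DataFrame
    n_frames: int
    dropped_links: int = 0

    @property
    def ids(self) -> np.ndarray:
        return np.unique(self.table["id"].to_numpy())

    @property
    def complete_ids(self) -> np.ndarray:
        counts = self.table.groupby("id")["frame"].count()
        return counts.index[counts == self.n_frames].to_numpy()

    def positions(self, track_id: int) -> np.ndarray:
        rows = self.table[self.table["id"] == track_id].sort_values("frame")
        return rows[["x_px", "y_px"]].to_numpy()


@dataclass
class HomodyneFlowField:
    """Per-pixel complex velocity phasor field interpolated from sub-FOV values."""

    u_x: np.ndarray  # (H, W) complex, m/s
    u_y: np.ndarray
    subfov_u: np.ndarray  # (n, n, 2) complex phasors at the grid centres
    centers_x: np.ndarray  # (n,) sub-FOV centre columns, px
    centers_y: np.ndarray
    n_grid: int
    f0: float
    pixel_pitch_um: float

    def at(self, x_px: np.ndarray, y_px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Sample the interpolated field at (sub-)pixel positions."""
        xi = np.clip(np.round(np.asarray(x_px)).astype(int), 0, self.u_x.shape[1] - 1)
        yi = np.clip(np.round(np.asarray(y_px)).astype(int), 0, self.u_x.shape[0] - 1)
        return self.u_x[yi, xi], self.u_y[yi, xi]


@dataclass
class StressField:
    """Complex wall shear-stress phasors, Pa, per direction."""

    sigma_x: np.ndarray
    sigma_y: np.ndarray
    mu: float
    bead_radius_m: float


# ---------------------------------------------------------------------------
# detection and linking


def detect_beads(
    frame: np.ndarray,
    radius_px: float = 3.0,
    *,
    threshold_rel: float = 0.25,
    n_sigma: float = 8.0,
) -> np.ndarray:
    """Sub-pixel centroids (x, y) of dark disc-like beads in one frame.

    The frame is inverted around its median, smoothed at the bead scale, and
    local maxima above a noise-aware threshold are kept; detections closer
    than one radius are merged (brightest wins).  Centroids are refined by an
    iterated intensity-weighted mean in a circular window.  Returns an (n, 2)
    array; empty for a blank frame.
    """
    img = np.asarray(frame, dtype=float)
    inv = np.median(img) - img
    sm = ndimage.gaussian_filter(inv, radius_px / 2.0)
    mad = np.median(np.abs(sm - np.median(sm)))
    thresh = max(n_sigma * 1.4826 * mad, threshold_rel * sm.max(), 1e-12)
    size = max(int(round(radius_px)) * 2 + 1, 3)
    peaks = (sm == ndimage.maximum_filter(sm, size=size)) & (sm > thresh)
    ys, xs = np.nonzero(peaks)
    if xs.size == 0:
        return np.empty((0, 2))
    order = np.argsort(sm[ys, xs])[::-1]
    ys, xs = ys[order], xs[order]
    kept: list[tuple[float, float]] = []
    for x, y in zip(xs, ys):
        if all((x - kx) ** 2 + (y - ky) ** 2 >= radius_px**2 for kx, ky in kept):
            kept.append((float(x), float(y)))
    # centroid refinement on the smoothed, background-free image
    win = int(np.ceil(2.0 * radius_px))
    refined = []
    for x, y in kept:
        for _ in range(3):
            ic, jc = int(round(y)), int(round(x))
            rs = slice(max(ic - win, 0), min(ic + win + 1, img.shape[0]))
            cs = slice(max(jc - win, 0), min(jc + win + 1, img.shape[1]))
            rows, cols = np.mgrid[rs, cs]
            wmask = ((cols - x) ** 2 + (rows - y) ** 2) <= win**2
            weights = np.clip(sm[rs, cs], 0.0, None) * wmask
            total = weights.sum()
            if total <= 0:
                break
            x = float((weights * cols).sum() / total)
            y = float((weights * rows).sum() / total)
        refined.append((x, y))
    return np.asarray(refined)


def link_tracks(
    centroids_per_frame: list[np.ndarray],
    max_jump: float | None = None,
) -> TrackSet:
    """Nearest-neighbour frame-to-frame linking with a maximum-jump gate.

    The gate defaults to half the median nearest-neighbour distance of each
    frame's detections (linking is only valid when displacements stay below
    inter-particle distances).  Ambiguous links — a detection claimed by two
    tracks, or a track with two candidates inside the gate — are dropped and
    counted; the contested detections seed new tracks.
    """
    records: list[tuple[int, int, float, float]] = []
    next_id = 0
    active: dict[int, np.ndarray] = {}
    dropped = 0
    for frame_idx, pts in enumerate(centroids_per_frame):
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        if frame_idx == 0 or not active:
            new_active = {}
            for p in pts:
                records.append((frame_idx, next_id, p[0], p[1]))
                new_active[next_id] = p
                next_id += 1
            active = new_active
            continue
        gate = max_jump
        if gate is None:
            if pts.shape[0] >= 2:
                tree = cKDTree(pts)
                d, _ = tree.query(pts, k=2)
                gate = 0.5 * float(np.median(d[:, 1]))
            else:
                gate = np.inf
        ids = list(active.keys())
        prev = np.array([active[i] for i in ids])
        new_active = {}
        if pts.shape[0]:
            tree = cKDTree(pts)
            neighbours = tree.query_ball_point(prev, r=gate)
            claims: dict[int, list[int]] = {}
            for ti, cand in enumerate(neighbours):
                for ci in cand:
                    claims.setdefault(ci, []).append(ti)
            used = set()
            for ti, cand in enumerate(neighbours):
                if len(cand) == 1 and len(claims[cand[0]]) == 1:
                    ci = cand[0]
                    records.append((frame_idx, ids[ti], pts[ci, 0], pts[ci, 1]))
                    new_active[ids[ti]] = pts[ci]
                    used.add(ci)
                elif len(cand) > 1:
                    dropped += 1
            for ci in range(pts.shape[0]):
                if ci not in used and len(claims.get(ci, [])) <= 1:
                    records.append((frame_idx, next_id, pts[ci, 0], pts[ci, 1]))
                    new_active[next_id] = pts[ci]
                    next_id += 1
                elif ci not in used:
                    dropped += 1
        active = new_active
    table = pd.DataFrame(records, columns=["frame", "id", "x_px", "y_px"])
    return TrackSet(table=table, n_frames=len(centroids_per_frame), dropped_links=dropped)


def track_stack(
    stack: np.ndarray,
    radius_px: float = 3.0,
    max_jump: float | None = None,
) -> TrackSet:
    """Detect and link beads across a whole image stack."""
    centroids = [detect_beads(frame, radius_px) for frame in stack]
    return link_tracks(centroids, max_jump=max_jump)


# ---------------------------------------------------------------------------
# homodyne flow and stress


def _select_grid_order(positions: np.ndarray, shape, min_per_cell: int) -> int:
    """Largest n for which every n x n sub-FOV holds >= min_per_cell tracks."""
    n_tracks = positions.shape[0]
    for n in range(max(int(np.sqrt(n_tracks / min_per_cell)), 1), 0, -1):
        iy = np.clip((positions[:, 1] * n / shape[0]).astype(int), 0, n - 1)
        ix = np.clip((positions[:, 0] * n / shape[1]).astype(int), 0, n - 1)
        counts = np.zeros((n, n), dtype=int)
        np.add.at(counts, (iy, ix), 1)
        if counts.min() >= min_per_cell:
            return n
    raise ValueError(
        "no sub-FOV grid satisfies the minimum-particle rule; add more tracers"
    )


def homodyne_flow(
    tracks: TrackSet,
    schedule: StrobeSchedule,
    f0: float,
    image_shape: tuple[int, int],
    pixel_pitch_um: float,
    *,
    min_per_cell: int = 5,
    n_grid: int | None = None,
    velocity: bool = True,
) -> HomodyneFlowField:
    """Homodyne oscillating flow field from complete tracks.

    Per sub-FOV, displacements are averaged over the particles, homodyne
    detected, and (by default) converted to a velocity phasor by
    ``i * 2 * pi * f0``; the per-pixel field is an order-2 spline interpolation
    across the sub-FOV centres with constant extrapolation outside their hull.
    """
    complete = tracks.complete_ids
    if complete.size == 0:
        raise ValueError("no complete tracks: cannot estimate the flow field")
    sub = tracks.table[tracks.table["id"].isin(complete)]
    n_frames = tracks.n_frames
    times = schedule.sample_times[:n_frames]
    piv = sub.pivot_table(index="frame", columns="id", values=["x_px", "y_px"])
    xs = piv["x_px"].to_numpy()  # (T, n_tracks)
    ys = piv["y_px"].to_numpy()
    mean_pos = np.stack([xs.mean(axis=0), ys.mean(axis=0)], axis=1)

    n = n_grid if n_grid is not None else _select_grid_order(mean_pos, image_shape, min_per_cell)
    iy = np.clip((mean_pos[:, 1] * n / image_shape[0]).astype(int), 0, n - 1)
    ix = np.clip((mean_pos[:, 0] * n / image_shape[1]).astype(int), 0, n - 1)
    if n_grid is not None:
        counts = np.zeros((n, n), dtype=int)
        np.add.at(counts, (iy, ix), 1)
        if counts.min() < 1:
            raise ValueError(f"forced grid order {n} leaves empty sub-FOVs")

    scale = pixel_pitch_um * 1e-6
    conv = 1j * 2.0 * np.pi * f0 * scale if velocity else scale
    sub_u = np.zeros((n, n, 2), dtype=complex)
    for gy in range(n):
        for gx in range(n):
            sel = (iy == gy) & (ix == gx)
            if not sel.any():
                continue
            disp_x = (xs[:, sel] - xs[:, sel].mean(axis=0)).mean(axis=1)
            disp_y = (ys[:, sel] - ys[:, sel].mean(axis=0)).mean(axis=1)
            sub_u[gy, gx, 0] = homodyne_coefficient(disp_x, times, f0) * conv
            sub_u[gy, gx, 1] = homodyne_coefficient(disp_y, times, f0) * conv

    centers_y = (np.arange(n) + 0.5) * image_shape[0] / n
    centers_x = (np.arange(n) + 0.5) * image_shape[1] / n
    yy = np.clip(np.arange(image_shape[0], dtype=float), centers_y[0], centers_y[-1])
    xx = np.clip(np.arange(image_shape[1], dtype=float), centers_x[0], centers_x[-1])
    fields = []
    for k in range(2):
        if n == 1:
            fields.append(np.full(image_shape, sub_u[0, 0, k]))
            continue
        order = min(n - 1, 2)
        re = RectBivariateSpline(centers_y, centers_x, sub_u[:, :, k].real, kx=order, ky=order)
        im = RectBivariateSpline(centers_y, centers_x, sub_u[:, :, k].imag, kx=order, ky=order)
        fields.append(re(yy, xx) + 1j * im(yy, xx))
    return HomodyneFlowField(
        u_x=fields[0],
        u_y=fields[1],
        subfov_u=sub_u,
        centers_x=centers_x,
        centers_y=centers_y,
        n_grid=n,
        f0=f0,
        pixel_pitch_um=pixel_pitch_um,
    )


def stress_field(flow: HomodyneFlowField, mu: float, bead_radius_m: float) -> StressField:
    """Wall shear stress from the linear vertical velocity gradient,
    ``sigma_k = mu * u_k / R_b`` (beads rest on the dish, centres at z = R_b)."""
    if bead_radius_m <= 0:
        raise ValueError("bead radius must be positive")
    factor = mu / bead_radius_m
    return StressField(
        sigma_x=flow.u_x * factor,
        sigma_y=flow.u_y * factor,
        mu=mu,
        bead_radius_m=bead_radius_m,
    )


def flow_residuals(
    tracks: TrackSet,
    flow: HomodyneFlowField,
    schedule: StrobeSchedule,
    *,
    outlier_factor: float = 5.0,
) -> tuple[float, pd.DataFrame]:
    """Relative flow-field error from per-track residuals.

    Each complete track's own homodyne velocity phasor is compared with the
    interpolated field at its mean position; the reported error is the RMS
    residual over tracks and directions divided by the RMS field value there.
    Tracks whose residual exceeds ``outlier_factor`` times the median are
    flagged in the per-track table.
    """
    complete = tracks.complete_ids
    if complete.size == 0:
        raise ValueError("no complete tracks")
    times = schedule.sample_times[: tracks.n_frames]
    conv = 1j * 2.0 * np.pi * flow.f0 * flow.pixel_pitch_um * 1e-6
    rows = []
    for tid in complete:
        pos = tracks.positions(tid)
        ux_i = homodyne_coefficient(pos[:, 0] - pos[:, 0].mean(), times, flow.f0) * conv
        uy_i = homodyne_coefficient(pos[:, 1] - pos[:, 1].mean(), times, flow.f0) * conv
        fx, fy = flow.at(pos[:, 0].mean(), pos[:, 1].mean())
        rows.append((tid, pos[:, 0].mean(), pos[:, 1].mean(), ux_i, uy_i, fx, fy))
    per_track = pd.DataFrame(
        rows, columns=["id", "x_px", "y_px", "u_x", "u_y", "field_x", "field_y"]
    )
    res2 = (
        np.abs(per_track["u_x"] - per_track["field_x"]) ** 2
        + np.abs(per_track["u_y"] - per_track["field_y"]) ** 2
    )
    ref2 = np.abs(per_track["field_x"]) ** 2 + np.abs(per_track["field_y"]) ** 2
    rel_error = float(np.sqrt(res2.mean() / max(ref2.mean(), 1e-300)))
    med = np.median(res2)
    per_track["residual2"] = res2
    # an outlier must dominate the median *and* matter relative to the field
    per_track["outlier"] = (res2 > outlier_factor * max(med, 1e-300)) & (
        res2 > 1e-6 * ref2.mean()
    )
    return rel_error, per_track
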