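"""Digital image correlation of the stroboscopic cell stack.

Per frame, non-overlapping comparison boxes (default 5 x 5 px, the native
statistical unit downstream) are matched against an averaged rest reference
image by normalized cross-correlation over an integer search window, refined
to sub-pixel by a separable parabolic fit on the log-correlation around the
peak.  The per-box displacement time series are then homodyne-detected at the
carrier frequency, yielding complex displacement phasor maps, and can be
warped into fluorescence-camera coordinates with a known affine transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .signals import StrobeSchedule, homodyne_coefficient

__all__ = [
    "DisplacementStack",
    "HomodyneDisplacementMap",
    "reference_image",
    "dic_displacements",
    "homodyne_displacement",
    "warp_to_fluorescence",
]


@dataclass
class DisplacementStack:
    """Per-frame, per-box displacements from DIC.

    ``delta`` has shape (T, n_boxes_y, n_boxes_x, 2) with the last axis
    ordered (x, y) in fast-camera pixels; frames where a box's correlation
    peak fell below the contrast threshold hold NaN.  ``valid`` marks boxes
    with enough reference texture to be matched at all.
    """

    delta: np.ndarray
    valid: np.ndarray  # (n_boxes_y, n_boxes_x) bool
    box_size: int
    box_centers_x: np.ndarray  # (n_boxes_x,) px
    box_centers_y: np.ndarray


@dataclass
class HomodyneDisplacementMap:
    """Complex displacement phasors per DIC box, fast-camera pixels."""

    delta_x: np.ndarray  # (n_boxes_y, n_boxes_x) complex
    delta_y: np.ndarray
    valid: np.ndarray
    box_size: int
    box_centers_x: np.ndarray
    box_centers_y: np.ndarray
    pixel_pitch_um: float | None = None

    @property
    def amplitude(self) -> np.ndarray:
        """|delta| = sqrt(|dx|^2 + |dy|^2) per box (px)."""
        return np.hypot(np.abs(self.delta_x), np.abs(self.delta_y))


def reference_image(stack: np.ndarray, n_pulses: int) -> np.ndarray:
    """Average of the trailing rest frames (acquired straight after the burst
    train); their noise averages down by 1/sqrt(N_aq - N)."""
    stack = np.asarray(stack)
    if stack.shape[0] <= n_pulses:
        raise ValueError(
            "stack has no rest frames after the pulse train; acquire N_aq > N frames"
        )
    return stack[n_pulses:].astype(np.float32).mean(axis=0)


def _box_sum(arr: np.ndarray, b: int) -> np.ndarray:
    """Sum over non-overlapping b x b boxes; arr shape (..., H, W) with H, W
    multiples of b."""
    s = arr.shape
    arr = arr.reshape(s[:-2] + (s[-2] // b, b, s[-1] // b, b))
    return arr.sum(axis=(-3, -1))


def _fourier_gradients(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spectral spatial derivatives (exact for band-limited textures)."""
    ky = 2j * np.pi * np.fft.fftfreq(image.shape[0])[:, None]
    kx = 2j * np.pi * np.fft.fftfreq(image.shape[1])[None, :]
    spec = np.fft.fft2(image)
    gy = np.fft.ifft2(spec * ky).real.astype(np.float32)
    gx = np.fft.ifft2(spec * kx).real.astype(np.float32)
    return gx, gy


def _gather_patches(padded: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return padded[rows, cols]


def dic_displacements(
    stack: np.ndarray,
    reference: np.ndarray,
    box_size: int = 5,
    search_radius: int = 10,
    *,
    min_contrast: float = 0.2,
    min_texture_std: float = 1.0,
    chunk: int = 16,
) -> DisplacementStack:
    """Block-matching DIC of every frame against the reference image.

    For each box the displacement maximizing the normalized cross-correlation
    over integer shifts within ``search_radius`` is refined to sub-pixel by a
    single gradient-based (Lucas-Kanade) least-squares step against the
    integer-aligned reference patch, using spectrally exact reference
    gradients and a free intensity-offset term.  At a perfect match the
    correction is identically zero, so noise-free integer shifts are
    recovered exactly.  Boxes whose reference patch has standard deviation
    below ``min_texture_std`` gray levels are flagged invalid; frames whose
    peak NCC falls below ``min_contrast`` give NaN for that box.
    """
    if box_size % 2 == 0:
        raise ValueError("box_size must be odd")
    stack = np.asarray(stack)
    ref = np.asarray(reference, dtype=np.float32)
    b, r = box_size, search_radius
    h = (ref.shape[0] // b) * b
    w = (ref.shape[1] // b) * b
    ref = ref[:h, :w]
    nby, nbx = h // b, w // b
    n_px = float(b * b)

    shifts = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)]
    n_shift = len(shifts)
    ref_pad = np.pad(ref, r, mode="edge")
    # reference-patch statistics per candidate displacement (frame independent)
    rs_sum = np.empty((n_shift, nby, nbx), dtype=np.float32)
    rs_var = np.empty_like(rs_sum)
    for si, (dy, dx) in enumerate(shifts):
        view = ref_pad[r - dy : r - dy + h, r - dx : r - dx + w]
        rs_sum[si] = _box_sum(view, b)
        rs_var[si] = _box_sum(view * view, b) - rs_sum[si] ** 2 / n_px
    rs_var = np.clip(rs_var, 0.0, None)

    zero_idx = shifts.index((0, 0))
    valid = rs_var[zero_idx] / n_px >= min_texture_std**2
    # boxes whose search window leaves the image cannot be matched reliably
    bi = np.arange(nby)
    bj = np.arange(nbx)
    in_y = (bi * b - r >= 0) & ((bi + 1) * b + r <= h)
    in_x = (bj * b - r >= 0) & ((bj + 1) * b + r <= w)
    valid &= in_y[:, None] & in_x[None, :]

    gx, gy = _fourier_gradients(ref)
    gx_pad = np.pad(gx, r, mode="edge")
    gy_pad = np.pad(gy, r, mode="edge")
    ref_coeffs = ndimage.spline_filter(ref_pad.astype(float), order=3, mode="mirror")

    base_r = (np.arange(nby) * b)[:, None, None, None] + np.arange(b)[None, None, :, None]
    base_c = (np.arange(nbx) * b)[None, :, None, None] + np.arange(b)[None, None, None, :]

    n_frames = stack.shape[0]
    delta = np.full((n_frames, nby, nbx, 2), np.nan, dtype=np.float32)
    grid = np.arange(-r, r + 1, dtype=np.float32)
    for start in range(0, n_frames, chunk):
        frames = stack[start : start + chunk, :h, :w].astype(np.float32)
        c = frames.shape[0]
        f_sum = _box_sum(frames, b)
        f_var = np.clip(_box_sum(frames * frames, b) - f_sum**2 / n_px, 0.0, None)
        ncc = np.empty((c, nby, nbx, n_shift), dtype=np.float32)
        for si, (dy, dx) in enumerate(shifts):
            view = ref_pad[r - dy : r - dy + h, r - dx : r - dx + w]
            cross = _box_sum(frames * view[None], b)
            num = cross - f_sum * rs_sum[si] / n_px
            den = np.sqrt(f_var * rs_var[si][None]) + 1e-9
            ncc[..., si] = num / den
        best = np.argmax(ncc, axis=-1)
        iy, ix = np.divmod(best, 2 * r + 1)
        peak = np.take_along_axis(ncc, best[..., None], axis=-1)[..., 0]
        dy_int = grid[iy]
        dx_int = grid[ix]

        # gather integer-aligned reference / gradient patches per box
        rows = (r - dy_int.astype(int))[..., None, None] + base_r[None]
        cols = (r - dx_int.astype(int))[..., None, None] + base_c[None]
        r_patch = _gather_patches(ref_pad, rows, cols)
        gx_patch = _gather_patches(gx_pad, rows, cols)
        gy_patch = _gather_patches(gy_pad, rows, cols)
        f_patch = frames.reshape(c, nby, b, nbx, b).transpose(0, 1, 3, 2, 4)

        # one Lucas-Kanade step with a free intensity offset:
        # F - R_d ~= -dx*Gx - dy*Gy + const  (all per-box centred)
        diff = f_patch - r_patch
        diff -= diff.mean(axis=(-2, -1), keepdims=True)
        gx_c = gx_patch - gx_patch.mean(axis=(-2, -1), keepdims=True)
        gy_c = gy_patch - gy_patch.mean(axis=(-2, -1), keepdims=True)
        axx = (gx_c * gx_c).sum(axis=(-2, -1))
        axy = (gx_c * gy_c).sum(axis=(-2, -1))
        ayy = (gy_c * gy_c).sum(axis=(-2, -1))
        b1 = -(gx_c * diff).sum(axis=(-2, -1))
        b2 = -(gy_c * diff).sum(axis=(-2, -1))
        det = axx * ayy - axy * axy
        with np.errstate(invalid="ignore", divide="ignore"):
            off_x = (ayy * b1 - axy * b2) / det
            off_y = (axx * b2 - axy * b1) / det
        bad = ~np.isfinite(off_x) | ~np.isfinite(off_y) | (det <= 0)
        off_x = np.clip(np.where(bad, 0.0, off_x), -1.5, 1.5)
        off_y = np.clip(np.where(bad, 0.0, off_y), -1.5, 1.5)

        # second Gauss-Newton step: re-evaluate the residual against the
        # reference resampled (cubic) at the refined position, reusing the
        # integer-aligned Jacobian; removes the linearization bias when the
        # integer peak jitters by one pixel under noise
        rows_f, cols_f = np.broadcast_arrays(
            rows - off_y[..., None, None], cols - off_x[..., None, None]
        )
        r_shift = ndimage.map_coordinates(
            ref_coeffs,
            [rows_f.ravel(), cols_f.ravel()],
            order=3,
            prefilter=False,
            mode="nearest",
        ).reshape(rows_f.shape)
        diff2 = f_patch - r_shift
        diff2 -= diff2.mean(axis=(-2, -1), keepdims=True)
        b1 = -(gx_c * diff2).sum(axis=(-2, -1))
        b2 = -(gy_c * diff2).sum(axis=(-2, -1))
        with np.errstate(invalid="ignore", divide="ignore"):
            off_x2 = (ayy * b1 - axy * b2) / det
            off_y2 = (axx * b2 - axy * b1) / det
        ok2 = np.isfinite(off_x2) & np.isfinite(off_y2) & ~bad
        off_x = np.clip(off_x + np.where(ok2, off_x2, 0.0), -1.5, 1.5)
        off_y = np.clip(off_y + np.where(ok2, off_y2, 0.0), -1.5, 1.5)

        ok = (peak >= min_contrast) & valid[None]
        delta[start : start + c, ..., 0] = np.where(ok, dx_int + off_x, np.nan)
        delta[start : start + c, ..., 1] = np.where(ok, dy_int + off_y, np.nan)

    centers_x = (np.arange(nbx) * b + (b - 1) / 2.0).astype(float)
    centers_y = (np.arange(nby) * b + (b - 1) / 2.0).astype(float)
    return DisplacementStack(
        delta=delta,
        valid=valid,
        box_size=b,
        box_centers_x=centers_x,
        box_centers_y=centers_y,
    )


def homodyne_displacement(
    dstack: DisplacementStack,
    schedule: StrobeSchedule,
    f0: float,
    *,
    n_pulses: int | None = None,
    max_invalid_fraction: float = 0.05,
    pixel_pitch_um: float | None = None,
) -> HomodyneDisplacementMap:
    """Homodyne detection of the per-box displacement series.

    Uses the first ``n_pulses`` frames (the reconstructed oscillation record).
    Boxes with more than ``max_invalid_fraction`` NaN frames are invalidated;
    remaining sparse NaNs are filled with the box's mean displacement before
    the projection (a NaN-free series is required by the FFT).
    """
    n_t = dstack.delta.shape[0] if n_pulses is None else min(n_pulses, dstack.delta.shape[0])
    series = dstack.delta[:n_t].astype(float)
    times = schedule.sample_times[:n_t]
    nan_frac = np.isnan(series[..., 0]).mean(axis=0)
    valid = dstack.valid & (nan_frac <= max_invalid_fraction)
    out = []
    for k in range(2):
        x = series[..., k].copy()
        finite = np.isfinite(x)
        counts = np.maximum(finite.sum(axis=0), 1)
        mean = np.where(finite, x, 0.0).sum(axis=0) / counts
        bad = np.isnan(x)
        x[bad] = np.broadcast_to(mean, x.shape)[bad]
        coef = homodyne_coefficient(x, times, f0, axis=0)
        out.append(np.where(valid, coef, np.nan + 0j))
    return HomodyneDisplacementMap(
        delta_x=out[0],
        delta_y=out[1],
        valid=valid,
        box_size=dstack.box_size,
        box_centers_x=dstack.box_centers_x,
        box_centers_y=dstack.box_centers_y,
        pixel_pitch_um=pixel_pitch_um,
    )


def warp_to_fluorescence(
    field: np.ndarray,
    affine: np.ndarray,
    out_shape: tuple[int, int],
    *,
    box_centers_x: np.ndarray | None = None,
    box_centers_y: np.ndarray | None = None,
) -> np.ndarray:
    """Resample a (possibly complex) fast-camera field onto the fluorescence grid.

    ``affine`` is the 2x3 transform taking fast-camera (x, y) px to
    fluorescence (x, y) px; real and imaginary parts are interpolated
    bilinearly and NaNs are kept out of the output by validity-mask warping.
    If box-centre coordinates are given, the field is understood to live on
    the DIC-box grid and is sampled accordingly.
    """
    affine = np.asarray(affine, dtype=float)
    lin = affine[:, :2]
    if abs(np.linalg.det(lin)) < 1e-12:
        raise ValueError("affine transform is singular")
    inv = np.linalg.inv(lin)
    xf, yf = np.meshgrid(np.arange(out_shape[1]), np.arange(out_shape[0]))
    src = np.stack([xf.ravel() - affine[0, 2], yf.ravel() - affine[1, 2]])
    xs, ys = inv @ src
    if box_centers_x is not None:
        sx = box_centers_x[1] - box_centers_x[0] if box_centers_x.size > 1 else 1.0
        sy = box_centers_y[1] - box_centers_y[0] if box_centers_y.size > 1 else 1.0
        xs = (xs - box_centers_x[0]) / sx
        ys = (ys - box_centers_y[0]) / sy
    coords = [ys.reshape(out_shape), xs.reshape(out_shape)]

    def _interp(component: np.ndarray) -> np.ndarray:
        finite = np.isfinite(component)
        filled = np.where(finite, component, 0.0)
        val = ndimage.map_coordinates(filled, coords, order=1, mode="constant", cval=0.0)
        cov = ndimage.map_coordinates(
            finite.astype(float), coords, order=1, mode="constant", cval=0.0
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            out = val / cov
        out[cov < 0.99] = np.nan
        return out

    if np.iscomplexobj(field):
        return _interp(field.real) + 1j * _interp(field.imag)
    return _interp(np.asarray(field, dtype=float))
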