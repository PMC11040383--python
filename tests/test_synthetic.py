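"""Forward model: ground-truth construction and rendering."""

import numpy as np
import pytest
from scipy import ndimage

import strobomech as sm
from strobomech.synthetic import (
    _stress_at_cell,
    flow_phasor_at,
    ground_truth_displacement,
    label_image,
)


def analytic_recovery(scene, delta_um, erode=3):
    """Independent oracle: apply the strain/compliance sums by central
    differences to the displacement field and invert for each cell's G."""
    labels = label_image(scene)
    pitch = scene.pixel_pitch_um
    ddx_dy, ddx_dx = np.gradient(delta_um[0], pitch, pitch)
    ddy_dy, ddy_dx = np.gradient(delta_um[1], pitch, pitch)
    recovered = []
    for idx, cell in enumerate(scene.cells, start=1):
        sx, sy = _stress_at_cell(scene, cell)
        inner = ndimage.binary_erosion(labels == idx, iterations=erode)
        with np.errstate(invalid="ignore", divide="ignore"):
            inv_gp = ddx_dx / sx + ddy_dy / sy
            inv_gs = ddx_dy / sx + ddy_dx / sy
            g = 2.0 / (inv_gp + inv_gs)
        vals = g[inner]
        recovered.append(np.median(vals.real) + 1j * np.median(vals.imag))
    return np.array(recovered)


def scene_with_moduli(moduli, radius=18.0, spacing=64.0, **kwargs):
    n = len(moduli)
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    cells = tuple(
        sm.CellSpec(
            center=((i // ncols + 0.5) * spacing, (i % ncols + 0.5) * spacing),
            radius_px=radius,
            modulus=m,
        )
        for i, m in enumerate(moduli)
    )
    shape = (int(nrows * spacing), int(ncols * spacing))
    return sm.SceneSpec(shape=shape, cells=cells, **kwargs)


class TestGroundTruthDisplacement:
    def test_closed_form_recovery_many_random_cells(self):
        rng = np.random.default_rng(7)
        mags = rng.uniform(1e3, 10e3, size=20)
        phases = rng.uniform(0, np.pi / 2, size=20)
        moduli = mags * np.exp(1j * phases)
        scene = scene_with_moduli(moduli)
        delta = ground_truth_displacement(scene)
        rec = analytic_recovery(scene, delta)
        assert np.all(np.abs(rec - moduli) <= 1e-6 * np.abs(moduli))

    def test_purely_imaginary_modulus_gives_quadrature_gradients(self):
        # viscous material: strain lags stress by pi/2
        scene = scene_with_moduli([5e3 * 1j])
        delta = ground_truth_displacement(scene)
        sx, _ = _stress_at_cell(scene, scene.cells[0])
        pitch = scene.pixel_pitch_um
        _, ddx_dx = np.gradient(delta[0], pitch, pitch)
        inner = ndimage.binary_erosion(label_image(scene) == 1, iterations=3)
        rel_phase = np.angle(np.median(ddx_dx[inner] / sx))
        assert rel_phase == pytest.approx(-np.pi / 2, abs=1e-9)

    def test_soft_center_halves_the_central_modulus(self):
        scene = scene_with_moduli([6e3 + 6e3j], radius=24.0, spacing=96.0)
        scene = sm.SceneSpec(
            shape=scene.shape,
            cells=(
                sm.CellSpec(center=(48.0, 48.0), radius_px=24.0, modulus=6e3 + 6e3j, soft_center=0.5),
            ),
        )
        delta = ground_truth_displacement(scene)
        labels = label_image(scene)
        pitch = scene.pixel_pitch_um
        sx, sy = _stress_at_cell(scene, scene.cells[0])
        ddx_dy, ddx_dx = np.gradient(delta[0], pitch, pitch)
        ddy_dy, ddy_dx = np.gradient(delta[1], pitch, pitch)
        with np.errstate(invalid="ignore", divide="ignore"):
            g = 2.0 / (ddx_dx / sx + ddy_dy / sy + ddx_dy / sx + ddy_dx / sy)
        centre = np.abs(g[48, 48])
        rim = np.abs(g[48, 48 + 20])
        g0 = abs(6e3 + 6e3j)
        # radial profile G(r) = G * (1 - soft * (1 - (r/R)^2))
        assert centre == pytest.approx(0.5 * g0, rel=0.05)
        assert rim == pytest.approx(g0 * (1 - 0.5 * (1 - (20 / 24) ** 2)), rel=0.05)
        assert rim > centre

    def test_zero_flow_with_cells_is_an_error(self):
        scene = scene_with_moduli([5e3], flow_velocity=(0j, 0j))
        with pytest.raises(ValueError, match="zero stress"):
            ground_truth_displacement(scene)

    def test_field_vanishes_far_from_cells(self):
        scene = scene_with_moduli([5e3 + 2e3j])
        delta = ground_truth_displacement(scene)
        far = ndimage.distance_transform_edt(label_image(scene) == 0) > scene.taper_outer_px + 2
        assert np.abs(delta[:, far]).max() == 0.0


class TestRenderStrobeStack:
    def test_null_motion_gives_identical_frames(self):
        scene = sm.SceneSpec(shape=(96, 96), cells=(), n_beads=0, noise_sigma=0.0)
        cfg = sm.PulseTrainConfig(f0=30e3, alpha=10e3, n_pulses=40)
        stack, _, _, _ = sm.render_strobe_stack(scene, config=cfg, with_beads=False)
        assert np.all(stack == stack[0])

    def test_deterministic_under_fixed_seed(self):
        scene = sm.two_population_scene(seed=9, shape=(96, 96), n_cells=2, n_beads=8)
        cfg = sm.PulseTrainConfig(f0=30e3, alpha=10e3, n_pulses=60)
        a = sm.render_strobe_stack(scene, config=cfg)
        b = sm.render_strobe_stack(scene, config=cfg)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1], b[1])

    def test_noise_seed_changes_noise_not_geometry(self):
        base = sm.two_population_scene(seed=9, shape=(96, 96), n_cells=2, n_beads=8)
        other = sm.two_population_scene(seed=9, shape=(96, 96), n_cells=2, n_beads=8, noise_seed=77)
        assert np.array_equal(label_image(base), label_image(other))
        cfg = sm.PulseTrainConfig(f0=30e3, alpha=10e3, n_pulses=60)
        a = sm.render_strobe_stack(base, config=cfg)
        b = sm.render_strobe_stack(other, config=cfg)
        assert not np.array_equal(a[0], b[0])
        # ground-truth bead geometry identical
        assert np.allclose(
            a[2].groupby("id")[["x_px", "y_px"]].mean(),
            b[2].groupby("id")[["x_px", "y_px"]].mean(),
        )

    def test_bead_oscillation_amplitude_matches_harmonic_motion(self):
        # |displacement| = |v| / (2 pi f0): 1 m/s at 30 kHz -> 5.3 um
        scene = sm.SceneSpec(
            shape=(96, 96), cells=(), n_beads=1, flow_velocity=(1.0 + 0j, 0j), noise_sigma=0.0
        )
        cfg = sm.PulseTrainConfig(f0=30e3, alpha=10e3, n_pulses=1000)
        _, _, tracks, _ = sm.render_strobe_stack(scene, config=cfg)
        x = tracks[tracks["id"] == 0].sort_values("frame")["x_px"].to_numpy()
        measured_um = (x.max() - x.min()) / 2 * scene.pixel_pitch_um
        expected_um = 1.0 / (2 * np.pi * 30e3) * 1e6
        assert expected_um == pytest.approx(5.305, abs=0.01)
        # discrete sampling under the Gaussian envelope shaves a little off the peak
        assert measured_um == pytest.approx(expected_um, rel=0.03)


class TestRenderFluorescence:
    def test_threshold_recovers_single_cell_mask(self):
        scene = sm.SceneSpec(
            shape=(128, 128),
            cells=(sm.CellSpec(center=(64.0, 64.0), radius_px=25.0, channel="green"),),
            n_beads=0,
        )
        stacks, affine, shape_fluo = sm.render_fluorescence(
            scene, n_images=10, background=False, noise_sigma=0.0
        )
        mask = sm.segment_channel(stacks["green"])
        from strobomech.synthetic import _warp_mask_to_fluo

        truth = _warp_mask_to_fluo((label_image(scene) > 0).astype(float), affine, shape_fluo) > 0.5
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou > 0.95

    def test_overlapping_cells_bright_in_both_channels(self):
        cells = (
            sm.CellSpec(center=(64.0, 56.0), radius_px=20.0, channel="green"),
            sm.CellSpec(center=(64.0, 76.0), radius_px=20.0, channel="orange"),
        )
        scene = sm.SceneSpec(shape=(128, 128), cells=cells, n_beads=0)
        stacks, affine, shape_fluo = sm.render_fluorescence(
            scene, n_images=10, background=False, noise_sigma=0.0
        )
        overlap_fast = (label_image(scene) == 0) * 0
        labels = label_image(scene)
        # pixels of the second cell that sit within the first cell's ellipse
        rows, cols = np.mgrid[0:128, 0:128].astype(float)
        from strobomech.synthetic import _ellipse_r2

        both = (_ellipse_r2(cells[0], rows, cols) <= 0.8) & (
            _ellipse_r2(cells[1], rows, cols) <= 0.8
        )
        assert both.any()
        ys, xs = np.nonzero(both)
        lin, off = affine[:, :2], affine[:, 2]
        pts = np.stack([xs, ys], axis=1) @ lin.T + off
        xi, yi = np.round(pts[:, 0]).astype(int), np.round(pts[:, 1]).astype(int)
        for ch in ("green", "orange"):
            assert np.all(stacks[ch][0][yi, xi] > 600)

    def test_requires_at_least_one_image(self):
        scene = sm.SceneSpec(shape=(64, 64), cells=())
        with pytest.raises(ValueError):
            sm.render_fluorescence(scene, n_images=0)


class TestSceneBuilders:
    def test_two_population_medians_are_exact(self):
        scene = sm.two_population_scene(seed=4, shape=(256, 256), n_cells=18)
        mags = {"green": [], "orange": []}
        for c in scene.cells:
            mags[c.channel].append(abs(c.modulus))
        assert np.median(mags["green"]) == pytest.approx(4400.0, rel=1e-9)
        assert np.median(mags["orange"]) == pytest.approx(6300.0, rel=1e-9)

    def test_flow_ramp_varies_linearly(self):
        scene = sm.SceneSpec(shape=(100, 100), flow_ramp=(0.5, 0.0))
        ux_l, _ = flow_phasor_at(scene, np.array(0.0), np.array(50.0))
        ux_r, _ = flow_phasor_at(scene, np.array(100.0), np.array(50.0))
        assert abs(ux_r) > abs(ux_l)
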