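"""Bead detection, linking, homodyne flow and stress estimation."""

import numpy as np
import pandas as pd
import pytest

import strobomech as sm
from strobomech.synthetic import _draw_bead


def bead_frame(positions, shape=(128, 128), r0=3.0, depth=90.0, noise=0.0, seed=0):
    frame = np.full(shape, 140.0)
    for x, y in positions:
        _draw_bead(frame, x, y, r0, depth)
    if noise:
        frame += noise * np.random.default_rng(seed).standard_normal(shape)
    return frame


def strobe_times(n, f_repet=1000.0):
    cfg = sm.PulseTrainConfig(f0=30e3, alpha=10e3, n_pulses=n, f_repet=f_repet)
    return sm.strobe_schedule(cfg).sample_times[:n]


def synthetic_tracks(amplitudes_px, rest_positions, n_frames=200, f0=30e3):
    """TrackSet with x-displacement A_i * sin(2 pi f0 t_n) per particle."""
    t = strobe_times(n_frames)
    rows = []
    for pid, (amp, (x0, y0)) in enumerate(zip(amplitudes_px, rest_positions)):
        xs = x0 + amp * np.sin(2 * np.pi * f0 * t)
        for n in range(n_frames):
            rows.append((n, pid, xs[n], y0))
    table = pd.DataFrame(rows, columns=["frame", "id", "x_px", "y_px"])
    return sm.TrackSet(table=table, n_frames=n_frames)


class TestDetectBeads:
    def test_subpixel_accuracy_noise_free(self):
        truth = [(30.3, 40.7), (80.6, 25.2), (60.1, 90.9)]
        found = sm.detect_beads(bead_frame(truth), radius_px=3.0)
        assert found.shape[0] == 3
        for x, y in truth:
            d = np.min(np.hypot(found[:, 0] - x, found[:, 1] - y))
            assert d < 0.1

    def test_blank_frame_yields_nothing(self):
        frame = np.full((128, 128), 140.0) + np.random.default_rng(0).normal(0, 3, (128, 128))
        assert sm.detect_beads(frame, radius_px=3.0).shape[0] == 0

    def test_touching_beads_are_merged_not_tripled(self):
        found = sm.detect_beads(bead_frame([(64.0, 64.0), (65.0, 64.0)]), radius_px=3.0)
        assert found.shape[0] <= 2


class TestLinkTracks:
    def test_oscillating_beads_stay_linked(self):
        rng = np.random.default_rng(1)
        rest = np.stack([rng.uniform(20, 108, 6), rng.uniform(20, 108, 6)], axis=1)
        t = strobe_times(50)
        frames = []
        for n in range(50):
            dx = 2.0 * np.sin(2 * np.pi * 30e3 * t[n])
            frames.append(rest + np.array([dx, 0.0]))
        tracks = sm.link_tracks(frames)
        assert tracks.complete_ids.size == 6
        # identities stable: each track's spread stays near its rest point
        for tid in tracks.complete_ids:
            pos = tracks.positions(tid)
            assert np.ptp(pos[:, 0]) <= 4.5
            assert np.ptp(pos[:, 1]) == 0.0

    def test_single_frame_gives_unit_tracks(self):
        tracks = sm.link_tracks([np.array([[10.0, 10.0], [50.0, 50.0]])])
        assert tracks.ids.size == 2
        assert tracks.complete_ids.size == 2

    def test_lost_particle_flagged_incomplete(self):
        full = np.array([[10.0, 10.0], [50.0, 50.0], [90.0, 90.0]])
        frames = [full, full, full[:2], full[:2]]
        tracks = sm.link_tracks(frames)
        assert tracks.complete_ids.size == 2
        assert tracks.ids.size >= 3


class TestHomodyneFlow:
    def test_uniform_oscillation_gives_uniform_velocity(self):
        rest = [(x, y) for x in (30, 60, 90) for y in (30, 60, 90)]
        rest = rest * 3  # 27 tracks, >= 5 everywhere for n = 1 or 2
        amp = 2.0
        tracks = synthetic_tracks([amp] * len(rest), rest)
        sch = sm.strobe_schedule(sm.PulseTrainConfig(f0=30e3, alpha=10e3, n_pulses=200))
        flow = sm.homodyne_flow(tracks, sch, 30e3, (128, 128), pixel_pitch_um=0.5)
        expected = amp * 0.5e-6 * 2 * np.pi * 30e3
        assert np.allclose(np.abs(flow.u_x), expected, rtol=1e-6)
        assert np.allclose(np.abs(flow.u_y), 0.0, atol=1e-12)
        # displacement ~ sin -> velocity phasor is real positive
        assert np.allclose(np.angle(flow.u_x), 0.0, atol=1e-6)

    def test_linear_ramp_recovered_by_interpolation(self):
        grid = np.linspace(16.0, 284.0, 9)
        rest = [(x, y) for x in grid for y in grid]
        amps = [1.0 + 2.0 * x / 300.0 for x, _ in rest]
        tracks = synthetic_tracks(amps, rest)
        sch = sm.strobe_schedule(sm.PulseTrainConfig(f0=30e3, alpha=10e3, n_pulses=200))
        flow = sm.homodyne_flow(tracks, sch, 30e3, (300, 300), pixel_pitch_um=0.5, n_grid=3)
        conv = 0.5e-6 * 2 * np.pi * 30e3
        # the spline interpolates between sub-FOV centres (extrapolation
        # outside their hull is deliberately constant)
        for (x, y), amp in zip(rest, amps):
            if not (50.0 <= x <= 250.0 and 50.0 <= y <= 250.0):
                continue
            ux, _ = flow.at(np.array(x), np.array(y))
            assert abs(ux) == pytest.approx(amp * conv, rel=0.05)

    def test_forced_single_cell_grid_is_global_average(self):
        rest = [(20.0 + 10 * i, 50.0) for i in range(8)]
        amps = [1.0 + 0.2 * i for i in range(8)]
        tracks = synthetic_tracks(amps, rest)
        sch = sm.strobe_schedule(sm.PulseTrainConfig(f0=30e3, alpha=10e3, n_pulses=200))
        flow = sm.homodyne_flow(tracks, sch, 30e3, (128, 128), pixel_pitch_um=0.5, n_grid=1)
        assert flow.n_grid == 1
        assert np.unique(np.round(np.abs(flow.u_x), 12)).size == 1

    def test_too_few_tracks_is_an_error(self):
        tracks = synthetic_tracks([1.0], [(50.0, 50.0)], n_frames=20)
        sch = sm.strobe_schedule(sm.PulseTrainConfig(f0=30e3, alpha=10e3, n_pulses=20))
        with pytest.raises(ValueError, match="tracers"):
            sm.homodyne_flow(tracks, sch, 30e3, (128, 128), pixel_pitch_um=0.5)


class TestStressField:
    def test_magnitude_from_viscous_gradient(self):
        # |u| = 1 m/s, mu = 1.002 mPa s, R_b = 1.5 um -> ~668 Pa
        flow = sm.HomodyneFlowField(
            u_x=np.full((4, 4), 1.0 + 0j),
            u_y=np.zeros((4, 4), complex),
            subfov_u=np.zeros((1, 1, 2), complex),
            centers_x=np.array([2.0]),
            centers_y=np.array([2.0]),
            n_grid=1,
            f0=30e3,
            pixel_pitch_um=0.5,
        )
        stress = sm.stress_field(flow, mu=1.002e-3, bead_radius_m=1.5e-6)
        assert np.allclose(np.abs(stress.sigma_x), 668.0, atol=0.5)
        assert np.allclose(stress.sigma_y, 0.0)

    def test_phase_passes_through(self):
        phi = 0.7
        flow = sm.HomodyneFlowField(
            u_x=np.full((2, 2), np.exp(1j * phi)),
            u_y=np.zeros((2, 2), complex),
            subfov_u=np.zeros((1, 1, 2), complex),
            centers_x=np.array([1.0]),
            centers_y=np.array([1.0]),
            n_grid=1,
            f0=30e3,
            pixel_pitch_um=0.5,
        )
        stress = sm.stress_field(flow, mu=1e-3, bead_radius_m=1.5e-6)
        assert np.allclose(np.angle(stress.sigma_x), phi)

    def test_rejects_bad_radius(self):
        flow = sm.HomodyneFlowField(
            u_x=np.zeros((2, 2), complex),
            u_y=np.zeros((2, 2), complex),
            subfov_u=np.zeros((1, 1, 2), complex),
            centers_x=np.array([1.0]),
            centers_y=np.array([1.0]),
            n_grid=1,
            f0=30e3,
            pixel_pitch_um=0.5,
        )
        with pytest.raises(ValueError):
            sm.stress_field(flow, mu=1e-3, bead_radius_m=0.0)


class TestFlowResiduals:
    def test_self_consistent_uniform_flow_has_zero_residual(self):
        rest = [(20.0 + 15 * i, 30.0 + 9 * i) for i in range(6)]
        tracks = synthetic_tracks([2.0] * 6, rest)
        sch = sm.strobe_schedule(sm.PulseTrainConfig(f0=30e3, alpha=10e3, n_pulses=200))
        flow = sm.homodyne_flow(tracks, sch, 30e3, (128, 128), pixel_pitch_um=0.5, n_grid=1)
        rel, per_track = sm.flow_residuals(tracks, flow, sch)
        assert rel < 1e-9
        assert not per_track["outlier"].any()

    def test_outlier_track_dominates_and_is_flagged(self):
        rest = [(15.0 + 12 * i, 40.0) for i in range(9)]
        amps = [2.0] * 8 + [20.0]
        tracks = synthetic_tracks(amps, rest)
        sch = sm.strobe_schedule(sm.PulseTrainConfig(f0=30e3, alpha=10e3, n_pulses=200))
        flow = sm.homodyne_flow(tracks, sch, 30e3, (128, 128), pixel_pitch_um=0.5, n_grid=1)
        rel, per_track = sm.flow_residuals(tracks, flow, sch)
        assert per_track["outlier"].sum() == 1
        flagged = per_track.loc[per_track["outlier"], "id"].iloc[0]
        assert flagged == 8
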