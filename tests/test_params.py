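"""The six behavioral parameters against brute-force and analytic oracles."""

import numpy as np
import pytest

import zetafish as zf
from zetafish.params import (
    compute_area,
    compute_circling,
    compute_distance_to_inflow,
    compute_speed,
    compute_zlevel,
    detect_surface_events,
    ParameterPanel,
)


def _traj(pos, fps=30.0):
    pos = np.asarray(pos, dtype=float)
    t = np.arange(len(pos)) / fps
    return zf.Trajectory(fish_id="f", fps=fps, t=t, pos=pos)


# ---------------------------------------------------------------- speed


def test_speed_static_fish_is_zero():
    traj = _traj(np.tile([3.0, 2.0, 1.0], (50, 1)))
    assert np.all(compute_speed(traj) == 0.0)


def test_speed_constant_displacement():
    # 0.1 cm per frame at 30 fps -> 3 cm/s
    pos = np.column_stack([np.arange(40) * 0.1, np.full(40, 2.0), np.full(40, 1.0)])
    speed = compute_speed(_traj(pos))
    assert speed == pytest.approx(3.0)


def test_speed_matches_bruteforce_oracle(random_trajectory):
    speed = compute_speed(random_trajectory)
    pos = random_trajectory.pos
    expected = [
        np.sqrt(((pos[i] - pos[i - 1]) ** 2).sum()) * 30.0 for i in range(1, len(pos))
    ]
    assert np.allclose(speed[1:], expected, rtol=1e-12, atol=0)
    assert speed[0] == speed[1]


def test_speed_nonuniform_timestamps_rejected(geometry):
    traj = _traj(np.zeros((10, 3)))
    traj.t[5] += 0.01
    with pytest.raises(ValueError, match="uniform"):
        compute_speed(traj)


# ---------------------------------------------------------------- z-level


def test_zlevel_endpoints_and_arithmetic(geometry):
    traj = _traj([[1, 1, 0.0], [1, 1, 6.0], [1, 1, 4.2]])
    zl = compute_zlevel(traj, geometry)
    assert zl == pytest.approx([0.0, 1.0, 0.7])


def test_zlevel_clipped_above_surface(geometry):
    traj = _traj([[1, 1, 6.3], [1, 1, 3.0]])
    zl = compute_zlevel(traj, geometry)
    assert zl[0] == 1.0


# ---------------------------------------------------------------- area


def test_area_ring_center_inside_far_corner_outside(geometry):
    rx, ry = geometry.ring_center
    traj = _traj([[rx, ry, 1.0], [geometry.length_cm - 0.1, geometry.width_cm - 0.1, 1.0]])
    assert compute_area(traj, geometry).tolist() == [1.0, 0.0]


def test_area_matches_point_in_rectangle_oracle(geometry, random_trajectory):
    area = compute_area(random_trajectory, geometry)
    x0, y0, x1, y1 = geometry.reward_zone
    for i in range(len(random_trajectory)):
        x, y, _ = random_trajectory.pos[i]
        assert area[i] == float(x0 <= x <= x1 and y0 <= y <= y1)


def test_area_boundary_is_closed(geometry):
    x1 = geometry.reward_zone[2]
    traj = _traj([[x1, 1.0, 1.0]])
    assert compute_area(traj, geometry)[0] == 1.0


# ---------------------------------------------------------------- surface events


def _excursion(geometry, n_events, inside_ring=True, fps=30.0):
    """Trajectory with n separated above-threshold excursions."""
    rx, ry = geometry.ring_center if inside_ring else (geometry.length_cm - 1.0, 1.0)
    z_lo, z_hi = 2.0, 5.0  # threshold at 4.2
    frames = []
    for _ in range(n_events):
        frames += [z_lo] * 30 + [z_hi] * 15 + [z_lo] * 30
    z = np.array(frames)
    pos = np.column_stack([np.full_like(z, rx), np.full_like(z, ry), z])
    return _traj(pos, fps)


def test_no_surface_events_below_threshold(geometry):
    traj = _traj(np.tile([2.5, 2.4, 3.0], (100, 1)))
    assert detect_surface_events(traj, geometry).sum() == 0


@pytest.mark.parametrize("k", [1, 3, 5])
def test_surface_event_count_exact(geometry, k):
    traj = _excursion(geometry, k)
    assert detect_surface_events(traj, geometry).sum() == k


def test_excursion_outside_ring_not_counted(geometry):
    traj = _excursion(geometry, 3, inside_ring=False)
    assert detect_surface_events(traj, geometry).sum() == 0


def test_surface_hysteresis_single_event_per_excursion(geometry):
    """One long noisy excursion that never re-crosses downward counts once
    (run-length oracle)."""
    rng = np.random.default_rng(0)
    thr = geometry.surface_threshold_cm
    z = np.concatenate([np.full(30, 2.0), thr + 0.5 + 0.3 * rng.uniform(size=60), np.full(30, 2.0)])
    rx, ry = geometry.ring_center
    traj = _traj(np.column_stack([np.full_like(z, rx), np.full_like(z, ry), z]))
    events = detect_surface_events(traj, geometry)
    above = z >= thr
    runs = np.sum(np.diff(above.astype(int)) == 1)
    assert events.sum() == runs == 1


# ---------------------------------------------------------------- distance


def test_distance_at_and_near_inflow(geometry):
    ix, iy, iz = geometry.inflow_pos
    traj = _traj([[ix, iy, iz], [ix + 3.0, iy, iz]])
    d = compute_distance_to_inflow(traj, geometry)
    assert d == pytest.approx([0.0, 3.0])


def test_distance_matches_bruteforce_oracle(geometry, random_trajectory):
    d = compute_distance_to_inflow(random_trajectory, geometry)
    inflow = np.array(geometry.inflow_pos)
    expected = [np.sqrt(((p - inflow) ** 2).sum()) for p in random_trajectory.pos]
    assert np.allclose(d, expected, rtol=1e-12, atol=0)


def test_speed_and_distance_translation_invariant(geometry, random_trajectory):
    """Rigid translation applied to trajectory and geometry together leaves
    Speed and Distance unchanged."""
    shift = np.array([2.0, -1.0, 0.5])
    traj2 = zf.Trajectory(
        "f", random_trajectory.fps, random_trajectory.t, random_trajectory.pos + shift
    )
    ix, iy, iz = geometry.inflow_pos
    geo2 = zf.TankGeometry(
        length_cm=geometry.length_cm + 10,
        width_cm=geometry.width_cm + 10,
        water_height_cm=geometry.water_height_cm + 10,
        inflow_pos=(ix + shift[0], iy + shift[1], iz + shift[2]),
        reward_zone=(0, 0, 10, 19.5),
    )
    assert np.allclose(compute_speed(random_trajectory), compute_speed(traj2))
    assert np.allclose(
        compute_distance_to_inflow(random_trajectory, geometry),
        compute_distance_to_inflow(traj2, geo2),
    )


# ---------------------------------------------------------------- circling


def _x_traj(x, fps=30.0):
    x = np.asarray(x, dtype=float)
    pos = np.column_stack([x, np.full_like(x, 2.0), np.full_like(x, 2.0)])
    return _traj(pos, fps)


def test_circling_low_freq_sinusoid_high_power():
    t = np.arange(90 * 30) / 30.0
    traj = _x_traj(10 + 5 * np.sin(2 * np.pi * 0.05 * t))
    tb, circ = compute_circling(traj)
    interior = (tb > 16) & (tb < t[-1] - 16)
    assert np.all(circ[interior] > 0.9)


def test_circling_fast_sinusoid_low_power():
    t = np.arange(90 * 30) / 30.0
    traj = _x_traj(10 + 5 * np.sin(2 * np.pi * 1.0 * t))
    _, circ = compute_circling(traj)
    assert np.all(circ < 0.05)


def test_circling_constant_position_defined_zero():
    traj = _x_traj(np.full(40 * 30, 7.0))
    _, circ = compute_circling(traj)
    assert np.all(circ == 0.0)


def test_circling_white_noise_matches_band_fraction():
    """For white noise the expected relative band power equals the band's
    share of the non-DC periodogram bins (Monte-Carlo against analytic)."""
    rng = np.random.default_rng(42)
    vals = []
    for _ in range(20):
        traj = _x_traj(10 + rng.standard_normal(60 * 30))
        _, circ = compute_circling(traj)
        vals.append(circ.mean())
    freqs = np.fft.rfftfreq(900, d=1 / 30.0)
    band = ((freqs >= 0.029) & (freqs <= 0.146)).sum()
    expected = band / (len(freqs) - 1)
    assert np.mean(vals) == pytest.approx(expected, abs=3e-3)


def test_circling_in_unit_interval_on_simulated_fish(geometry):
    sched = zf.TrialSchedule.alternating(n_days=1, trials_per_day_per_stimulus=2,
                                         iti_s=160.0, first_onset_s=160.0)
    traj = zf.simulate_fish(geometry, sched, zf.BehaviorModel(seed=4))
    _, circ = compute_circling(traj)
    assert np.all((circ >= 0) & (circ <= 1))
    assert np.median(circ) > 0.5  # spontaneous behavior is dominated by circling


# ---------------------------------------------------------------- panel


def test_panel_roundtrip_through_tidy_table(geometry, random_trajectory):
    panel = ParameterPanel.from_trajectory(random_trajectory, geometry)
    df = panel.to_frame()
    assert set(df.columns) == {"fish_id", "frame", "t_s", "parameter", "value"}
    panel2 = ParameterPanel.from_frame(df)
    for name, (t, v) in panel.series.items():
        t2, v2 = panel2.series[name]
        assert np.allclose(t, t2) and np.allclose(v, v2)
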