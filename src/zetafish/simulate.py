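"""Synthetic 3D swimming trajectories for an appetitive conditioning tank.

The generator emulates the statistical structure the downstream analysis
assumes: between trials the fish performs stereotyped wall-following
circling at a low frequency (~0.03-0.15 Hz) with stochastic perturbations;
during response windows of rewarded-odor trials it expresses a learned
appetitive repertoire — faster swimming, elevation in the water column,
attraction to the reward zone and inflow tube, discrete surface-sampling
excursions under the feeding ring, and interruption of circling — whose
strength grows over trials with a saturating learning curve.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .config import (
    CS_MINUS,
    CS_PLUS,
    BehaviorModel,
    ScheduleError,
    TankGeometry,
    TrialSchedule,
)
from .trajectory import Trajectory

__all__ = [
    "simulate_fish",
    "simulate_cohort",
    "learning_level",
    "expected_speed_increase",
    "CohortMember",
]

_RAMP_S = 2.0  # rise/fall time of the response envelope
_WALL_MARGIN_CM = 1.0
_EVENT_Z_RISE_S = 1.2  # duration of a surface-sampling z excursion
_EVENT_XY_PAD_S = 0.7  # extra ring-attraction time around the z excursion
_EVENT_MIN_SEP_S = 3.0


def _ou(rng: np.random.Generator, n: int, dt: float, tau_s: float, sd: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path via an AR(1) recursion."""
    if sd == 0.0:
        # keep the stream position identical so seeds stay comparable
        rng.standard_normal(n)
        return np.zeros(n)
    a = math.exp(-dt / tau_s)
    eps = rng.standard_normal(n)
    innov = eps * (sd * math.sqrt(1.0 - a * a))
    innov[0] = eps[0] * sd
    return lfilter([1.0], [1.0, -a], innov)


def _ellipse_perimeter(a: float, b: float) -> float:
    # Ramanujan's approximation; ample for a behavioral generator
    h = 3.0 * (a + b)
    return math.pi * (h - math.sqrt((3.0 * a + b) * (a + 3.0 * b)))


def learning_level(model: BehaviorModel, class_index: int) -> float:
    """Saturating response strength on the ``class_index``-th (1-based) trial
    of a stimulus class: ``1 - exp(-learning_rate * k)``."""
    if class_index < 1:
        return 0.0
    return float(-np.expm1(-model.learning_rate * class_index))


_Z_TAU_S = 5.0  # cruising-depth OU time constant
_Z_SD_CM = 0.35
_NOISE_TAU_S = 0.7


def _orbit(geometry: TankGeometry, model: BehaviorModel) -> tuple[float, float, float]:
    """Wall-following orbit semi-axes and mean path speed (a, b, v_base)."""
    a0 = geometry.length_cm / 2.0 - _WALL_MARGIN_CM
    b0 = geometry.width_cm / 2.0 - _WALL_MARGIN_CM
    f = model.baseline_circle_freq_hz
    v0 = _ellipse_perimeter(a0, b0) * f
    s = float(np.clip(model.baseline_speed_cms / v0, 0.25, 1.0))
    return a0 * s, b0 * s, v0 * s


def _ou_step_sd(sd: float, tau_s: float, fps: float) -> float:
    """Per-second RMS of frame-to-frame displacement of an OU path."""
    return sd * math.sqrt(2.0 * (1.0 - math.exp(-1.0 / (tau_s * fps)))) * fps


def expected_speed_increase(
    model: BehaviorModel,
    level: float,
    duration_s: float,
    geometry: TankGeometry | None = None,
    fps: float = 30.0,
) -> float:
    """Closed-form expected increase of mean measured speed over a
    response window of ``duration_s``, at response strength ``level``.

    The generator advances the orbital phase faster by
    ``response_gains.speed_cms * envelope`` (trapezoidal envelope with
    ``_RAMP_S`` ramps, time average ``level * (1 - ramp/duration)``), so
    the path speed rises additively by that amount. Measured 3D speed also
    carries the vertical cruising-depth fluctuation and positional noise,
    which add in quadrature and compress the apparent increment:
    ``sqrt((v+g)^2 + s^2) - sqrt(v^2 + s^2)``.
    """
    gain = model.response_gains.speed_cms * level * (1.0 - _RAMP_S / duration_s)
    if geometry is None:
        return gain
    _, _, v_base = _orbit(geometry, model)
    var = _ou_step_sd(_Z_SD_CM, _Z_TAU_S, fps) ** 2
    var += 3.0 * _ou_step_sd(model.noise_sd, _NOISE_TAU_S, fps) ** 2
    return math.sqrt((v_base + gain) ** 2 + var) - math.sqrt(v_base**2 + var)


def _response_events(schedule: TrialSchedule, model: BehaviorModel, mode: str):
    """List of (start_s, duration_s, level) behavioral-response episodes."""
    events = []
    if mode == "conditioned":
        counts: dict[str, int] = {}
        for tr in schedule:
            counts[tr.label] = counts.get(tr.label, 0) + 1
            lev = learning_level(model, counts[tr.label])
            if tr.label == CS_MINUS:
                lev *= model.cs_minus_gain_frac
            events.append((tr.onset_s, tr.food_delay_s, lev))
    elif mode == "unpaired":
        # odors predict nothing; feeding behavior is expressed at the food
        # deliveries themselves, which occur on rewarded trials only
        for tr in schedule:
            if tr.rewarded:
                events.append((tr.onset_s + tr.food_delay_s, 30.0, 1.0))
    else:
        raise ValueError(f"unknown simulation mode '{mode}'")
    return events


def _envelope(t: np.ndarray, events, ramp_s: float = _RAMP_S) -> np.ndarray:
    env = np.zeros_like(t)
    for t0, dur, level in events:
        if level <= 0.0:
            continue
        up = np.clip((t - t0) / ramp_s, 0.0, 1.0)
        down = np.clip((t0 + dur - t) / ramp_s, 0.0, 1.0)
        np.maximum(env, level * np.minimum(up, down), out=env)
    return env


def _surface_event_times(
    rng: np.random.Generator, events, rate_hz: float, spont_hz: float, duration_s: float
):
    """Poisson surface-sampling episodes: evoked inside response windows at
    ``rate_hz`` times the response level, plus rare spontaneous episodes at
    ``spont_hz`` throughout the session."""
    cand: list[float] = []
    for t0, dur, level in events:
        lam = rate_hz * level * dur
        if lam <= 0.0:
            continue
        n = int(rng.poisson(lam))
        lo = t0 + 1.0
        hi = t0 + dur - (_EVENT_Z_RISE_S + _EVENT_XY_PAD_S + 0.5)
        if n == 0 or hi <= lo:
            continue
        cand.extend(rng.uniform(lo, hi, size=n).tolist())
    if spont_hz > 0 and duration_s > 10.0:
        n = int(rng.poisson(spont_hz * (duration_s - 10.0)))
        if n:
            cand.extend(rng.uniform(5.0, duration_s - 5.0, size=n).tolist())
    times: list[float] = []
    last = -np.inf
    for c in sorted(cand):
        if c - last >= _EVENT_MIN_SEP_S:
            times.append(float(c))
            last = c
    return times


def simulate_fish(
    geometry: TankGeometry,
    schedule: TrialSchedule,
    model: BehaviorModel,
    fps: float = 30.0,
    fish_id: str = "fish0",
    mode: str = "conditioned",
    duration_s: float | None = None,
    min_pre_onset_s: float = 120.0,
) -> Trajectory:
    """Simulate one fish over an entire trial schedule.

    The trajectory starts at t = 0 and covers every trial's reference,
    baseline and response window (the first onset must leave at least
    ``min_pre_onset_s`` of pre-stimulus recording; shorter schedules are
    rejected with a :class:`ScheduleError`). Identical seeds produce
    bit-identical trajectories.
    """
    if len(schedule) < 1:
        raise ScheduleError("schedule must contain at least one trial")
    first = schedule.trials[0]
    if first.onset_s < min_pre_onset_s:
        raise ScheduleError(
            f"first onset at {first.onset_s:.0f} s leaves no room for the "
            f"reference window (need >= {min_pre_onset_s:.0f} s)"
        )
    events = _response_events(schedule, model, mode)
    last_end = max(tr.onset_s + tr.food_delay_s for tr in schedule)
    if events:
        last_end = max(last_end, max(t0 + d for t0, d, _ in events))
    if duration_s is None:
        duration_s = last_end + 30.0
    n = int(round(duration_s * fps)) + 1
    dt = 1.0 / fps
    t = np.arange(n) * dt
    rng = np.random.default_rng(model.seed)
    g = model.response_gains

    # trial-to-trial variability of response expression (mean-1 gamma)
    cv = model.trial_amplitude_cv
    if cv > 0 and events:
        shape = 1.0 / cv**2
        amps = rng.gamma(shape, scale=cv**2, size=len(events))
        events = [(t0, dur, lev * a) for (t0, dur, lev), a in zip(events, amps)]

    env = _envelope(t, events)

    # --- stereotyped circling along the walls -------------------------------
    a0, b0, v_base = _orbit(geometry, model)
    f = model.baseline_circle_freq_hz

    freq_jitter = _ou(rng, n, dt, tau_s=20.0, sd=0.20)
    amp_jitter = _ou(rng, n, dt, tau_s=30.0, sd=0.05)
    phase0 = rng.uniform(0.0, 2.0 * math.pi)
    direction = 1.0 if rng.uniform() < 0.5 else -1.0

    speed_mult = 1.0 + (g.speed_cms / v_base) * env
    theta = phase0 + direction * 2.0 * math.pi * f * dt * np.cumsum(
        (1.0 + freq_jitter) * speed_mult
    )
    amp = 1.0 + amp_jitter
    cx = geometry.length_cm / 2.0
    cy = geometry.width_cm / 2.0

    # circling suppression: shrink the orbit and replace it with incoherent
    # zigzag swimming above the circling band (~0.4-0.6 Hz)
    wc = np.clip(g.circling * env, 0.0, 0.95)
    zig_phase = _ou(rng, n, dt, tau_s=5.0, sd=1.0)
    wander_x = 3.0 * np.sin(2.0 * math.pi * 0.45 * t + zig_phase)
    wander_y = 1.2 * np.sin(2.0 * math.pi * 0.60 * t + 2.0 * zig_phase)
    x = cx + a0 * amp * (1.0 - wc) * np.cos(theta) + wc * wander_x
    y = cy + b0 * amp * (1.0 - wc) * np.sin(theta) + wc * wander_y

    # z: low cruising depth, elevated during responses
    z0 = 0.35 * geometry.water_height_cm
    z = z0 + g.zlevel_cm * env + _ou(rng, n, dt, tau_s=_Z_TAU_S, sd=_Z_SD_CM)

    # attraction toward the feeding ring (reward-zone occupancy)
    wa = np.clip(g.area * env, 0.0, 0.9)
    rx, ry = geometry.ring_center
    x += wa * (rx - x)
    y += wa * (ry - y)

    # attraction toward the inflow tube
    wi = np.clip(g.inflow * env, 0.0, 0.85)
    ix, iy, iz = geometry.inflow_pos
    x += wi * (ix - x)
    y += wi * (iy - y)
    z += wi * (iz - z)

    # discrete surface-sampling excursions under the ring center
    thr = geometry.surface_threshold_cm
    for te in _surface_event_times(rng, events, g.surface_hz, model.spont_surface_hz, duration_s):
        s0 = te - _EVENT_XY_PAD_S
        s1 = te + _EVENT_Z_RISE_S + _EVENT_XY_PAD_S
        i0, i1 = max(0, int(s0 * fps)), min(n, int(s1 * fps) + 1)
        if i1 <= i0:
            continue
        tt = t[i0:i1]
        w = np.minimum(
            np.clip((tt - s0) / _EVENT_XY_PAD_S, 0.0, 1.0),
            np.clip((s1 - tt) / _EVENT_XY_PAD_S, 0.0, 1.0),
        )
        x[i0:i1] += w * (rx - x[i0:i1])
        y[i0:i1] += w * (ry - y[i0:i1])
        j0, j1 = int(te * fps), min(n, int((te + _EVENT_Z_RISE_S) * fps) + 1)
        if j1 > j0:
            tau = (t[j0:j1] - te) / _EVENT_Z_RISE_S
            zprof = geometry.water_height_cm * (
                geometry.surface_threshold_frac - 0.06 + 0.30 * np.sin(math.pi * np.clip(tau, 0, 1))
            )
            z[j0:j1] = np.maximum(z[j0:j1], zprof)
        # hysteresis guard: start/end of the excursion sit below threshold
        assert thr > 0

    # measurement/positional noise and confinement to the tank
    if model.noise_sd > 0:
        x += _ou(rng, n, dt, tau_s=_NOISE_TAU_S, sd=model.noise_sd)
        y += _ou(rng, n, dt, tau_s=_NOISE_TAU_S, sd=model.noise_sd)
        z += _ou(rng, n, dt, tau_s=_NOISE_TAU_S, sd=model.noise_sd)
    np.clip(x, 0.05, geometry.length_cm - 0.05, out=x)
    np.clip(y, 0.05, geometry.width_cm - 0.05, out=y)
    np.clip(z, 0.02, geometry.water_height_cm, out=z)

    pos = np.column_stack([x, y, z])
    return Trajectory(fish_id=fish_id, fps=fps, t=t, pos=pos)


@dataclass
class CohortMember:
    fish_id: str
    trajectory: Trajectory
    schedule: TrialSchedule
    odor_as_cs_plus: str


def simulate_cohort(
    n_fish: int,
    geometry: TankGeometry,
    model: BehaviorModel,
    scenario: str = "learning",
    seed: int = 0,
    n_days: int = 2,
    trials_per_day_per_stimulus: int = 9,
    iti_s: float = 1200.0,
    first_onset_s: float | None = None,
    food_delay_s: float = 30.0,
    fps: float = 30.0,
) -> list[CohortMember]:
    """Simulate a cohort under one of three study scenarios.

    ``learning``  rewarded/unrewarded odors alternate; the response to the
                  rewarded odor grows with the model's learning rate.
    ``null``      identical schedule but all response gains forced to zero,
                  so CS+ and CS- trials are statistically identical.
    ``unpaired``  odors predict nothing; food arrives ``food_delay_s`` after
                  either odor with probability 0.5, and feeding behavior is
                  expressed at food delivery only. Trials are labeled by
                  odor ('A'/'B') for later balanced random CS assignment.

    Odor identities are balanced: even-numbered fish have odor A as the
    rewarded stimulus, odd-numbered fish odor B.
    """
    if scenario not in ("learning", "null", "unpaired"):
        raise ValueError(f"unknown scenario '{scenario}'")
    root = np.random.default_rng(seed)
    fish_seeds = root.integers(0, 2**31 - 1, size=n_fish)
    reward_rng = np.random.default_rng(root.integers(0, 2**31 - 1))
    eff_model = model
    if scenario == "null":
        eff_model = dataclasses.replace(model, response_gains=model.response_gains.scaled(0.0))

    members: list[CohortMember] = []
    for i in range(n_fish):
        odor_plus = "A" if i % 2 == 0 else "B"
        odor_minus = "B" if odor_plus == "A" else "A"
        if scenario == "unpaired":
            sched = TrialSchedule.alternating(
                n_days=n_days,
                trials_per_day_per_stimulus=trials_per_day_per_stimulus,
                iti_s=iti_s,
                first_onset_s=first_onset_s,
                food_delay_s=food_delay_s,
                first_label="A",
                labels=("A", "B"),
            )
            rewards = reward_rng.uniform(size=len(sched)) < 0.5
            for tr, rew in zip(sched.trials, rewards):
                tr.odor = tr.label
                tr.rewarded = bool(rew)
            mode = "unpaired"
        else:
            first = CS_PLUS if i % 2 == 0 else CS_MINUS
            sched = TrialSchedule.alternating(
                n_days=n_days,
                trials_per_day_per_stimulus=trials_per_day_per_stimulus,
                iti_s=iti_s,
                first_onset_s=first_onset_s,
                food_delay_s=food_delay_s,
                first_label=first,
            )
            for tr in sched.trials:
                tr.odor = odor_plus if tr.label == CS_PLUS else odor_minus
            mode = "conditioned"
        fish_model = dataclasses.replace(eff_model, seed=int(fish_seeds[i]))
        fish_id = f"fish{i:03d}"
        traj = simulate_fish(geometry, sched, fish_model, fps=fps, fish_id=fish_id, mode=mode)
        members.append(CohortMember(fish_id, traj, sched, odor_plus))
    return members
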