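"""Stochastic tri-component gearset simulator.

Model: an ensemble of ``n_motors`` independent rotary units, each a two-state
continuous-time Markov chain over rotational direction (dominant vs minority).
The ensemble drives a belt; while the belt is engaged the cell translates at
constant speed along its heading.  A direction flip of any motor makes the
belt slip: the cell pauses for an exponential re-engagement delay, after which
the heading is redrawn (von Mises around the previous heading, or reversed by
pi with probability ``reversal_prob``) and the run resumes.

The dwell times are parameterized so the stationary probability of the
dominant direction equals ``bias``: with mean dominant dwell ``tau_d`` the
minority dwell mean is ``tau_d * (1 - bias) / bias``, giving
``P(dominant) = tau_d / (tau_d + tau_m) = bias``.

All randomness derives from a single seed; per-motor streams are spawned by
index so the ensemble is reproducible and the belt stream is independent of
the motor count ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .track import Track

__all__ = [
    "GearsetParams",
    "MotorSeries",
    "GearsetResult",
    "simulate_motor_ensemble",
    "simulate_gliding_cell",
    "opposite_fraction",
    "SPEED_PER_REV_UM",
]

#: Derived gear-ratio constant: belt advance per motor revolution, from the
#: wild-type regime (2 um/s gliding at 1.3 Hz rotation).  Not used by the
#: simulator itself; provided for users who want motor-frequency-driven speed.
SPEED_PER_REV_UM = 2.0 / 1.3


@dataclass(frozen=True)
class GearsetParams:
    """Parameters of the motor-ensemble / belt / cell-kinematics simulator."""

    n_motors: int = 10
    bias: float = 0.9
    dominant_direction: int = +1
    mean_dwell_dominant_s: float = 10.0
    run_speed_um_s: float = 2.0
    slip_mean_s: float = 0.5
    turn_kappa: float = 0.0
    reversal_prob: float = 0.5
    diffusion_um2_s: float = 0.0
    engage_rule: str = "any_flip"  # or "majority"
    dt_s: float = 1.0 / 15.0
    duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_motors, (int, np.integer)) and self.n_motors >= 1):
            raise ParameterError(f"n_motors must be an integer >= 1, got {self.n_motors}")
        for name in (
            "bias",
            "mean_dwell_dominant_s",
            "run_speed_um_s",
            "slip_mean_s",
            "turn_kappa",
            "reversal_prob",
            "diffusion_um2_s",
            "dt_s",
            "duration_s",
        ):
            v = getattr(self, name)
            if not math.isfinite(float(v)):
                raise ParameterError(f"{name} must be finite, got {v}")
        if not 0.0 < self.bias <= 1.0:
            raise ParameterError(f"bias must be in (0, 1], got {self.bias}")
        if self.dominant_direction not in (+1, -1):
            raise ParameterError("dominant_direction must be +1 or -1")
        for name in ("mean_dwell_dominant_s", "slip_mean_s", "dt_s", "duration_s"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.run_speed_um_s < 0 or self.turn_kappa < 0 or self.diffusion_um2_s < 0:
            raise ParameterError("run_speed_um_s, turn_kappa, diffusion_um2_s must be >= 0")
        if not 0.0 <= self.reversal_prob <= 1.0:
            raise ParameterError("reversal_prob must be in [0, 1]")
        if self.engage_rule not in ("any_flip", "majority"):
            raise ParameterError("engage_rule must be 'any_flip' or 'majority'")

    @property
    def mean_dwell_minority_s(self) -> float:
        """Minority dwell mean implied by ``bias`` (0 when bias == 1)."""
        return self.mean_dwell_dominant_s * (1.0 - self.bias) / self.bias

    def with_(self, **kw) -> "GearsetParams":
        return replace(self, **kw)


@dataclass
class MotorSeries:
    """Per-motor rotational direction (+1/-1) sampled on a regular grid."""

    times_s: np.ndarray
    directions: np.ndarray  # shape (n_motors, n_times), entries in {+1, -1}

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.directions = np.asarray(self.directions, dtype=np.int8)
        if self.directions.ndim != 2 or self.directions.shape[1] != self.times_s.size:
            raise ValueError("directions must be (n_motors, n_times)")
        if not np.all(np.isin(self.directions, (-1, 1))):
            raise ValueError("directions entries must be +1 or -1")

    @property
    def n_motors(self) -> int:
        return int(self.directions.shape[0])

    def fraction_in_direction(self, direction: int) -> float:
        """Time-and-motor fraction of samples rotating in ``direction``."""
        return float(np.mean(self.directions == direction))


@dataclass
class GearsetResult:
    """Output of :func:`simulate_gliding_cell`."""

    track: Track
    motor_series: MotorSeries
    events: list[tuple[float, str]] = field(default_factory=list)
    params: GearsetParams | None = None


def opposite_fraction(n_motors: int, n_dissenting: int) -> float:
    """Percentage of an ensemble rotating against the consensus.

    ``opposite_fraction(8, 1) == 12.5`` and ``opposite_fraction(12, 1)`` is
    8.33...: the noise-percentage endpoints for one dissenting unit in the
    smallest and largest plausible ensembles.
    """
    if not isinstance(n_motors, (int, np.integer)) or n_motors < 1:
        raise ParameterError(f"n_motors must be an integer >= 1, got {n_motors}")
    if not isinstance(n_dissenting, (int, np.integer)) or not 0 <= n_dissenting <= n_motors:
        raise ParameterError("n_dissenting must satisfy 0 <= n_dissenting <= n_motors")
    return 100.0 * n_dissenting / n_motors


def _time_grid(duration_s: float, dt_s: float) -> np.ndarray:
    n = max(1, int(math.ceil(duration_s / dt_s - 1e-9)))
    return np.linspace(0.0, duration_s, n + 1)


def _spawn_rngs(params: GearsetParams):
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(params.n_motors + 1)
    motor_rngs = [np.random.default_rng(c) for c in children[: params.n_motors]]
    belt_rng = np.random.default_rng(children[-1])
    return motor_rngs, belt_rng


def _motor_flip_times(rng: np.random.Generator, params: GearsetParams):
    """Flip times of one motor over [0, duration], plus its initial state.

    Returns ``(start_dominant, times)``; the motor alternates state at each
    time.  Initial state drawn from the stationary distribution.  At
    ``bias == 1`` the minority dwell is zero, which we take as the absorbing
    limit: the motor never leaves the dominant state and never flips.
    """
    if params.bias >= 1.0:
        return True, np.empty(0)
    tau_d = params.mean_dwell_dominant_s
    tau_m = params.mean_dwell_minority_s
    start_dominant = bool(rng.random() < params.bias)
    times = []
    t = 0.0
    dominant = start_dominant
    while True:
        t += rng.exponential(tau_d if dominant else tau_m)
        if t >= params.duration_s:
            break
        times.append(t)
        dominant = not dominant
    return start_dominant, np.asarray(times)


def _sample_motor(start_dominant: bool, flips: np.ndarray, times: np.ndarray,
                  dominant_direction: int) -> np.ndarray:
    n_flips = np.searchsorted(flips, times, side="right")
    dominant = (n_flips % 2 == 0) == start_dominant
    return np.where(dominant, dominant_direction, -dominant_direction).astype(np.int8)


def simulate_motor_ensemble(params: GearsetParams) -> MotorSeries:
    """Simulate ``n_motors`` independent two-state direction chains.

    Each motor dwells in the dominant direction for Exponential
    (mean ``mean_dwell_dominant_s``) and in the minority direction for
    Exponential (mean ``mean_dwell_dominant_s * (1-bias)/bias``), so the
    stationary probability of the dominant direction is ``bias``.  Sampled on
    a regular grid of step ``dt_s`` over [0, duration_s].
    """
    times = _time_grid(params.duration_s, params.dt_s)
    motor_rngs, _ = _spawn_rngs(params)
    directions = np.empty((params.n_motors, times.size), dtype=np.int8)
    for i, rng in enumerate(motor_rngs):
        start, flips = _motor_flip_times(rng, params)
        directions[i] = _sample_motor(start, flips, times, params.dominant_direction)
    return MotorSeries(times_s=times, directions=directions)


def simulate_gliding_cell(params: GearsetParams) -> GearsetResult:
    """Simulate the full gearset: motors -> belt slips -> run-and-turn track.

    The belt is engaged at t=0 with a uniform random heading.  Under the
    default ``engage_rule='any_flip'`` every motor direction flip while
    engaged triggers a slip; under ``'majority'`` a slip triggers only when
    the instantaneous majority direction changes from the one recorded at the
    last engagement.  During a slip the cell is stationary for an exponential
    delay of mean ``slip_mean_s`` (plus optional Brownian displacement if
    ``diffusion_um2_s > 0``, applied at re-engagement); at re-engagement the
    heading reverses by pi with probability ``reversal_prob``, otherwise it is
    redrawn from a von Mises around the previous heading with concentration
    ``turn_kappa`` (0 = uniform).
    """
    motor_rngs, belt_rng = _spawn_rngs(params)
    starts = []
    flip_lists = []
    for rng in motor_rngs:
        s, f = _motor_flip_times(rng, params)
        starts.append(s)
        flip_lists.append(f)

    # Merge flip events (time, motor index), time-ordered.
    if any(len(f) for f in flip_lists):
        all_times = np.concatenate(flip_lists)
        all_motors = np.concatenate(
            [np.full(len(f), i) for i, f in enumerate(flip_lists)]
        )
        order = np.argsort(all_times, kind="stable")
        all_times = all_times[order]
        all_motors = all_motors[order]
    else:
        all_times = np.empty(0)
        all_motors = np.empty(0, dtype=int)

    duration = params.duration_s
    speed = params.run_speed_um_s
    state = np.array(starts, dtype=bool)  # True = dominant
    dom_count = int(state.sum())

    def majority() -> int:
        # Sign of the instantaneous majority in dominant units; ties go dominant.
        return +1 if 2 * dom_count >= params.n_motors else -1

    heading = float(belt_rng.uniform(-np.pi, np.pi))
    pos = np.zeros(2)
    seg_t0, seg_x0, seg_y0, seg_h, seg_mov = [0.0], [0.0], [0.0], [heading], [True]
    events: list[tuple[float, str]] = []
    engaged = True
    consensus = majority()
    t_re = math.inf
    i = 0
    t = 0.0

    def close_segment(t1: float) -> None:
        nonlocal pos
        t0 = seg_t0[-1]
        if seg_mov[-1]:
            pos = pos + speed * (t1 - t0) * np.array(
                [math.cos(seg_h[-1]), math.sin(seg_h[-1])]
            )

    while True:
        t_flip = all_times[i] if i < all_times.size else math.inf
        if engaged:
            if t_flip >= duration:
                close_segment(duration)
                t = duration
                break
            # apply the flip
            m = all_motors[i]
            dom_count += -1 if state[m] else +1
            state[m] = not state[m]
            i += 1
            trigger = params.engage_rule == "any_flip" or majority() != consensus
            if trigger:
                close_segment(t_flip)
                events.append((float(t_flip), "slip"))
                t_re = t_flip + float(belt_rng.exponential(params.slip_mean_s))
                seg_t0.append(float(t_flip))
                seg_x0.append(float(pos[0]))
                seg_y0.append(float(pos[1]))
                seg_h.append(heading)
                seg_mov.append(False)
                engaged = False
        else:
            if t_flip < t_re:
                if t_flip >= duration:
                    # slip outlives the simulation; still record its re-engagement
                    events.append((float(t_re), "re_engage"))
                    t = duration
                    break
                m = all_motors[i]
                dom_count += -1 if state[m] else +1
                state[m] = not state[m]
                i += 1
                continue
            # re-engage at t_re (possibly beyond duration)
            events.append((float(t_re), "re_engage"))
            if belt_rng.random() < params.reversal_prob:
                heading = _wrap_angle(heading + math.pi)
                events.append((float(t_re), "reversal"))
            elif params.turn_kappa > 0:
                heading = _wrap_angle(float(belt_rng.vonmises(heading, params.turn_kappa)))
            else:
                heading = float(belt_rng.uniform(-np.pi, np.pi))
            if params.diffusion_um2_s > 0:
                sd = math.sqrt(2.0 * params.diffusion_um2_s * (t_re - seg_t0[-1]))
                pos = pos + belt_rng.normal(0.0, sd, size=2)
            if t_re >= duration:
                t = duration
                break
            consensus = majority()
            engaged = True
            seg_t0.append(float(t_re))
            seg_x0.append(float(pos[0]))
            seg_y0.append(float(pos[1]))
            seg_h.append(heading)
            seg_mov.append(True)
            t_re = math.inf

    # Sample the piecewise-linear motion on the regular grid.
    times = _time_grid(duration, params.dt_s)
    seg_t0_a = np.asarray(seg_t0)
    idx = np.clip(np.searchsorted(seg_t0_a, times, side="right") - 1, 0, len(seg_t0) - 1)
    dt_in = times - seg_t0_a[idx]
    mov = np.asarray(seg_mov, dtype=float)[idx]
    h = np.asarray(seg_h)[idx]
    xs = np.asarray(seg_x0)[idx] + mov * speed * dt_in * np.cos(h)
    ys = np.asarray(seg_y0)[idx] + mov * speed * dt_in * np.sin(h)
    track = Track(track_id=0, t_s=times, x_um=xs, y_um=ys, source="simulated")

    directions = np.empty((params.n_motors, times.size), dtype=np.int8)
    for j in range(params.n_motors):
        directions[j] = _sample_motor(
            starts[j], flip_lists[j], times, params.dominant_direction
        )
    series = MotorSeries(times_s=times, directions=directions)
    return GearsetResult(track=track, motor_series=series, events=events, params=params)


def _wrap_angle(a: float) -> float:
    return float((a + math.pi) % (2.0 * math.pi) - math.pi)
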