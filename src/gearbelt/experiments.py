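"""Parameter-recovery experiment protocols on synthetic ground truth.

Each function generates synthetic data with a known ground-truth value,
runs the corresponding analysis pipeline end-to-end, and returns the
recovered quantity.  These protocols back both the acceptance test suite and
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from . import gearset, motility, rotation, spots, synth
from .track import Track

#: Frame geometry used by the recovery experiments: a 12.8 µm field is ample
#: for a 5 µm cell orbiting a ~1 µm tether offset, and keeps rendering fast.
TETHERED_SHAPE = (128, 128)
SPOT_SHAPE = (48, 144)

#: Localization noise (µm) representative of centroiding a ~400-pixel cell
#: body in phase contrast.
GLIDING_NOISE_SD_UM = 0.02


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0]) for c in ss.spawn(n)]


def rotation_recovery(
    signed_freq_hz: float,
    n_videos: int,
    seed: int,
    duration_s: float = 10.0,
    noise_sd: float = 4.0,
) -> rotation.SpeedDistribution:
    """Render tethered videos at a known signed frequency and run the full
    rotation pipeline (extract -> frequency -> distribution)."""
    n_frames = int(round(duration_s * 15))
    meta = synth.VideoMeta(n_frames=n_frames, shape_px=TETHERED_SHAPE)
    records = []
    for i, s in enumerate(_spawn_seeds(seed, n_videos)):
        stack, _ = synth.render_tethered_video(
            signed_freq_hz=signed_freq_hz, meta=meta, noise_sd=noise_sd,
            seed=s, theta0_rad=2.0 * np.pi * i / max(1, n_videos),
        )
        trace = rotation.extract_angle_trace(stack)
        records.append(rotation.rotation_frequency(trace, motor_id=i))
    return rotation.speed_distribution(records)


def add_localization_noise(track: Track, sd_um: float, seed: int) -> Track:
    rng = np.random.default_rng(seed)
    return Track(
        track_id=track.track_id,
        t_s=track.t_s,
        x_um=track.x_um + rng.normal(0.0, sd_um, len(track)),
        y_um=track.y_um + rng.normal(0.0, sd_um, len(track)),
        source=track.source,
    )


def simulate_noisy_population(
    run_speed_um_s: float,
    n_tracks: int,
    seed: int,
    duration_s: float = 60.0,
    mean_dwell_dominant_s: float = 200.0,
    slip_mean_s: float = 0.1,
    reversal_prob: float = 0.5,
    noise_sd_um: float = GLIDING_NOISE_SD_UM,
) -> tuple[list[Track], list[Track]]:
    """Gearset trajectories plus noisy observed copies.

    Returns ``(truth_tracks, observed_tracks)``.  The long dominant dwell
    gives the long-run regime; the short slip keeps pauses a negligible
    fraction of the recording so the mean frame speed reflects the run speed.
    """
    seeds = _spawn_seeds(seed, 2 * n_tracks)
    truth, observed = [], []
    for i in range(n_tracks):
        params = gearset.GearsetParams(
            run_speed_um_s=run_speed_um_s,
            mean_dwell_dominant_s=mean_dwell_dominant_s,
            slip_mean_s=slip_mean_s,
            reversal_prob=reversal_prob,
            duration_s=duration_s,
            seed=seeds[i],
        )
        tr = gearset.simulate_gliding_cell(params).track
        tr.track_id = i
        truth.append(tr)
        observed.append(add_localization_noise(tr, noise_sd_um, seeds[n_tracks + i]))
    return truth, observed


def gliding_speed_recovery(
    run_speed_um_s: float,
    n_tracks: int,
    seed: int,
    reversal_prob: float = 0.5,
    noise_sd_um: float = GLIDING_NOISE_SD_UM,
) -> float:
    """Population mean speed recovered from noisy gearset trajectories."""
    _, observed = simulate_noisy_population(
        run_speed_um_s, n_tracks, seed,
        reversal_prob=reversal_prob, noise_sd_um=noise_sd_um,
    )
    return motility.population_summary(observed)["mean_speed_um_s"]


def farthest_displacement_recovery(
    target_mean_um: float,
    n_tracks: int,
    seed: int,
    run_speed_um_s: float = 2.0,
) -> tuple[float, float, float]:
    """Calibrate run length to a target ground-truth mean farthest
    displacement, then recover it from noisy tracks.

    The mean dominant dwell (which sets the run length) is bisected until the
    noiseless ground-truth per-track farthest displacement averages
    ``target_mean_um``.  Returns ``(dwell_s, truth_mean, recovered_mean)``.
    """

    def truth_mean(dwell: float) -> float:
        truth, _ = simulate_noisy_population(
            run_speed_um_s, n_tracks, seed, mean_dwell_dominant_s=dwell,
        )
        return float(
            np.mean([motility.farthest_displacement(t) for t in truth])
        )

    lo, hi = 5.0, 500.0
    for _ in range(24):
        mid = 0.5 * (lo + hi)
        if truth_mean(mid) < target_mean_um:
            lo = mid
        else:
            hi = mid
    dwell = 0.5 * (lo + hi)
    truth, observed = simulate_noisy_population(
        run_speed_um_s, n_tracks, seed, mean_dwell_dominant_s=dwell,
    )
    t_mean = float(np.mean([motility.farthest_displacement(t) for t in truth]))
    r_mean = motility.population_summary(observed)["farthest_displacement_um"]
    return dwell, t_mean, r_mean


def bias_classification(
    bias: float,
    n_motors: int,
    seed: int,
    duration_s: float = 30.0,
    mean_dwell_dominant_s: float = 1000.0,
    magnitude_hz: float = 1.3,
) -> rotation.SpeedDistribution:
    """Classify independently simulated motors through the rotation pipeline.

    Each motor's direction series is converted to an angular trace at a fixed
    frequency magnitude with its instantaneous sign, then classified with
    :func:`gearbelt.rotation.rotation_frequency`.  The dwell time is long
    relative to the observation window, so each motor reports its stationary
    direction draw and the dominant fraction estimates ``bias``.
    """
    records = []
    for i, s in enumerate(_spawn_seeds(seed, n_motors)):
        params = gearset.GearsetParams(
            n_motors=1, bias=bias, mean_dwell_dominant_s=mean_dwell_dominant_s,
            duration_s=duration_s, dt_s=1.0 / 15.0, seed=s,
        )
        series = gearset.simulate_motor_ensemble(params)
        omega = 2.0 * np.pi * magnitude_hz * series.directions[0].astype(float)
        theta = np.concatenate(
            [[0.0], np.cumsum(omega[:-1] * np.diff(series.times_s))]
        )
        trace = rotation.AngularTrace(times_s=series.times_s, theta_rad=theta)
        records.append(rotation.rotation_frequency(trace, motor_id=i))
    return rotation.speed_distribution(records)


def spot_speed_recovery(
    belt_speed_um_s: float,
    n_videos: int,
    seed: int,
    duration_s: float = 20.0,
    cell_length_um: float = 10.0,
) -> float:
    """Mean spot speed recovered by detect -> link -> speed over videos."""
    n_frames = int(round(duration_s * 15))
    meta = synth.VideoMeta(n_frames=n_frames, shape_px=SPOT_SHAPE, bit_depth=16)
    speeds = []
    perimeter, _ = synth.stadium_path(cell_length_um, 1.0)
    for i, s in enumerate(_spawn_seeds(seed, n_videos)):
        stack, _truth = synth.render_spot_video(
            belt_speed_um_s=belt_speed_um_s, meta=meta,
            cell_length_um=cell_length_um, seed=s,
            s0_um=i * perimeter / n_videos,
        )
        dets = spots.detect_spots_stack(stack, psf_sigma_um=0.15)
        tracks = spots.link_spot_tracks(dets, meta.times_s)
        best = max(tracks, key=len)
        speeds.append(spots.spot_speed(best))
    return float(np.mean(speeds))


def oscillation_classification(
    belt_speed_um_s: float,
    seed: int,
    osc_span_um: float = 1.0,
    duration_s: float = 20.0,
) -> spots.ShapeClass:
    """Render an oscillation-mode spot video and classify its trajectory."""
    n_frames = int(round(duration_s * 15))
    meta = synth.VideoMeta(n_frames=n_frames, shape_px=SPOT_SHAPE, bit_depth=16)
    stack, _ = synth.render_spot_video(
        belt_speed_um_s=belt_speed_um_s, meta=meta, mode="oscillate",
        osc_span_um=osc_span_um, seed=seed,
    )
    dets = spots.detect_spots_stack(stack, psf_sigma_um=0.15)
    tracks = spots.link_spot_tracks(dets, meta.times_s)
    best = max(tracks, key=len)
    return spots.classify_shape(best)
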