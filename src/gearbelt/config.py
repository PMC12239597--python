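"""Run configuration: YAML loading, key validation, per-stage seeds.

CLI flags override file values.  Unknown keys are rejected so typos fail
loudly instead of silently running with defaults.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml

from .errors import ConfigError

# Allowed keys per command block; values are defaults.
SCHEMAS: dict[str, dict] = {
    "global": {"seed": 0, "out": "gearbelt_out", "log_level": "INFO"},
    "simulate": {
        "n_motors": 10,
        "bias": 0.9,
        "dominant_direction": 1,
        "mean_dwell_dominant_s": 10.0,
        "run_speed_um_s": 2.0,
        "slip_mean_s": 0.5,
        "turn_kappa": 0.0,
        "reversal_prob": 0.5,
        "dt_s": 1.0 / 15.0,
        "duration_s": 60.0,
    },
    "render": {
        "kind": "tethered",
        "pixel_size_um": 0.1,
        "frame_interval_s": 1.0 / 15.0,
        "n_frames": 150,
        "shape_px": [256, 256],
        "bit_depth": 8,
        "signed_freq_hz": 1.3,
        "cell_length_um": 5.0,
        "cell_width_um": 0.8,
        "tether_offset_um": 1.0,
        "noise_sd": 4.0,
        "belt_speed_um_s": 2.0,
        "psf_sigma_um": 0.15,
        "photon_level": 2000.0,
        "mode": "loop",
        "tracks_csv": None,
    },
    "analyze_rotation": {
        "pixel_size_um": None,
        "frame_interval_s": None,
        "min_area_px": 50,
        "bin_width_hz": 0.2,
    },
    "analyze_gliding": {
        "max_jump_um": 2.0,
        "max_gap_frames": 2,
        "smooth_window_frames": 5,
    },
    "analyze_spots": {
        "pixel_size_um": None,
        "frame_interval_s": None,
        "psf_sigma_um": 0.15,
        "snr_threshold": 7.0,
        "max_jump_um": 0.5,
        "max_gap_frames": 2,
        "smooth_window_frames": 5,
        "loop_closure_um": 0.5,
        "reversal_count_threshold": 3,
        "min_loop_path_um": 5.0,
    },
}


def load_config(path) -> dict:
    """Load a YAML config and validate its keys against the schemas."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown_blocks = set(raw) - set(SCHEMAS)
    if unknown_blocks:
        raise ConfigError(f"unknown config blocks: {sorted(unknown_blocks)}")
    for block, values in raw.items():
        if values is None:
            continue
        bad = set(values) - set(SCHEMAS[block])
        if bad:
            raise ConfigError(f"unknown keys in [{block}]: {sorted(bad)}")
    return raw


def resolve(block: str, file_config: dict | None = None, **overrides) -> dict:
    """Defaults <- config file <- explicit (non-None) overrides."""
    if block not in SCHEMAS:
        raise ConfigError(f"unknown config block {block!r}")
    out = dict(SCHEMAS[block])
    if file_config:
        out.update(file_config.get(block) or {})
    out.update({k: v for k, v in overrides.items() if v is not None})
    bad = set(out) - set(SCHEMAS[block])
    if bad:
        raise ConfigError(f"unknown keys in [{block}]: {sorted(bad)}")
    return out


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived by hashing the stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")
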