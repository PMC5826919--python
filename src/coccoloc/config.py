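"""Pipeline configuration: defaults, YAML overlay, per-stage seed derivation.

One top-level seed drives everything: each stage derives an independent
substream seed from it (seed combined with a stable per-stage key), so every
stage is reproducible on its own and the whole pipeline is idempotent under
a fixed config.
"""

from __future__ import annotations

import copy
import hashlib
import zlib
from pathlib import Path

import yaml

from .errors import ParameterError

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "generator": {
        "image_size": 48,          # per-cell crop, px
        "cell_radius_px": 8.0,     # 1 µm cell at 65 nm/px
        "ring_sigma_px": 1.5,
        "ring_amplitude": 1000.0,
        "cytoplasm_level": 0.2,
        "psf_sigma_px": 1.6,
        "photon_scale": 0.2,       # photons per intensity unit
        "read_noise_sd": 10.0,
        "bit_depth": 12,
        "background": 20.0,
        "centre_jitter_px": 1.5,   # error added to annotated centres
        "groups": [
            {"name": "punctate", "pattern": "punctate", "n_puncta": 6,
             "puncta_contrast": 3.0, "n_cells": 20},
            {"name": "homogeneous", "pattern": "homogeneous_ring", "n_cells": 20},
        ],
        "bleach": {
            "n_frames": 720,       # 6 min at 0.5 s/frame
            "amplitude": 1000.0,
            "offset": 50.0,
            "noise_sd": 20.0,
            "tau_donor_frames": 100.0,
            "true_efficiency": 0.20,   # tau' = tau / (1 - E)
            "n_cells_per_arm": 20,
        },
        "coloc": {
            "overlaps": [0.75, 0.20],
            "n_fields": 3,
            "field_size": 128,
            "n_cells": 4,
            "n_spots_per_cell": 4,
            "spot_ring_radius_px": 10.0,
        },
    },
    "analysis": {
        "n_angle_bins": 360,
        "remove_cytoplasm": True,  # convolved-style images carry cytoplasmic signal
        "refine_centres": True,
        "cv_scale": 100.0,
        "rolling_ball_radius_px": 50,
        "bootstrap_resamples": 1000,
        "fit_offset": True,
    },
}

_STAGES = ("generate", "cv", "fret", "coloc", "report")


def _deep_merge(base: dict, overlay: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in overlay.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid with an optional YAML file, then explicit overrides."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ParameterError(f"{path}: config must be a YAML mapping")
        config = _deep_merge(config, user)
    if overrides:
        config = _deep_merge(config, overrides)
    return config


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (always < 2**31)."""
    if stage not in _STAGES:
        raise ParameterError(f"unknown stage {stage!r}; choose from {_STAGES}")
    return (int(seed) * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31)


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved config, for run logs."""
    canon = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()[:12]


def write_resolved_config(config: dict, out_dir: str | Path) -> Path:
    """Write the fully resolved config next to the outputs it produced."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "resolved_config.yaml"
    path.write_text(yaml.safe_dump(config, sort_keys=True))
    return path
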