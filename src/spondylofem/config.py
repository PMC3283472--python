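"""YAML configuration: documented defaults and deep-merge loading."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .loading import DEFAULT_BW_FRACTIONS


def default_config() -> dict:
    """Full default configuration of the modelling pipeline."""
    return {
        "geometry": {
            "pi_deg": 61.0,
            "ss_deg": 52.0,
            "slip_pct": 30.0,          # Grade II baseline
            "lumbar_lordosis_deg": 65.0,
            "thoracic_kyphosis_deg": 40.0,
            "dome_height_mm": 3.0,     # 0 disables the sacral dome
        },
        "patient": {"age_yr": 14.0, "height_cm": 157.2, "weight_kg": 45.5},
        "reconstruction": {
            "noise_sd_mm": 3.3,          # landmark emulation accuracy
            "campaign_noise_sd_mm": 0.0,  # campaign runs on the ideal template
        },
        "mesh": {
            "resolution": 12,
            "include_ribcage": True,
            "pars_lysis": True,
        },
        "materials": {},  # nested overrides: solids/springs/beam_sections
        "loading": {
            "gravity_m_s2": 9.81,
            "torsion_stiffness_nmm": 5.0e6,
            "fractions": dict(DEFAULT_BW_FRACTIONS),
            "follower": {"tol_rad": 1e-3, "max_iter": 25,
                         "single_pass": False},
        },
        "analysis": {"dome_quantile": 0.8, "lateral_quantile": 0.7},
        "campaign": {"alpha": 0.05},
    }


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, overlaid with a user YAML file if given."""
    cfg = default_config()
    if path is None:
        return cfg
    user = yaml.safe_load(Path(path).read_text()) or {}
    return _deep_merge(cfg, user)
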