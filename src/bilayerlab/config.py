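"""Run configuration: defaults, validation, normalization.

A single structured (YAML) config file with per-stage blocks; CLI flags
override config values. Every threshold the analyses use is recorded here
so a run is fully reproducible from its config.
"""

from __future__ import annotations

import copy
from typing import Any

import yaml

from .errors import ConfigError

STAGES = ("simulate", "dsc", "saxs", "waxd", "p31", "noesy", "density", "contacts", "report")

#: Default depth distribution (nm, relative to the bilayer center) for the
#: synthetic NOESY/trajectory scenario: lipid proton groups from the chain
#: terminus to the headgroup, plus two ligand groups near the first chain
#: carbons.
DEFAULT_DEPTH_GROUPS: list[dict[str, Any]] = [
    {"label": "CH3",    "mean_z": 0.00, "sd_z": 0.30, "n_atoms": 6, "atom_mass": 15.0},
    {"label": "(CH2)n", "mean_z": 0.60, "sd_z": 0.35, "n_atoms": 24, "atom_mass": 14.0},
    {"label": "CH2C=",  "mean_z": 0.95, "sd_z": 0.30, "n_atoms": 4, "atom_mass": 14.0},
    {"label": "C3",     "mean_z": 1.25, "sd_z": 0.25, "n_atoms": 4, "atom_mass": 14.0},
    {"label": "C2",     "mean_z": 1.35, "sd_z": 0.25, "n_atoms": 4, "atom_mass": 14.0},
    {"label": "G1",     "mean_z": 1.55, "sd_z": 0.25, "n_atoms": 2, "atom_mass": 14.0},
    {"label": "gamma",  "mean_z": 2.00, "sd_z": 0.25, "n_atoms": 9, "atom_mass": 15.0},
    {"label": "III",    "mean_z": 1.28, "sd_z": 0.30, "n_atoms": 4, "atom_mass": 13.0},
    {"label": "IV",     "mean_z": 1.32, "sd_z": 0.30, "n_atoms": 4, "atom_mass": 13.0},
]

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "outdir": "bilayerlab_out",
    "stages": list(STAGES),
    "thresholds": {
        "ratio_tolerance": 0.03,       # relative tolerance for Bragg indexing
        "contact_cutoff_nm": 0.5,
        "bin_width_nm": 0.1,
        "pretransition_fraction": 0.5,
        "dsc_prominence": None,        # None -> 5x robust noise estimate
        "peak_prominence": None,       # None -> 2% of intensity range
        "skew_threshold": 0.15,
        "edge_frac": 0.05,
    },
    "dsc": {
        "transitions": [[13.0, 0.6, 300.0], [24.0, 6.0, 600.0]],
        "baseline_slope": 0.0,
        "baseline_intercept": 0.0,
        "noise_sd": 0.01,
        "t_range": [5.0, 40.0],
        "t_step": 0.05,
        "exclusion_windows": [[10.0, 16.0], [20.0, 28.0]],
    },
    "saxs": {
        "d": 64.0, "zH": 19.5, "sigmaH": 3.0, "sigmaC": 5.4,
        "rho_ratio": -1.0, "n_lamellae": 25, "eta": 0.0,
        "noise_sd": 0.0, "s_min": 0.0075, "s_max": 0.07, "n_points": 640,
    },
    "hexagonal": {"d10": 60.0},
    "waxd": {"peaks": [[4.19, 100.0, 0.0015], [4.10, 45.0, 0.004]], "noise_sd": 0.5},
    "p31": {
        "delta_sigma": -40.0, "phase": "lamellar",
        "lb": 100.0, "field_MHz": 242.9, "noise_sd": 0.005,
    },
    "noesy": {
        "tm": 0.3, "ligand_groups": ["III", "IV"], "scale": 1000.0, "noise_frac": 0.05,
    },
    "trajectory": {
        "n_frames": 100, "box": [4.0, 4.0, 8.0], "reference_group": "CH3",
    },
    "depth_groups": DEFAULT_DEPTH_GROUPS,
    "inputs": {},   # per-stage explicit input paths; default to simulate outputs
}

_POSITIVE_THRESHOLDS = ("ratio_tolerance", "contact_cutoff_nm", "bin_width_nm",
                        "pretransition_fraction", "skew_threshold", "edge_frac")


def _merge(base: dict, override: dict, path: str, errors: list[str]) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key not in base:
            errors.append(f"unknown key {path}{key!r}")
            continue
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, f"{path}{key}.", errors)
        else:
            out[key] = copy.deepcopy(val)
    return out


def validate_config(cfg: dict | None) -> dict:
    """Fill defaults, normalize, and validate; aggregate all violations.

    Returns the normalized configuration dict. Raises
    :class:`ConfigError` listing every unknown key and invalid value.
    """
    errors: list[str] = []
    merged = _merge(DEFAULTS, cfg or {}, "", errors)

    for name in merged["stages"]:
        if name not in STAGES:
            errors.append(f"unknown stage {name!r}")
    thr = merged["thresholds"]
    for key in _POSITIVE_THRESHOLDS:
        if thr[key] is None or thr[key] <= 0:
            errors.append(f"threshold {key!r} must be positive, got {thr[key]!r}")
    for key in ("dsc_prominence", "peak_prominence"):
        if thr[key] is not None and thr[key] <= 0:
            errors.append(f"threshold {key!r} must be positive when set")
    needs_seed = any(s == "simulate" for s in merged["stages"])
    if needs_seed and not isinstance(merged["seed"], int):
        errors.append("an integer seed is mandatory when the simulate stage is selected")
    if errors:
        raise ConfigError(errors)
    return merged


def load_config(path: str | None) -> dict:
    """Load a YAML config file (or use pure defaults) and validate it."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    return validate_config(raw)
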