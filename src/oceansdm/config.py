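"""Run configuration: plain-text (YAML) config file, validation, defaults.

The config mirrors the pipeline stages: ``ocean``, ``truth``, ``sampling``,
``prepare``, ``fit``, ``project``, ``ensemble``, ``evaluate``, plus a global
``seed`` and ``output_dir``. Unknown keys are rejected (with a suggestion);
validation reports *all* violations, not just the first.
"""

from __future__ import annotations

import copy
import difflib
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ConfigurationError

DEFAULTS: dict[str, Any] = {
    "seed": 42,
    "output_dir": "sdm_run",
    "ocean": {
        "grid_step": 2.0,
        "lat_range": [-78.0, 80.0],
        "lon_range": [-180.0, 180.0],
        "sst_pole": -5.0,
        "sst_equator": 12.0,
        "seasonal_amp": 2.0,
        "nitrate_max": 30.0,
        "nutrient_decay_lat": 8.0,
        "nitrate_mid_lat": -45.0,
        "si_decouple_band": [-48.0, -38.0],
        "si_ratio": 1.5,
        "land_fraction": 0.2,
        "noise_amp_deg": 2.0,
        "noise_corr_deg": 15.0,
    },
    "truth": {
        "nitrate_mid": 15.0,
        "nitrate_slope": 2.0,
        "sst_max": 7.5,
        "sst_slope": 0.5,
    },
    "sampling": {
        "n": 200,
        "month_weights": None,  # null -> austral-summer-biased default
    },
    "prepare": {
        "background": 2000,
        "bias_smooth_radius": 1,
        "use_bias": False,
    },
    "fit": {
        "beta_multiplier": 1.0,
        "knots": 30,
        "tol": 1.0e-5,
        "max_iter": 3000,
    },
    "project": {
        "threshold": 0.2,
        "consensus_threshold": 0.2,
    },
    "ensemble": {
        "n_gcms": 5,
        "delta_sst": 2.0,
        "nitrate_scale": 0.7,
        "perturb": 0.05,
        "scenario": "rcp85",
        "months": list(range(1, 13)),
    },
    "evaluate": {
        "cv": 5,
        "jackknife": True,
        "curve_points": 50,
    },
}

# per-key validators: (predicate, message)
_RULES: dict[tuple[str, ...], tuple] = {
    ("seed",): (lambda v: isinstance(v, int), "must be an integer"),
    ("output_dir",): (lambda v: isinstance(v, str) and v, "must be a non-empty path"),
    ("ocean", "grid_step"): (lambda v: v > 0, "must be positive"),
    ("ocean", "seasonal_amp"): (lambda v: v >= 0, "must be >= 0"),
    ("ocean", "land_fraction"): (lambda v: 0 <= v <= 0.3, "must lie in [0, 0.3]"),
    ("truth", "nitrate_slope"): (lambda v: v > 0, "must be positive"),
    ("truth", "sst_slope"): (lambda v: v > 0, "must be positive"),
    ("sampling", "n"): (lambda v: isinstance(v, int) and v >= 1, "must be an integer >= 1"),
    ("prepare", "background"): (lambda v: isinstance(v, int) and v >= 10, "must be an integer >= 10"),
    ("fit", "beta_multiplier"): (lambda v: v > 0, "must be positive"),
    ("fit", "knots"): (lambda v: isinstance(v, int) and v >= 1, "must be an integer >= 1"),
    ("fit", "tol"): (lambda v: v > 0, "must be positive"),
    ("fit", "max_iter"): (lambda v: isinstance(v, int) and v >= 1, "must be an integer >= 1"),
    ("project", "threshold"): (lambda v: 0 < v < 1, "must lie in (0, 1)"),
    ("project", "consensus_threshold"): (lambda v: 0 < v < 1, "must lie in (0, 1)"),
    ("ensemble", "n_gcms"): (lambda v: isinstance(v, int) and v >= 1, "must be an integer >= 1"),
    ("ensemble", "nitrate_scale"): (lambda v: 0 < v <= 1, "must lie in (0, 1]"),
    ("ensemble", "months"): (
        lambda v: isinstance(v, list) and v and all(isinstance(m, int) and 1 <= m <= 12 for m in v),
        "must be a non-empty list of months 1..12",
    ),
    ("evaluate", "cv"): (lambda v: v == 0 or (isinstance(v, int) and v >= 2),
                         "must be 0 (off) or an integer >= 2"),
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (defaults merged in)."""

    data: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    @property
    def seed(self) -> int:
        return self.data["seed"]

    @property
    def output_dir(self) -> str:
        return self.data["output_dir"]


def _check(data: dict[str, Any]) -> list[str]:
    errors: list[str] = []
    for key, value in data.items():
        if key not in DEFAULTS:
            hint = difflib.get_close_matches(key, DEFAULTS.keys(), n=1)
            extra = f" (did you mean {hint[0]!r}?)" if hint else ""
            errors.append(f"unknown section or key {key!r}{extra}")
            continue
        if isinstance(DEFAULTS[key], dict):
            if not isinstance(value, dict):
                errors.append(f"section {key!r} must be a mapping")
                continue
            for sub, sval in value.items():
                if sub not in DEFAULTS[key]:
                    hint = difflib.get_close_matches(sub, DEFAULTS[key].keys(), n=1)
                    extra = f" (did you mean {hint[0]!r}?)" if hint else ""
                    errors.append(f"unknown key {key}.{sub}{extra}")
                    continue
                rule = _RULES.get((key, sub))
                if rule is not None:
                    ok = False
                    try:
                        ok = rule[0](sval)
                    except TypeError:
                        pass
                    if not ok:
                        errors.append(f"{key}.{sub} = {sval!r}: {rule[1]}")
        else:
            rule = _RULES.get((key,))
            if rule is not None:
                ok = False
                try:
                    ok = rule[0](value)
                except TypeError:
                    pass
                if not ok:
                    errors.append(f"{key} = {value!r}: {rule[1]}")
    return errors


def merge_config(overrides: dict[str, Any] | None) -> RunConfig:
    """Merge a (validated) override mapping over the defaults."""
    merged = copy.deepcopy(DEFAULTS)
    for key, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return RunConfig(data=merged)


def validate_config(path: str) -> RunConfig:
    """Load + validate a YAML config; raises with *all* violations listed."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config root must be a mapping")
    errors = _check(raw)
    if errors:
        raise ConfigurationError(
            f"{path}: {len(errors)} configuration error(s):\n  - " + "\n  - ".join(errors)
        )
    return merge_config(raw)
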