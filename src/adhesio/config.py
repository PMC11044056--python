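"""Run configuration: YAML + flag merging, validation, and output plumbing.

Flags override file values; the effective configuration is echoed to the log
and written alongside outputs, and every output CSV carries a header comment
with the tool version and a hash of the effective configuration so runs are
attributable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .morphometrics import K_RANGE

logger = logging.getLogger("adhesio")

_DEFAULTS = {
    "pixel_size_um": 0.16,
    "frame_interval_s": 20.0,
    "median_radius_px": 1.5,
    "rolling_ball_radius_px": 50.0,
    "threshold_multiplier_k": "auto",
    "min_area_um2": 0.25,
    "max_area_um2": None,
    "enrichment_threshold": 6.0,
    "min_trials": 2,
    "min_tier": "moderate",
    "seed": 0,
    "log_level": "INFO",
}


@dataclass(frozen=True)
class RunConfig:
    subcommand: str
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __getattr__(self, name):
        try:
            return self.params[name]
        except KeyError:
            raise AttributeError(name)

    def as_dict(self) -> dict:
        return {
            "subcommand": self.subcommand,
            "inputs": dict(self.inputs),
            "params": dict(self.params),
        }

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _validate(params: dict) -> None:
    k = params["threshold_multiplier_k"]
    if not (isinstance(k, str) and k == "auto"):
        try:
            k = float(k)
        except (TypeError, ValueError):
            raise ValueError("threshold_multiplier_k must be numeric or 'auto'")
        if not (K_RANGE[0] <= k <= K_RANGE[1]):
            raise ValueError(
                f"threshold_multiplier_k={k:g} outside the valid range "
                f"[{K_RANGE[0]:g}, {K_RANGE[1]:g}]"
            )
        params["threshold_multiplier_k"] = k
    if params["pixel_size_um"] <= 0:
        raise ValueError("pixel_size_um must be positive")
    if params["frame_interval_s"] <= 0:
        raise ValueError("frame_interval_s must be positive")
    if params["min_area_um2"] < 0:
        raise ValueError("min_area_um2 must be >= 0")
    if params["enrichment_threshold"] <= 0:
        raise ValueError("enrichment_threshold must be positive")
    if params["min_trials"] < 1:
        raise ValueError("min_trials must be >= 1")
    if params["min_tier"] not in ("moderate", "strong"):
        raise ValueError("min_tier must be 'moderate' or 'strong'")
    if not isinstance(params["seed"], int):
        raise ValueError("seed must be an integer")


def load_config(
    subcommand: str,
    config_path: str | None = None,
    inputs: dict | None = None,
    **flag_overrides,
) -> RunConfig:
    """Build a validated RunConfig from defaults, a YAML file, and flags.

    Precedence: flags > file > defaults.  Unknown keys are an error naming
    the valid keys; out-of-range values are an error naming the constraint.
    Referenced input paths must exist.
    """
    params = dict(_DEFAULTS)
    if config_path is not None:
        with open(config_path) as fh:
            file_vals = yaml.safe_load(fh) or {}
        unknown = set(file_vals) - set(_DEFAULTS)
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; valid keys: "
                f"{sorted(_DEFAULTS)}"
            )
        params.update(file_vals)
    for key, val in flag_overrides.items():
        if key not in _DEFAULTS:
            raise ValueError(
                f"unknown config key {key!r}; valid keys: {sorted(_DEFAULTS)}"
            )
        if val is not None:
            if key in params and params[key] != _DEFAULTS[key] and params[key] != val:
                logger.info("flag overrides config file: %s=%r", key, val)
            params[key] = val
    _validate(params)
    inputs = dict(inputs or {})
    for name, path in inputs.items():
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"input {name!r} does not exist: {path}")
    cfg = RunConfig(subcommand=subcommand, inputs=inputs, params=params)
    logger.info("effective config: %s", cfg.as_dict())
    return cfg


def echo_config(cfg: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / f"{cfg.subcommand}_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.as_dict(), fh, sort_keys=True)


def write_csv(df: pd.DataFrame, path, cfg: RunConfig | None = None) -> None:
    """Write a result CSV with a provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        tag = f" config={cfg.config_hash}" if cfg is not None else ""
        fh.write(f"# adhesio {__version__}{tag}\n")
        df.to_csv(fh, index=False)


def read_result_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
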