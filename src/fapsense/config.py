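"""Run configuration: TOML in, a frozen dataclass out.

Defaults reproduce the standard assay settings: readings every 12 min,
order-2 reference model, OD 0.6 readout anchor, alpha 0.05.
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from .generator import DEFAULT_IPTG_DOSES_MM

__all__ = ["RunConfig", "load_config", "dump_config", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    outdir: str = "results"
    # generator
    n_times: int = 240
    ts_min: float = 12.0
    noise_sigma: float = 0.02
    replicates: int = 3
    iptg_doses_mm: tuple = DEFAULT_IPTG_DOSES_MM
    arabinose_pct: float = 0.01
    x0: float = 0.05
    xmax: float = 1.2
    mu: float = 0.01
    lag_min: float = 60.0
    # identification
    order: int = 2
    # analysis
    od_threshold: float = 0.6
    od_floor: float = 0.05
    alpha: float = 0.05


_SECTIONS = {
    "generator": (
        "n_times",
        "ts_min",
        "noise_sigma",
        "replicates",
        "iptg_doses_mm",
        "arabinose_pct",
        "x0",
        "xmax",
        "mu",
        "lag_min",
    ),
    "identification": ("order",),
    "analysis": ("od_threshold", "od_floor", "alpha"),
}


def load_config(path) -> RunConfig:
    """Read a TOML config; unknown keys raise, absent keys keep defaults."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = RunConfig()
    updates: dict = {}
    for key in ("seed", "outdir"):
        if key in raw:
            updates[key] = raw.pop(key)
    for section, keys in _SECTIONS.items():
        body = raw.pop(section, {})
        for k, v in body.items():
            if k not in keys:
                raise KeyError(f"unknown key [{section}].{k}")
            updates[k] = tuple(v) if isinstance(v, list) else v
    if raw:
        raise KeyError(f"unknown config sections/keys: {sorted(raw)}")
    return replace(cfg, **updates)


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, (tuple, list)):
        return "[" + ", ".join(_fmt(v) for v in value) + "]"
    return '"' + str(value) + '"'


def dump_config(cfg: RunConfig) -> str:
    """Serialize a config to TOML text (the sidecar written next to plates)."""
    d = asdict(cfg)
    lines = [f"seed = {_fmt(d['seed'])}", f"outdir = {_fmt(d['outdir'])}", ""]
    for section, keys in _SECTIONS.items():
        lines.append(f"[{section}]")
        lines.extend(f"{k} = {_fmt(d[k])}" for k in keys)
        lines.append("")
    return "\n".join(lines)


def config_hash(cfg: RunConfig) -> str:
    """Short digest identifying a configuration (logged with every run)."""
    return hashlib.sha256(dump_config(cfg).encode()).hexdigest()[:12]


def save_config(cfg: RunConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(dump_config(cfg))
    return path
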