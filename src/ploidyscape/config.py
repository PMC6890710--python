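"""Run configuration: a flat key=value text format with typed schema,
unknown-key rejection, and a provenance record per run."""

from __future__ import annotations

import dataclasses
import json
import platform
import sys
from pathlib import Path
from typing import Any

from .ltr import LTRParams
from .synthdata import SimConfig


def _coerce(value: str, template: Any) -> Any:
    if isinstance(template, bool):
        return value.lower() in ("1", "true", "yes")
    if isinstance(template, int):
        return int(value)
    if isinstance(template, float):
        return float(value)
    if isinstance(template, tuple):
        parts = [p.strip() for p in value.split(",")]
        return tuple(type(t)(p) for t, p in zip(template, parts))
    if isinstance(template, dict):
        out = {}
        if value.strip():
            for item in value.split(";"):
                k, v = item.split("=", 1)
                out[k.strip()] = float(v)
        return out
    return value


def parse_flat_config(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected key = value")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def apply_config(obj: Any, raw: dict[str, str], prefix: str = "") -> list[str]:
    """Apply prefixed keys onto a dataclass; returns the consumed keys.
    Unknown prefixed keys raise, naming the offender."""
    fields = {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
    consumed = []
    for key, value in raw.items():
        if prefix and not key.startswith(prefix + "."):
            continue
        name = key[len(prefix) + 1 :] if prefix else key
        if name not in fields:
            raise KeyError(f"unknown configuration key: {key}")
        setattr(obj, name, _coerce(value, fields[name]))
        consumed.append(key)
    return consumed


def load_sim_config(path: str | Path | None, seed: int | None = None) -> SimConfig:
    cfg = SimConfig()
    if path is not None:
        raw = parse_flat_config(Path(path).read_text(encoding="utf-8"))
        sim_keys = {k: v for k, v in raw.items() if k.startswith("sim.")}
        apply_config(cfg, sim_keys, "sim")
    if seed is not None:
        cfg.seed = seed
    cfg.validate()
    return cfg


def load_ltr_params(path: str | Path | None) -> LTRParams:
    params = LTRParams()
    if path is not None:
        raw = parse_flat_config(Path(path).read_text(encoding="utf-8"))
        ltr_keys = {k: v for k, v in raw.items() if k.startswith("ltr.")}
        apply_config(params, ltr_keys, "ltr")
    params.validate()
    return params


def write_provenance(out_dir: str | Path, stage: str, seed: int | None, config: Any) -> Path:
    """Record everything needed to reproduce a run bit-for-bit."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        from importlib.metadata import version

        pkg_version = version("ploidyscape")
    except Exception:
        pkg_version = "unknown"
    record = {
        "stage": stage,
        "seed": seed,
        "config": dataclasses.asdict(config) if dataclasses.is_dataclass(config) else config,
        "package_version": pkg_version,
        "python": sys.version.split()[0],
        "platform": platform.platform(),
    }
    path = out_dir / f"provenance_{stage}.json"
    path.write_text(json.dumps(record, indent=2, default=str) + "\n", encoding="utf-8")
    return path
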