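"""Run configuration as structured text (YAML) with validation.

A run config collects every tunable the protocol exposes — optimizer
budgets, scoring thresholds, noise settings — so a run can be archived and
repeated exactly.  Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .calibrate import FitConfig
from .peaks import Thresholds
from .protocol import ProtocolConfig

__all__ = ["load_config", "dump_config"]

_SECTIONS = {"protocol", "fit", "stage2_fit", "thresholds"}


def load_config(path: str | Path) -> ProtocolConfig:
    """Parse and validate a YAML run config into a ProtocolConfig."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a mapping")
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")

    def build(cls, section):
        data = raw.get(section, {}) or {}
        valid = set(cls.__dataclass_fields__)
        bad = set(data) - valid
        if bad:
            raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
        return cls(**data)

    fit = build(FitConfig, "fit")
    stage2 = build(FitConfig, "stage2_fit") if "stage2_fit" in raw else None
    thresholds = build(Thresholds, "thresholds")
    protocol_kwargs = dict(raw.get("protocol", {}) or {})
    bad = set(protocol_kwargs) - set(ProtocolConfig.__dataclass_fields__)
    if bad:
        raise ValueError(f"unknown keys in [protocol]: {sorted(bad)}")
    kwargs = dict(protocol_kwargs, fit_config=fit, thresholds=thresholds)
    if stage2 is not None:
        kwargs["stage2_fit_config"] = stage2
    return ProtocolConfig(**kwargs)


def dump_config(config: ProtocolConfig, path: str | Path) -> None:
    """Archive the resolved configuration of a run."""
    payload = {
        "protocol": {
            k: v for k, v in asdict(config).items()
            if k not in ("fit_config", "stage2_fit_config", "thresholds")
        },
        "fit": asdict(config.fit_config),
        "stage2_fit": asdict(config.stage2_fit_config),
        "thresholds": asdict(config.thresholds),
    }
    payload["protocol"]["init_free"] = dict(payload["protocol"]["init_free"])
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
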