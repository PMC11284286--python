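"""YAML configuration loading for machine, plan, simulator and errors.

A config file is a flat mapping with optional ``machine``, ``plan``,
``sim`` and ``detect`` sections whose keys mirror the corresponding model
fields; an errors file has ``jaw_offsets`` (segment -> [dx1, dx2]) and
``leaf_offsets`` (leaf -> d) sections.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .detect import DetectParams
from .machine import MachineModel
from .plan import BPFConfig, ErrorSpec
from .simulate import SimConfig


def _load(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return data


def load_config(path=None) -> dict:
    """Load a config file into model instances (defaults when absent)."""
    data = _load(path) if path else {}
    return {
        "machine": MachineModel(**data.get("machine", {})),
        "plan": BPFConfig(**data.get("plan", {})),
        "sim": SimConfig(**data.get("sim", {})),
        "detect": DetectParams(**data.get("detect", {})),
    }


def load_errors(path) -> ErrorSpec:
    """Load an :class:`~bpfqa.plan.ErrorSpec` from YAML."""
    data = _load(path)
    jaw = {
        int(seg): (float(v[0]), float(v[1]))
        for seg, v in (data.get("jaw_offsets") or {}).items()
    }
    leaf = {int(k): float(v) for k, v in (data.get("leaf_offsets") or {}).items()}
    return ErrorSpec(jaw_offsets=jaw, leaf_offsets=leaf)
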