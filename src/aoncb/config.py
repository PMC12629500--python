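"""YAML/JSON configuration loading for neurons, pools and correlations."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .params import NeuronParams
from .synchrony import CorrelationSpec, InputPool

__all__ = ["load_config", "build_neurons", "build_pools", "build_correlation"]


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def build_neurons(cfg: dict) -> dict:
    """``{label: NeuronParams}`` from the ``neurons`` config block; a single
    anonymous neuron with default parameters if the block is absent."""
    out = {}
    for spec in cfg.get("neurons", [{"label": 0}]):
        spec = dict(spec)
        label = spec.pop("label", len(out))
        out[label] = NeuronParams(**spec)
    return out


def build_pools(cfg: dict) -> list[InputPool]:
    pools = []
    for spec in cfg.get("pools", []):
        pools.append(
            InputPool(
                kind=spec["kind"],
                K=int(spec["K"]),
                weights=spec.get("w", spec.get("weights", 0.0)),
                rates=spec.get("r", spec.get("rates", 0.0)),
            )
        )
    return pools


def build_correlation(cfg: dict) -> CorrelationSpec | None:
    block = cfg.get("correlation")
    if block is None:
        return None
    rho = np.asarray(block["blocks"], dtype=float)
    return CorrelationSpec(block_rho=rho, assignment=block.get("assignment"))
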