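"""Model parameter handling.

All quantitative constants of the simulator — plant, muscle, neuron, CPG
timing, sensory transduction and synaptic gains — live in one nested mapping
shipped as ``data/default_params.json`` (produced by :mod:`whiskloop.calibrate`).
Runs may override any leaf with a dotted-path map, e.g.
``{"muscle.extR_superficial.a_max": 3.0}``.
"""

from __future__ import annotations

import copy
import json
from importlib import resources
from typing import Any, Mapping

_DEFAULTS_CACHE: dict[str, Any] | None = None


def default_params() -> dict[str, Any]:
    """A deep copy of the shipped calibrated parameter set."""
    global _DEFAULTS_CACHE
    if _DEFAULTS_CACHE is None:
        with resources.files("whiskloop.data").joinpath("default_params.json").open() as fh:
            _DEFAULTS_CACHE = json.load(fh)
    return copy.deepcopy(_DEFAULTS_CACHE)


def apply_overrides(params: dict[str, Any], overrides: Mapping[str, Any] | None) -> dict[str, Any]:
    """Apply dotted-path overrides in place and return ``params``.

    Raises ``KeyError`` for a path whose parent does not exist, so typos in
    run configurations fail loudly rather than silently doing nothing.
    """
    if not overrides:
        return params
    for path, value in overrides.items():
        parts = path.split(".")
        node = params
        for p in parts[:-1]:
            if not isinstance(node, dict) or p not in node:
                raise KeyError(f"unknown parameter path {path!r}")
            node = node[p]
        if not isinstance(node, dict) or parts[-1] not in node:
            raise KeyError(f"unknown parameter path {path!r}")
        node[parts[-1]] = value
    return params


def get_path(params: Mapping[str, Any], path: str) -> Any:
    node: Any = params
    for p in path.split("."):
        node = node[p]
    return node
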