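"""Shared simulation fixtures.

The expensive simulator runs (free-air benchmark and the three pump
mechanisms) are session-scoped so the whole suite reuses them.
"""

from __future__ import annotations

import numpy as np
import pytest

from whiskloop import ObstacleConfig, RunConfig, run_simulation


@pytest.fixture(scope="session")
def freeair_result():
    """CPG-driven free-air benchmark run: defaults, seed 1, 2 s."""
    return run_simulation(RunConfig(duration_ms=2000.0, seed=1))


def _tip_run(mechanism: str, duration_ms: float = 1000.0) -> object:
    cfg = RunConfig(tip_mechanism=mechanism, duration_ms=duration_ms, seed=1,
                    obstacle=ObstacleConfig(whisker="A4", r=0.4))
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def er_result():
    return _tip_run("E_R")


@pytest.fixture(scope="session")
def direct_result():
    return _tip_run("DIRECT_I_P")


@pytest.fixture(scope="session")
def indirect_result():
    return _tip_run("INDIRECT_I_P")


def steady_episodes(result, whisker: str = "A4", t_min_ms: float = 250.0):
    """Contact episodes after the start-up transient."""
    return [e for e in result.episodes[whisker] if e[0] >= t_min_ms]
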