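"""Run orchestration: configuration validation, the event-loop/plant
interleave, result containers, parameter sweeps, and serialization.

The simulator advances in two interleaved layers: the discrete-event
scheduler dispatches every neural/muscular event due up to the next plant
step boundary, then the plant integrates one fixed step (default 0.5 ms)
using the muscles' current activation forces, and the sensory transducer
translates the resulting kinematic/contact state back into afferent volleys.
Everything is deterministic given (configuration, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import params as params_mod
from .engine import US_PER_MS, ms
from .network import (TIP_MECHANISMS, WHISKING_MECHANISMS, Configuration,
                      Network, build_network)
from .plant import ContactEpisode, Obstacle

__version__ = "0.1.0"


class ObstacleConfig(BaseModel):
    whisker: str = "A4"
    theta_obs_deg: float = 74.7
    r: float = Field(0.4, gt=0.0, le=1.0)


class RunConfig(BaseModel):
    """Schema-validated description of one simulation run."""

    whisking_mechanism: str = "CPG_ONLY"
    tip_mechanism: str = "NONE"
    seed: int = 1
    duration_ms: float = Field(2000.0, ge=0.0)
    obstacle: ObstacleConfig | None = None
    overrides: dict[str, Any] = Field(default_factory=dict)
    record_trace: bool = False

    @field_validator("whisking_mechanism")
    @classmethod
    def _check_wm(cls, v):
        if v not in WHISKING_MECHANISMS:
            raise ValueError(f"whisking_mechanism must be one of {WHISKING_MECHANISMS}")
        return v

    @field_validator("tip_mechanism")
    @classmethod
    def _check_tm(cls, v):
        if v not in TIP_MECHANISMS:
            raise ValueError(f"tip_mechanism must be one of {TIP_MECHANISMS}")
        return v

    def effective_params(self) -> dict:
        p = params_mod.default_params()
        params_mod.apply_overrides(p, self.overrides)
        return p

    def config_hash(self) -> str:
        blob = json.dumps(
            {"config": self.model_dump(), "params": self.effective_params()},
            sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class SimulationResult:
    """Trajectories, logs and metadata of one run (round-trippable to disk)."""

    t_ms: np.ndarray                       # shared time base
    theta: pd.DataFrame                    # columns = whisker ids, degrees
    episodes: dict[str, list[tuple[float, float]]]  # whisker -> (onset, offset) ms
    spikes: pd.DataFrame                   # t_ms, neuron_id, class, subtype, whisker
    metadata: dict[str, Any]

    @property
    def whiskers(self) -> list[str]:
        return list(self.theta.columns)

    def omega(self, whisker: str) -> np.ndarray:
        th = self.theta[whisker].to_numpy()
        return np.gradient(th, self.t_ms) if len(th) > 1 else np.zeros_like(th)

    # -- hashing -------------------------------------------------------
    def trajectory_hash(self) -> str:
        return hashlib.sha256(
            np.ascontiguousarray(self.theta.to_numpy()).tobytes()).hexdigest()

    def spike_hash(self) -> str:
        return hashlib.sha256(
            self.spikes.to_csv(index=False).encode()).hexdigest()

    # -- persistence -----------------------------------------------------
    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        traj = self.theta.copy()
        traj.insert(0, "t_ms", self.t_ms)
        traj.to_csv(out / "trajectory.csv", index=False)
        self.spikes.to_csv(out / "spikes.csv", index=False)
        with open(out / "episodes.json", "w") as fh:
            json.dump(self.episodes, fh)
        with open(out / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=1, default=str)
        return out

    @classmethod
    def load(cls, out_dir: str | Path) -> "SimulationResult":
        out = Path(out_dir)
        traj = pd.read_csv(out / "trajectory.csv")
        t_ms = traj.pop("t_ms").to_numpy()
        spikes = pd.read_csv(
            out / "spikes.csv",
            dtype={"neuron_id": str, "class": str, "subtype": str, "whisker": str})
        with open(out / "episodes.json") as fh:
            episodes = {w: [tuple(e) for e in eps] for w, eps in json.load(fh).items()}
        with open(out / "metadata.json") as fh:
            metadata = json.load(fh)
        return cls(t_ms, traj, episodes, spikes, metadata)

    def equals(self, other: "SimulationResult", atol: float = 1e-9) -> bool:
        return (np.allclose(self.t_ms, other.t_ms, atol=atol)
                and list(self.theta.columns) == list(other.theta.columns)
                and np.allclose(self.theta.to_numpy(), other.theta.to_numpy(), atol=1e-6)
                and self.episodes == other.episodes
                and len(self.spikes) == len(other.spikes))


def run_simulation(cfg: RunConfig) -> SimulationResult:
    """Execute one run; deterministic per (configuration, seed)."""
    p = cfg.effective_params()
    config = Configuration(cfg.whisking_mechanism, cfg.tip_mechanism, cfg.seed)
    obstacle = None
    if cfg.obstacle is not None:
        obstacle = Obstacle(cfg.obstacle.whisker, cfg.obstacle.theta_obs_deg, cfg.obstacle.r)
    net = build_network(config, p, obstacle, record_trace=cfg.record_trace)
    sched = net.sched
    plant = net.plant

    # start-up volley: the manager nudges every MN so that motion-gated
    # afferents have motion to report in the sensory-driven configurations
    kick = p["init_kick"]
    for v in range(int(kick["volleys"])):
        delay = ms(1.0 + v * kick["interval_ms"])
        for (w, typ), pool in net.mns.items():
            for n in pool:
                sched.post_to("stim", n.comp_id, delay, payload=(kick["weight"], 0),
                              source_id="manager")

    dt_us = ms(p["plant"]["dt_ms"])
    n_steps = int(round(ms(cfg.duration_ms) / dt_us))
    n_w = len(plant.ids)
    traj = np.empty((n_steps + 1, n_w))
    traj[0] = plant.theta
    prev_moving = plant.is_moving()

    for step in range(n_steps):
        t_next = (step + 1) * dt_us
        sched.run_until(t_next)
        torque = net.compute_torques(t_next)
        notes = plant.step(t_next, torque)
        net.transducer.on_plant_step(t_next, notes)
        moving = plant.is_moving()
        if not np.array_equal(moving, prev_moving):
            for i in np.flatnonzero(moving != prev_moving):
                kind = "move" if moving[i] else "settle"
                sched.post_to(kind, f"whisker[{plant.ids[i]}]", 0, source_id="plant")
            prev_moving = moving
        traj[step + 1] = plant.theta

    plant.close_episodes(n_steps * dt_us)
    t_ms_axis = np.arange(n_steps + 1) * (dt_us / US_PER_MS)
    theta_df = pd.DataFrame(traj, columns=plant.ids)
    episodes = {w: [] for w in plant.ids}
    if plant.obstacle is not None:
        episodes[plant.obstacle.whisker] = [
            (e.onset_us / US_PER_MS,
             (e.offset_us if e.offset_us is not None else n_steps * dt_us) / US_PER_MS)
            for e in plant.episodes]
    spikes = pd.DataFrame(
        [(t / US_PER_MS, nid, c, s, w) for (t, nid, c, s, w) in net.spike_log],
        columns=["t_ms", "neuron_id", "class", "subtype", "whisker"])
    metadata = {
        "config": cfg.model_dump(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "n_steps": n_steps,
        "synapse_hash": net.synapse_hash(),
    }
    result = SimulationResult(t_ms_axis, theta_df, episodes, spikes, metadata)
    if cfg.record_trace:
        result.metadata["n_trace_records"] = len(sched.trace)
        result.trace = sched.trace  # type: ignore[attr-defined]
    return result


def sweep(cfg: RunConfig, axis: str, values: Sequence[Any]) -> list[SimulationResult]:
    """One child run per value along ``axis`` (e.g. ``obstacle.r``), shared seed."""
    results = []
    for v in values:
        child = cfg.model_copy(deep=True)
        if axis.startswith("obstacle."):
            if child.obstacle is None:
                raise KeyError(f"axis {axis!r} requires an obstacle in the base config")
            fieldname = axis.split(".", 1)[1]
            if fieldname not in ObstacleConfig.model_fields:
                raise KeyError(f"unknown sweep axis {axis!r}")
            setattr(child.obstacle, fieldname, v)
        elif axis in RunConfig.model_fields:
            setattr(child, axis, v)
        else:
            # parameter override path; validated against the default tree
            params_mod.apply_overrides(params_mod.default_params(), {axis: v})
            child.overrides = dict(child.overrides)
            child.overrides[axis] = v
        results.append(run_simulation(child))
    return results
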