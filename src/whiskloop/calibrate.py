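"""Parameter calibration: coordinate refinement of the plant/muscle/latency
constants against the kinematic target set.

The default target set encodes the benchmark kinematics the model is meant to
reproduce: a ~150 ms whisk cycle split ~80/70 ms, protraction peaks of
79-81 degrees (74.5 for the rostral-most whisker of a seven-whisker row), and
the touch-induced-pump signatures of the three feedback mechanisms at a
contact 40 % out along the whisker.  ``calibrate`` starts from the current
defaults, runs a deterministic sequence of bounded one-dimensional secant
refinements on the most influential constants, and emits the parameter file
together with an achieved-vs-target report.  The shipped
``data/default_params.json`` is the product of this procedure.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import params as params_mod
from .analysis import detect_tips, first_tips, freeair_metrics
from .runner import ObstacleConfig, RunConfig, run_simulation

DEFAULT_TARGETS = {
    "cycle_ms": 150.0,
    "protraction_ms": 80.0,
    "retraction_ms": 70.0,
    "peak_interior_deg": 80.0,
    "peak_rostral_most_deg": 74.5,
    "er_delay_ms": 17.0,
    "er_touch_amp_deg": 0.6,
    "direct_delay_ms": 19.0,
    "direct_touch_amp_deg": 3.0,
    "indirect_touch_amp_deg": 5.0,
    "indirect_nontouch_amp_deg": 10.0,
}


def _freeair(overrides: dict, duration_ms: float, seed: int) -> dict:
    res = run_simulation(RunConfig(duration_ms=duration_ms, seed=seed, overrides=overrides))
    m = freeair_metrics(res)
    return {
        "cycle_ms": m["mean_cycle_ms"],
        "protraction_ms": m["mean_protraction_ms"],
        "retraction_ms": m["mean_retraction_ms"],
        "peak_interior_deg": m["peak_per_whisker"].get("C4", np.nan),
        "peak_rostral_most_deg": m["peak_per_whisker"].get("C7", np.nan),
    }


def _tip_stats(mech: str, overrides: dict, duration_ms: float, seed: int) -> dict:
    cfg = RunConfig(tip_mechanism=mech, duration_ms=duration_ms, seed=seed,
                    obstacle=ObstacleConfig(), overrides=overrides)
    res = run_simulation(cfg)
    eps = [e for e in res.episodes["A4"] if e[0] >= 250.0]
    out: dict[str, float] = {}
    t = res.t_ms
    for w in ("A4", "A3", "C4"):
        tips = first_tips(detect_tips(t, res.theta[w].to_numpy(), eps, whisker=w))
        if tips:
            out[f"{w}_delay"] = float(np.mean([x.delay_ms for x in tips]))
            out[f"{w}_amp"] = float(np.mean([x.amplitude_deg for x in tips]))
    return out


def measure(overrides: dict, duration_ms: float = 750.0, seed: int = 1) -> dict:
    """All calibration observables under the given overrides."""
    obs = _freeair(overrides, max(duration_ms, 1000.0), seed)
    er = _tip_stats("E_R", overrides, duration_ms, seed)
    di = _tip_stats("DIRECT_I_P", overrides, duration_ms, seed)
    ind = _tip_stats("INDIRECT_I_P", overrides, duration_ms, seed)
    obs["er_delay_ms"] = er.get("A4_delay", np.nan)
    obs["er_touch_amp_deg"] = er.get("A4_amp", np.nan)
    obs["direct_delay_ms"] = di.get("A4_delay", np.nan)
    obs["direct_touch_amp_deg"] = di.get("A4_amp", np.nan)
    obs["indirect_touch_amp_deg"] = ind.get("A4_amp", np.nan)
    obs["indirect_nontouch_amp_deg"] = ind.get("C4_amp", np.nan)
    return obs


# (parameter path, observable, relative step for the secant probe, bounds)
_REFINEMENT_PLAN = [
    ("muscle.intrinsic.a_max", "peak_interior_deg", 0.04, (8.0, 16.0)),
    ("muscle.extP_superficial.a_max", "peak_rostral_most_deg", 0.08, (2.0, 7.0)),
    ("sensory.pressure_latency_intercept_ms", "er_delay_ms", 0.25, (0.5, 9.0)),
    ("muscle.extR_superficial.a_max", "er_touch_amp_deg", 0.06, (3.0, 8.0)),
]


def calibrate(targets: dict | None = None, out_path: str | Path | None = None,
              duration_ms: float = 750.0, seed: int = 1,
              max_iter: int = 2, tol_frac: float = 0.02) -> dict:
    """Refine the default constants toward ``targets``; emit file + report.

    Deterministic: the refinement is a fixed sequence of bounded secant steps
    (one observable per knob), accepted only when they reduce that
    observable's residual.  Returns ``{"params", "report", "overrides"}``;
    writes the parameter file to ``out_path`` if given.
    """
    targets = {**DEFAULT_TARGETS, **(targets or {})}
    overrides: dict[str, float] = {}
    base = params_mod.default_params()
    obs = measure(overrides, duration_ms, seed)

    for path, key, step_frac, (lo, hi) in _REFINEMENT_PLAN:
        tgt = targets[key]
        for _ in range(max_iter):
            cur = obs.get(key, np.nan)
            if not np.isfinite(cur) or abs(cur - tgt) <= tol_frac * abs(tgt):
                break
            x0 = overrides.get(path, params_mod.get_path(base, path))
            x1 = float(np.clip(x0 * (1 + step_frac), lo, hi))
            probe = dict(overrides)
            probe[path] = x1
            obs1 = measure(probe, duration_ms, seed)
            y0, y1 = cur, obs1.get(key, np.nan)
            if not np.isfinite(y1) or y1 == y0:
                break
            x_new = float(np.clip(x0 + (tgt - y0) * (x1 - x0) / (y1 - y0), lo, hi))
            trial = dict(overrides)
            trial[path] = x_new
            obs_new = measure(trial, duration_ms, seed)
            if abs(obs_new.get(key, np.inf) - tgt) < abs(cur - tgt):
                overrides, obs = trial, obs_new
            else:
                break

    params = params_mod.apply_overrides(params_mod.default_params(), overrides)
    report = {
        k: {"target": targets[k], "achieved": obs.get(k),
            "residual": (obs.get(k, np.nan) - targets[k])}
        for k in targets
    }
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(params, fh, indent=1)
    return {"params": params, "overrides": overrides, "report": report}
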