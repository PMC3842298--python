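"""Neural dynamics: CPGs, event-driven threshold neurons, and the sensory
transduction of whisker state into the four primary-afferent firing classes.

Neurons are event-driven threshold units, not membrane ODEs: a leaky stimulus
accumulator (time constant ``tau_accum_ms``) integrates weighted synaptic
events; crossing ``threshold`` from Rest (or ``rrp_threshold`` from the
relative refractory period) moves the cell through GenerateAP -> ARP -> RRP.
An action potential is relayed ``t_relay_ms`` after the crossing, so the
minimum inter-spike interval is ``t_relay + ARP``.  Inhibitory events subtract
from the accumulator (floored at zero) and can impose a firing-veto window —
the model's rendering of an inhibitory burst, whose kinetics the underlying
physiology leaves open.

Primary afferents (SN1) fire in four classes: whisking (W) cells tick
quasi-periodically (per-cell jittered period) whenever their whisker is in
motion; contact (C) cells fire once at contact onset; pressure (P) cells fire
repetitively while the whisker presses the obstacle, with a first-spike
latency that grows with the radial distance of contact; detach (D) cells fire
once when contact is lost.  SN1 populations fire as synchronized volleys and
are delivered to second-order cells through fixed 50 % random fan-in masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import ChartDef, ChartInstance, Event, Scheduler, StateDef, Transition, ms

# ---------------------------------------------------------------------------
# pressure latency
# ---------------------------------------------------------------------------


def pressure_latency(r: float, intercept_ms: float = 3.5, slope_ms: float = 25.0) -> float:
    """First-spike latency (ms) of pressure cells for contact at radial fraction r.

    Strictly increasing in r: mechanoreceptor drive at the follicle weakens as
    the lever arm of the contact point grows, so threshold crossing is slower.
    The affine coefficients are calibrated so that end-to-end pump delays span
    12-30 ms over r in [0.2, 0.7] with ~17 ms at r = 0.4.
    """
    if not (0.0 < r <= 1.0):
        raise ValueError(f"radial fraction r={r} outside (0, 1]")
    return intercept_ms + slope_ms * r


# ---------------------------------------------------------------------------
# threshold neuron chart
# ---------------------------------------------------------------------------


@dataclass
class NeuronCfg:
    threshold: float
    rrp_threshold: float
    t_relay_us: int
    arp_us: int
    rrp_us: int
    tau_accum_ms: float

    @classmethod
    def from_dict(cls, d: dict, threshold: float | None = None,
                  rrp_threshold: float | None = None) -> "NeuronCfg":
        return cls(
            threshold=d["threshold"] if threshold is None else threshold,
            rrp_threshold=d["rrp_threshold"] if rrp_threshold is None else rrp_threshold,
            t_relay_us=ms(d["t_relay_ms"]),
            arp_us=ms(d["arp_ms"]),
            rrp_us=ms(d["rrp_ms"]),
            tau_accum_ms=d["tau_accum_ms"],
        )


def _absorb(inst: ChartInstance, ev: Event, gate: str) -> bool:
    """Integrate a synaptic event into the leaky accumulator.

    Returns True iff the accumulator crosses the gate level ("threshold" or
    "rrp_threshold") and no inhibitory veto is active.  Used as a transition
    guard: the accumulator update is the neuron's response to the stimulus
    whether or not it fires.
    """
    p = inst.params
    cfg: NeuronCfg = p["cfg"]
    sched: Scheduler = p["sched"]
    t = sched.clock
    dt_ms = (t - p["accum_t_us"]) / 1000.0
    if dt_ms > 0:
        p["accum"] *= float(np.exp(-dt_ms / cfg.tau_accum_ms))
        p["accum_t_us"] = t
    weight, veto_us = ev.payload
    if weight >= 0:
        p["accum"] += weight
    else:
        p["accum"] = max(0.0, p["accum"] + weight)
        if veto_us > 0:
            p["inhibited_until"] = max(p["inhibited_until"], t + veto_us)
        return False
    if t < p["inhibited_until"]:
        return False
    gate_level = cfg.threshold if gate == "threshold" else cfg.rrp_threshold
    return p["accum"] >= gate_level


def _guard_rest(inst, ev):
    return _absorb(inst, ev, "threshold")


def _guard_rrp(inst, ev):
    return _absorb(inst, ev, "rrp_threshold")


def _absorb_inhib_only(inst, ev):
    """Register an inhibitory veto even in states that ignore excitation
    (GenerateAP, ARP); excitatory events remain without effect there."""
    weight, veto_us = ev.payload
    if weight < 0 and veto_us > 0:
        sched = inst.params["sched"]
        inst.params["inhibited_until"] = max(
            inst.params["inhibited_until"], sched.clock + veto_us)
    return False


def _fire_ap(sched: Scheduler, inst: ChartInstance, ev: Event) -> None:
    """Emit the action potential: one stimulation event per outgoing synapse.

    An inhibitory veto that arrived while the spike was being prepared
    cancels the emission (the cell still passes through its refractory
    sequence)."""
    p = inst.params
    if sched.clock < p["inhibited_until"]:
        p["accum"] = 0.0
        return
    for target_id, weight, veto_us in p["targets"]:
        sched.post_to("stim", target_id, 0, payload=(weight, veto_us), source_id=inst.comp_id)
    p["accum"] = 0.0
    log = p.get("spike_log")
    if log is not None:
        log.append((sched.clock, inst.comp_id, p["cls"], p["subtype"], p["whisker"]))


def _reset_accum(sched, inst, ev):
    inst.params["accum"] = 0.0


def neuron_chart_def() -> ChartDef:
    cfg_relay = lambda inst: inst.params["cfg"].t_relay_us
    cfg_arp = lambda inst: inst.params["cfg"].arp_us
    cfg_rrp = lambda inst: inst.params["cfg"].rrp_us
    return ChartDef(
        "neuron",
        [
            StateDef("Rest", transitions={
                "stim": [Transition("stim", "GenerateAP", guard=_guard_rest)],
            }),
            StateDef("GenerateAP",
                     transitions={
                         "stim": [Transition("stim", "GenerateAP", guard=_absorb_inhib_only)],
                     },
                     timeouts={"fire": cfg_relay}),
            StateDef("ARP", transitions={
                "stim": [Transition("stim", "ARP", guard=_absorb_inhib_only)],
            }, timeouts={"arp": cfg_arp}),
            StateDef("RRP", transitions={
                "stim": [Transition("stim", "GenerateAP", guard=_guard_rrp)],
            }, timeouts={"rrp": cfg_rrp}),
        ],
        initial="Rest",
    )


# transitions out of timeout states are installed on the shared def here
# (kept separate from the constructor for readability)
_NEURON_DEF = neuron_chart_def()
_NEURON_DEF.states["GenerateAP"].transitions["tm:fire"] = [
    Transition("tm:fire", "ARP", actions=[_fire_ap])
]
_NEURON_DEF.states["ARP"].transitions["tm:arp"] = [Transition("tm:arp", "RRP")]
_NEURON_DEF.states["RRP"].transitions["tm:rrp"] = [
    Transition("tm:rrp", "Rest", actions=[_reset_accum])
]


def make_neuron(sched: Scheduler, comp_id: str, cfg: NeuronCfg, cls: str,
                subtype: str, whisker: str, spike_log: list | None) -> ChartInstance:
    inst = ChartInstance(_NEURON_DEF, comp_id, {
        "cfg": cfg, "sched": sched, "accum": 0.0, "accum_t_us": 0,
        "inhibited_until": 0, "targets": [],
        "cls": cls, "subtype": subtype, "whisker": whisker,
        "spike_log": spike_log,
    })
    sched.add_chart(inst)
    return inst


def deliver_stimulus(sched: Scheduler, neuron: ChartInstance, weight: float,
                     veto_us: int = 0, delay_us: int = 0) -> None:
    """Post one weighted synaptic event to a neuron (sign carries E/I)."""
    sched.post_to("stim", neuron.comp_id, delay_us, payload=(weight, veto_us))


# ---------------------------------------------------------------------------
# CPG chart
# ---------------------------------------------------------------------------


def _cpg_can_continue(inst, ev):
    return inst.params["current_cycle"] < inst.params["cycles_num"]


def _cpg_broadcast(sched: Scheduler, inst: ChartInstance, ev: Event) -> None:
    """One stimulation event to every MN of the CPG's type, then advance the
    cycle counter.  While an inhibitory veto is pending the CPG *pauses*: the
    broadcast is skipped and the cycle is not counted, so the stimulation
    budget of the active period resumes when the veto lifts."""
    p = inst.params
    if sched.clock < p["inhibited_until"]:
        return
    if p["weight"] > 0:
        for target_id in p["mn_targets"]:
            sched.post_to("stim", target_id, 0, payload=(p["weight"], 0),
                          source_id=inst.comp_id)
    p["current_cycle"] += 1


def _cpg_reset(sched, inst, ev):
    inst.params["current_cycle"] = 0


def _cpg_inhibit(inst, ev):
    weight, veto_us = ev.payload
    if weight < 0 and veto_us > 0:
        sched = inst.params["sched"]
        inst.params["inhibited_until"] = max(
            inst.params["inhibited_until"], sched.clock + veto_us)
    return False  # never a state change


def _silence_delay(inst) -> int:
    """Relax duration, phase-locked to the CPG's nominal rhythm grid.

    Nominally equal to silenceDuration; if an inhibitory veto paused the
    active period (delaying its completion), the Relax interval shrinks so
    the next Activate still begins on the CPG's own period grid and the
    three CPGs stay mutually phased.
    """
    p = inst.params
    sched: Scheduler = p["sched"]
    period = p["cycles_num"] * p["cycle_us"] + p["silence_us"]
    rem = (p["phase_start_us"] - sched.clock) % period
    return rem if rem > 0 else period


def cpg_chart_def() -> ChartDef:
    cyc = lambda inst: inst.params["cycle_us"]
    sil = _silence_delay
    start = lambda inst: inst.params["phase_start_us"]
    d = ChartDef(
        "cpg",
        [
            StateDef("Init", transitions={}, timeouts={"start": start}),
            StateDef("Activate", transitions={
                "stim": [Transition("stim", "Activate", guard=_cpg_inhibit)],
            }, timeouts={"cycle": cyc}),
            StateDef("Relax", transitions={
                "stim": [Transition("stim", "Relax", guard=_cpg_inhibit)],
            }, timeouts={"silence": sil}),
        ],
        initial="Init",
    )
    d.states["Init"].transitions["tm:start"] = [Transition("tm:start", "Activate")]
    # condition connector after tm(cycleDuration): continue or relax
    d.states["Activate"].transitions["tm:cycle"] = [
        Transition("tm:cycle", "Activate", guard=_cpg_can_continue,
                   actions=[_cpg_broadcast]),
        Transition("tm:cycle", "Relax"),
    ]
    d.states["Relax"].transitions["tm:silence"] = [
        Transition("tm:silence", "Activate", actions=[_cpg_reset])
    ]
    return d


_CPG_DEF = cpg_chart_def()


def make_cpg(sched: Scheduler, comp_id: str, cpg_params: dict, weight: float,
             mn_targets: list[str]) -> ChartInstance:
    inst = ChartInstance(_CPG_DEF, comp_id, {
        "sched": sched,
        "phase_start_us": max(ms(cpg_params["phase_start_ms"]), 1),
        "cycle_us": ms(cpg_params["cycle_duration_ms"]),
        "cycles_num": int(cpg_params["cycles_num"]),
        "silence_us": ms(cpg_params["silence_duration_ms"]),
        "current_cycle": 0,
        "weight": weight,
        "mn_targets": list(mn_targets),
        "inhibited_until": 0,
    })
    sched.add_chart(inst)
    return inst


def cpg_period_ms(cpg_params: dict) -> float:
    """Closed-form CPG period: cyclesNum x cycleDuration + silenceDuration."""
    return (cpg_params["cycles_num"] * cpg_params["cycle_duration_ms"]
            + cpg_params["silence_duration_ms"])


# ---------------------------------------------------------------------------
# SN1 populations and transduction
# ---------------------------------------------------------------------------


@dataclass
class Sn1Pool:
    """One whisker's primary afferents of one class, firing as volleys."""
    whisker: str
    subtype: str  # W | C | P | D
    size: int
    # fan-in masks: (n_sn2, size) booleans, each row one SN2's sampled sources
    fanin: np.ndarray
    sn2_ids: list[str]


def draw_fanin(rng: np.random.Generator, pool_size: int, n_sn2: int,
               fraction: float) -> np.ndarray:
    """Each SN2 samples round(fraction x pool) distinct SN1 sources."""
    k = int(round(fraction * pool_size))
    mask = np.zeros((n_sn2, pool_size), dtype=bool)
    for j in range(n_sn2):
        mask[j, rng.choice(pool_size, size=k, replace=False)] = True
    return mask


class SensoryTransducer:
    """Turns whisker kinematic/contact state into SN1 volleys.

    One instance serves the whole pad.  W cells are sampled at plant-step
    boundaries (vectorized per whisker); C/P/D volleys are driven by the
    plant's contact notifications.  Pressure volleys repeat every
    ``p_period_ms`` while the whisker presses, with the first volley of each
    pressing episode delayed by ``pressure_latency(r)``.
    """

    COMP_ID = "transducer"

    def __init__(self, sched: Scheduler, plant, pools: dict[tuple[str, str], Sn1Pool],
                 sensory_params: dict, volley_gain: float, rng: np.random.Generator,
                 w_active: bool, spike_log: list | None):
        self.sched = sched
        self.plant = plant
        self.pools = pools
        self.gain = volley_gain
        self.sn1_relay_us = ms(sensory_params["sn1_relay_ms"])
        self.p_period_us = ms(sensory_params["p_period_ms"])
        self.lat_intercept = sensory_params["pressure_latency_intercept_ms"]
        self.lat_slope = sensory_params["pressure_latency_slope_ms"]
        self.w_active = w_active
        self.spike_log = spike_log
        self._press_token = 0  # invalidates scheduled P volleys on release
        # per-whisker W-cell phase state
        self.w_state: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if w_active:
            mean = ms(sensory_params["w_period_mean_ms"])
            jit = ms(sensory_params["w_period_jitter_ms"])
            for (wsk, sub), pool in pools.items():
                if sub != "W":
                    continue
                periods = mean + rng.integers(-jit, jit + 1, size=pool.size)
                phases = rng.integers(0, mean, size=pool.size)
                self.w_state[wsk] = (phases.astype(np.int64), periods.astype(np.int64))
        sched.add_handler(self.COMP_ID, self._on_event)

    # -- volley emission ---------------------------------------------
    def _emit_volley(self, whisker: str, subtype: str, t_post_us: int,
                     fired: np.ndarray | None = None) -> None:
        pool = self.pools.get((whisker, subtype))
        if pool is None:
            return
        if fired is None:
            weights = np.full(len(pool.sn2_ids), self.gain)
            n_fired = pool.size
        else:
            k = pool.fanin.sum(axis=1)
            overlap = pool.fanin[:, fired].sum(axis=1)
            weights = self.gain * overlap / np.maximum(k, 1)
            n_fired = int(len(fired))
        if self.spike_log is not None and n_fired:
            self.spike_log.append(
                (self.sched.clock, f"SN1_{subtype}[{whisker}]x{n_fired}",
                 "SN1", subtype, whisker))
        for sn2_id, w in zip(pool.sn2_ids, weights):
            if w > 0:
                self.sched.post_to("stim", sn2_id, self.sn1_relay_us,
                                   payload=(float(w), 0), source_id=self.COMP_ID)

    # -- plant-step hook ---------------------------------------------
    def on_plant_step(self, t_us: int, contact_notifications: list[str]) -> None:
        for note in contact_notifications:
            if note == "contact_onset":
                self._emit_volley(self._obs_whisker(), "C", t_us)
            elif note == "press_on":
                self._press_token += 1
                lat = pressure_latency(self.plant.obstacle.r,
                                       self.lat_intercept, self.lat_slope)
                self.sched.post_to("p_volley", self.COMP_ID, ms(lat),
                                   payload=self._press_token)
            elif note == "press_off":
                self._press_token += 1
            elif note == "detach":
                self._emit_volley(self._obs_whisker(), "D", t_us)
        if self.w_active:
            moving = self.plant.is_moving()
            for wsk, (next_t, periods) in self.w_state.items():
                due = next_t <= t_us
                if due.any():
                    if moving[self.plant.index[wsk]]:
                        self._emit_volley(wsk, "W", t_us, fired=np.flatnonzero(due))
                    next_t[due] += periods[due]

    def _obs_whisker(self) -> str:
        return self.plant.obstacle.whisker

    # -- scheduled pressure volleys -----------------------------------
    def _on_event(self, sched: Scheduler, ev: Event) -> None:
        if ev.kind != "p_volley" or ev.payload != self._press_token:
            return
        if not self.plant.pressing:
            return
        self._emit_volley(self._obs_whisker(), "P", sched.clock)
        sched.post_to("p_volley", self.COMP_ID, self.p_period_us,
                      payload=self._press_token)
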