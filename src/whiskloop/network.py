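"""Construct the full mystacial pad: whisker array, muscle attachment
topology, per-whisker neuron pools, and configuration-dependent wiring.

Pad layout
----------
Five ipsilateral rows: A and B with 4 whiskers, C, D and E with 7 (29 total).
Per row of n whiskers there are n intrinsic sling muscles, indexed 0..n-1 from
caudal to rostral: muscle 0 anchors whisker 1 to the pad; muscle j >= 1 is
slung between whiskers j and j+1, applying 0.75 of its force to its caudal
whisker j and 0.25 to its rostral neighbour j+1.  Every whisker therefore
receives one full unit of intrinsic drive — except the rostral-most whisker of
a seven-whisker row, which lacks a rostral sling and gets only the 0.25
spill-over (this is what depresses its protraction peak).  In four-whisker
rows the missing rostral sling is replaced by a pseudo-intrinsic muscle driven
by the same whisker's intrinsic motoneurons.

Extrinsic muscles act in groups: one superficial protractor per row block
(A-B and C-E), one superficial retractor spanning all rows, and one deep
retractor per row block.  Activating any muscle of a group contracts the whole
group, which is how single-whisker sensory feedback reaches the entire pad.

Wiring
------
Base loop per whisker: SN1_x -> SN2_x (random 50 % fan-in, per subtype), CPGs
-> all MNs of matching type, MNs -> all muscles of matching type attached to
their whisker.  The whisking-mechanism axis selects which pre-synaptic sources
drive the MNs and the MN threshold regime; the TIP-mechanism axis adds the
contact/pressure feedback edges: E-R excites the touching whisker's retractor
MNs, direct I-P inhibits its intrinsic MNs, indirect I-P inhibits the
intrinsic CPG itself.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .engine import ChartDef, ChartInstance, Scheduler, StateDef, Transition, ms
from .neurons import (NeuronCfg, Sn1Pool, SensoryTransducer, draw_fanin,
                      make_cpg, make_neuron)
from .plant import MuscleParams, MuscleState, Obstacle, WhiskerArrayPlant

WHISKING_MECHANISMS = ("CPG_ONLY", "SENSORY_ONLY", "CPG_PLUS_SENSORY")
TIP_MECHANISMS = ("NONE", "E_R", "DIRECT_I_P", "INDIRECT_I_P")

ROWS = (("A", 4), ("B", 4), ("C", 7), ("D", 7), ("E", 7))
SN1_SUBTYPES = ("W", "C", "P", "D")
MN_TYPES = ("Int", "ExtP", "ExtR")


@dataclass
class Configuration:
    """One point on the two mechanism axes, plus the mandatory seed."""

    whisking_mechanism: str = "CPG_ONLY"
    tip_mechanism: str = "NONE"
    seed: int = 1

    def __post_init__(self):
        if self.whisking_mechanism not in WHISKING_MECHANISMS:
            raise ValueError(f"unknown whisking mechanism {self.whisking_mechanism!r}; "
                             f"expected one of {WHISKING_MECHANISMS}")
        if self.tip_mechanism not in TIP_MECHANISMS:
            raise ValueError(f"unknown TIP mechanism {self.tip_mechanism!r}; "
                             f"expected one of {TIP_MECHANISMS}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


class PadLayout:
    """Static whisker/muscle geometry of the modeled pad.

    ``share_caudal``/``share_rostral`` split each intrinsic sling's force
    between its caudal whisker and its rostral neighbour; they sum to one so
    every whisker with a rostral sling receives one full unit of intrinsic
    drive.
    """

    def __init__(self, share_caudal: float = 0.75, share_rostral: float = 0.25):
        self.rows = dict(ROWS)
        self.whiskers: list[str] = [f"{row}{i}" for row, n in ROWS for i in range(1, n + 1)]
        gc, gr = share_caudal, share_rostral
        # muscle_id -> (type, [(whisker_id, signed_share)], [innervating whiskers])
        self.muscles: dict[str, tuple[str, list[tuple[str, float]], list[str]]] = {}
        for row, n in ROWS:
            for j in range(n):
                mid = f"int_{row}{j}"
                if j == 0:
                    attach = [(f"{row}1", +gr)]
                    innerv = [f"{row}1"]
                else:
                    attach = [(f"{row}{j}", +gc), (f"{row}{j+1}", +gr)]
                    innerv = [f"{row}{j}", f"{row}{j+1}"]
                self.muscles[mid] = ("intrinsic", attach, innerv)
            if n == 4:  # rows A-B: pseudo-intrinsic replaces the rostral sling
                w = f"{row}{n}"
                self.muscles[f"pseudo_{row}"] = ("pseudo_intrinsic", [(w, +gc)], [w])
        ab = [w for w in self.whiskers if w[0] in "AB"]
        cde = [w for w in self.whiskers if w[0] in "CDE"]
        self.muscles["extP_AB"] = ("extP_superficial", [(w, +1.0) for w in ab], ab)
        self.muscles["extP_CDE"] = ("extP_superficial", [(w, +1.0) for w in cde], cde)
        self.muscles["extRs_ALL"] = ("extR_superficial", [(w, -1.0) for w in self.whiskers],
                                     list(self.whiskers))
        self.muscles["extRd_AB"] = ("extR_deep", [(w, -1.0) for w in ab], ab)
        self.muscles["extRd_CDE"] = ("extR_deep", [(w, -1.0) for w in cde], cde)

    def muscles_of_whisker(self, whisker: str, mtype_prefix: str) -> list[str]:
        return [mid for mid, (mt, attach, _) in self.muscles.items()
                if mt.startswith(mtype_prefix) and any(w == whisker for w, _ in attach)]

    def neighbors(self, whisker: str) -> list[str]:
        row, idx = whisker[0], int(whisker[1:])
        out = []
        if idx > 1:
            out.append(f"{row}{idx-1}")
        if idx < self.rows[row]:
            out.append(f"{row}{idx+1}")
        return out

    def rostral_most_long_rows(self) -> list[str]:
        return [f"{row}{n}" for row, n in ROWS if n == 7]


# ---------------------------------------------------------------------------
# muscle and whisker charts
# ---------------------------------------------------------------------------


def _muscle_absorb(inst: ChartInstance, ev) -> bool:
    st: MuscleState = inst.params["state"]
    sched: Scheduler = inst.params["sched"]
    dca = ev.payload[0]
    st.stimulate(sched.clock, dca)
    return st.contracting_now


def _muscle_still_contracting(inst, ev) -> bool:
    st: MuscleState = inst.params["state"]
    sched: Scheduler = inst.params["sched"]
    return st.contracting_at(sched.clock)


def _muscle_moves(sched: Scheduler, inst: ChartInstance, ev) -> None:
    for wid in inst.params["whisker_charts"]:
        sched.post_to("move", wid, 0, source_id=inst.comp_id)


def _relax_delay(inst) -> int:
    return ms(inst.params["state"].ms_to_relax()) + 1


def muscle_chart_def() -> ChartDef:
    d = ChartDef(
        "muscle",
        [
            StateDef("Rest", transitions={
                "stim": [Transition("stim", "Contract", guard=_muscle_absorb,
                                    actions=[_muscle_moves])],
            }),
            StateDef("Contract", transitions={
                "stim": [Transition("stim", "Contract", guard=_muscle_absorb,
                                    actions=[_muscle_moves])],
            }, timeouts={"relax": _relax_delay}),
        ],
        initial="Rest",
    )
    d.states["Contract"].transitions["tm:relax"] = [
        Transition("tm:relax", "Contract", guard=_muscle_still_contracting),
        Transition("tm:relax", "Rest"),
    ]
    return d


_MUSCLE_DEF = muscle_chart_def()

_WHISKER_DEF = ChartDef(
    "whisker",
    [
        StateDef("Rest", transitions={"move": [Transition("move", "Move")]}),
        StateDef("Move", transitions={"settle": [Transition("settle", "Rest")]}),
    ],
    initial="Rest",
)


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------


@dataclass
class Network:
    config: Configuration
    layout: PadLayout
    sched: Scheduler
    plant: WhiskerArrayPlant
    transducer: SensoryTransducer
    cpgs: dict[str, ChartInstance]
    sn2: dict[tuple[str, str], list[ChartInstance]]     # (whisker, subtype) -> pool
    mns: dict[tuple[str, str], list[ChartInstance]]     # (whisker, type) -> pool
    muscles: dict[str, ChartInstance]
    muscle_states: dict[str, MuscleState]
    whisker_charts: dict[str, ChartInstance]
    sn1_pools: dict[tuple[str, str], Sn1Pool]
    synapses: list[tuple[str, str, float, int]]         # (pre, post, weight, sign)
    spike_log: list
    # attachment arrays for fast torque assembly
    _attach: list[tuple[MuscleState, np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def sn1_total(self) -> int:
        return sum(p.size for p in self.sn1_pools.values())

    def compute_torques(self, t_us: int) -> np.ndarray:
        torque = np.zeros(len(self.plant.ids))
        for st, idx, shares in self._attach:
            f = st.advance_force(t_us)
            if f != 0.0:
                torque[idx] += f * shares
        return torque

    def synapse_hash(self) -> str:
        h = hashlib.sha256()
        for pre, post, w, s in self.synapses:
            h.update(f"{pre}|{post}|{w:.9g}|{s};".encode())
        return h.hexdigest()

    def describe(self) -> dict[str, Any]:
        """JSON-serializable description for inspection and diffing."""
        return {
            "configuration": vars(self.config),
            "whiskers": self.plant.ids,
            "muscles": {mid: {"type": mt, "attachments": attach}
                        for mid, (mt, attach, _) in self.layout.muscles.items()},
            "populations": {
                "sn1_per_whisker": {s: self.sn1_pools[("A1", s)].size for s in SN1_SUBTYPES},
                "sn1_total": self.sn1_total,
                "sn2_per_subtype": len(self.sn2[("A1", "W")]),
                "mn_per_type": len(self.mns[("A1", "Int")]),
            },
            "n_synapses": len(self.synapses),
            "synapse_hash": self.synapse_hash(),
        }


def build_network(config: Configuration, params: dict,
                  obstacle: Obstacle | None = None,
                  record_trace: bool = False,
                  keep_spikes: bool = True) -> Network:
    """Wire the complete pad for one run configuration.

    Deterministic given ``config.seed``: the RNG drives only the SN2 fan-in
    draws and the W-cell period jitter, in a fixed construction order.
    """
    rng = np.random.default_rng(config.seed)
    mint = params["muscle"]["intrinsic"]
    layout = PadLayout(mint.get("share_caudal", 0.75), mint.get("share_rostral", 0.25))
    sched = Scheduler(record_trace=record_trace, log_discarded=False)
    plant = WhiskerArrayPlant(layout.whiskers, params["plant"], obstacle)
    spike_log: list = [] if keep_spikes else None

    mech = config.whisking_mechanism
    syn = params["synapses"]
    thr, rrp_thr = syn["mn_threshold"][mech]
    mn_cfg = NeuronCfg.from_dict(params["neuron"]["MN"], threshold=thr, rrp_threshold=rrp_thr)
    sn2_cfg = NeuronCfg.from_dict(params["neuron"]["SN2"])
    synapses: list[tuple[str, str, float, int]] = []

    # --- neuron pools -------------------------------------------------
    n_sn2 = params["population"]["sn2_pool"]
    n_mn = params["population"]["mn_pool"]
    sn1_counts = params["population"]["sn1_per_whisker"]
    fanin_frac = params["population"]["sn2_fan_in_fraction"]

    sn2: dict[tuple[str, str], list[ChartInstance]] = {}
    mns: dict[tuple[str, str], list[ChartInstance]] = {}
    sn1_pools: dict[tuple[str, str], Sn1Pool] = {}
    for w in layout.whiskers:
        for sub in SN1_SUBTYPES:
            pool = [make_neuron(sched, f"SN2_{sub}[{w}]{i}", sn2_cfg, "SN2", sub, w, spike_log)
                    for i in range(n_sn2)]
            sn2[(w, sub)] = pool
            size = sn1_counts[sub]
            fanin = draw_fanin(rng, size, n_sn2, fanin_frac)
            sn1_pools[(w, sub)] = Sn1Pool(w, sub, size, fanin, [n.comp_id for n in pool])
            for j, n in enumerate(pool):
                k = int(fanin[j].sum())
                for src in np.flatnonzero(fanin[j]):
                    synapses.append((f"SN1_{sub}[{w}]{src}", n.comp_id,
                                     syn["sn1_to_sn2_volley_gain"] / k, +1))
        for typ in MN_TYPES:
            mns[(w, typ)] = [make_neuron(sched, f"MN_{typ}[{w}]{i}", mn_cfg, "MN", typ, w, spike_log)
                             for i in range(n_mn)]

    # --- muscles ------------------------------------------------------
    muscles: dict[str, ChartInstance] = {}
    muscle_states: dict[str, MuscleState] = {}
    attach: list[tuple[MuscleState, np.ndarray, np.ndarray]] = []
    whisker_charts: dict[str, ChartInstance] = {}
    for w in layout.whiskers:
        wc = ChartInstance(_WHISKER_DEF, f"whisker[{w}]", {})
        sched.add_chart(wc)
        whisker_charts[w] = wc
    for mid, (mtype, attachments, innerv) in layout.muscles.items():
        mp = MuscleParams.from_dict(params["muscle"][mtype])
        st = MuscleState(mp)
        inst = ChartInstance(_MUSCLE_DEF, mid, {
            "sched": sched, "state": st,
            "whisker_charts": [f"whisker[{w}]" for w, _ in attachments],
        })
        sched.add_chart(inst)
        muscles[mid] = inst
        muscle_states[mid] = st
        idx = np.array([plant.index[w] for w, _ in attachments], dtype=int)
        shares = np.array([s for _, s in attachments], dtype=float)
        attach.append((st, idx, shares))
        # per-AP calcium increments (innervation-normalized for slings so a
        # full synchronized volley always bumps Ca by dca_volley; per-pool for
        # extrinsic groups so single-whisker feedback volleys stay effective)
        if mtype in ("intrinsic", "pseudo_intrinsic"):
            dca = mp.dca_volley / (len(innerv) * n_mn)
        else:
            dca = mp.dca_volley / n_mn
        mn_type = {"intrinsic": "Int", "pseudo_intrinsic": "Int",
                   "extP_superficial": "ExtP",
                   "extR_superficial": "ExtR", "extR_deep": "ExtR"}[mtype]
        for w in innerv:
            for n in mns[(w, mn_type)]:
                n.params["targets"].append((mid, dca, 0))
                synapses.append((n.comp_id, mid, dca, +1))

    # --- CPGs ---------------------------------------------------------
    cpg_w = syn["cpg_to_mn"][mech]
    cpgs: dict[str, ChartInstance] = {}
    for typ in MN_TYPES:
        targets = [n.comp_id for w in layout.whiskers for n in mns[(w, typ)]]
        cpgs[typ] = make_cpg(sched, f"CPG_{typ}", params["cpg"][typ], cpg_w, targets)
        if cpg_w > 0:
            synapses.extend((f"CPG_{typ}", t, cpg_w, +1) for t in targets)

    # --- whisking-mechanism sensory drive ------------------------------
    w_weight = syn["sn2w_to_mn"][mech]
    if w_weight > 0:
        for w in layout.whiskers:
            for n in sn2[(w, "W")]:
                for typ in MN_TYPES:
                    for m in mns[(w, typ)]:
                        n.params["targets"].append((m.comp_id, w_weight, 0))
                        synapses.append((n.comp_id, m.comp_id, w_weight, +1))

    # --- TIP-mechanism feedback edges ----------------------------------
    tip = config.tip_mechanism
    for w in layout.whiskers:
        if tip == "E_R":
            for n in sn2[(w, "P")]:
                for m in mns[(w, "ExtR")]:
                    n.params["targets"].append((m.comp_id, syn["sn2p_to_extr_mn"], 0))
                    synapses.append((n.comp_id, m.comp_id, syn["sn2p_to_extr_mn"], +1))
            for n in sn2[(w, "C")]:
                for m in mns[(w, "ExtR")]:
                    n.params["targets"].append((m.comp_id, syn["sn2c_to_extr_mn"], 0))
                    synapses.append((n.comp_id, m.comp_id, syn["sn2c_to_extr_mn"], +1))
        elif tip == "DIRECT_I_P":
            veto = ms(syn["veto_direct_ms"])
            for n in sn2[(w, "P")]:
                for m in mns[(w, "Int")]:
                    n.params["targets"].append((m.comp_id, -syn["sn2p_inhib_weight"], veto))
                    synapses.append((n.comp_id, m.comp_id, -syn["sn2p_inhib_weight"], -1))
            for n in sn2[(w, "C")]:
                for m in mns[(w, "Int")]:
                    n.params["targets"].append((m.comp_id, -syn["sn2c_inhib_weight"], 0))
                    synapses.append((n.comp_id, m.comp_id, -syn["sn2c_inhib_weight"], -1))
        elif tip == "INDIRECT_I_P":
            veto = ms(syn["veto_indirect_ms"])
            for n in sn2[(w, "P")]:
                n.params["targets"].append(("CPG_Int", -syn["sn2p_inhib_weight"], veto))
                synapses.append((n.comp_id, "CPG_Int", -syn["sn2p_inhib_weight"], -1))
            for n in sn2[(w, "C")]:
                n.params["targets"].append(("CPG_Int", -syn["sn2c_inhib_weight"], 0))
                synapses.append((n.comp_id, "CPG_Int", -syn["sn2c_inhib_weight"], -1))

    # --- transducer ----------------------------------------------------
    w_active = mech != "CPG_ONLY"
    transducer = SensoryTransducer(
        sched, plant, sn1_pools, params["sensory"],
        syn["sn1_to_sn2_volley_gain"], rng, w_active, spike_log)

    # start all charts (arms CPG phase offsets)
    for inst in sched.components.values():
        sched.start_chart(inst)

    return Network(config, layout, sched, plant, transducer, cpgs, sn2, mns,
                   muscles, muscle_states, whisker_charts, sn1_pools, synapses,
                   spike_log if keep_spikes else [], _attach=attach)
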