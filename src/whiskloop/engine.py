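"""Minimal executable-statechart semantics under a deterministic discrete-event scheduler.

The engine implements exactly the statechart dialect the brainstem-loop model
needs: flat states, event-triggered transitions with guards (condition
connectors are expressed as guard-ordered transition lists), entry-armed
timeouts, and actions that post further events.  Time is an integer
microsecond counter; events due at the same instant are dispatched in posting
order (FIFO), which makes every run bit-reproducible.

Run-to-completion holds by construction: :meth:`Scheduler.dispatch` processes
one event fully — exit, actions, entry, timeout re-arming — before the next
event is popped.  Actions may only *post* events (with non-negative delay),
never dispatch them.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Sequence

US_PER_MS = 1000


def ms(x: float) -> int:
    """Convert milliseconds to the integer-microsecond clock."""
    return int(round(x * US_PER_MS))


class SchedulerError(ValueError):
    """Raised for contract violations (negative delay, unknown component)."""


@dataclass
class Event:
    """A timed message addressed to one component.

    ``due_us`` and ``seq`` are assigned by the scheduler when the event is
    posted; ``seq`` is a strictly increasing insertion counter used to break
    equal-time ties FIFO.
    """

    kind: str
    target_id: str
    payload: Any = None
    source_id: str | None = None
    due_us: int = 0
    seq: int = -1

    def __lt__(self, other: "Event") -> bool:  # heap ordering
        return (self.due_us, self.seq) < (other.due_us, other.seq)


@dataclass
class Transition:
    """Guarded, event-triggered edge between two states of a chart.

    ``guard`` receives ``(instance, event)`` and defaults to always-true.
    ``actions`` run after exiting the source state and before entering the
    target state; each receives ``(scheduler, instance, event)``.
    """

    trigger: str
    target: str
    guard: Callable[["ChartInstance", Event], bool] | None = None
    actions: Sequence[Callable[["Scheduler", "ChartInstance", Event], None]] = ()


@dataclass
class StateDef:
    """A flat state: its outgoing transitions and the timeouts armed on entry.

    ``timeouts`` maps a tag to a delay in µs, or to a callable
    ``(instance) -> µs`` evaluated at entry time (used e.g. for the muscle's
    calcium-threshold crossing).  A timeout with tag ``t`` matches transitions
    whose trigger is ``"tm:t"``.
    """

    name: str
    transitions: dict[str, list[Transition]] = field(default_factory=dict)
    timeouts: dict[str, int | Callable[["ChartInstance"], int]] = field(default_factory=dict)


class ChartDef:
    """Immutable description of one statechart (shared by many instances)."""

    def __init__(self, name: str, states: Iterable[StateDef], initial: str):
        self.name = name
        self.states: dict[str, StateDef] = {s.name: s for s in states}
        if initial not in self.states:
            raise SchedulerError(f"initial state {initial!r} not among states")
        self.initial = initial
        for s in self.states.values():
            for trans_list in s.transitions.values():
                for tr in trans_list:
                    if tr.target not in self.states:
                        raise SchedulerError(
                            f"transition target {tr.target!r} missing from chart {name!r}"
                        )


class ChartInstance:
    """One live copy of a chart: current state, parameters, timeout bookkeeping.

    Exactly one active leaf state is held at all times (``state``).  Entering a
    state bumps ``entry_token``; timeout events stamped with an older token are
    stale and silently discarded, which implements "entering a state cancels
    that state's stale timeouts".
    """

    __slots__ = ("chart", "comp_id", "state", "params", "entry_token")

    def __init__(self, chart: ChartDef, comp_id: str, params: dict[str, Any] | None = None):
        self.chart = chart
        self.comp_id = comp_id
        self.state = chart.initial
        self.params: dict[str, Any] = params if params is not None else {}
        self.entry_token = 0

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{self.chart.name}:{self.comp_id} in {self.state}>"


@dataclass
class TransitionRecord:
    t_us: int
    component: str
    event: str
    from_state: str
    to_state: str | None  # None for a discarded event
    status: str  # "fired" | "discarded"

    def to_json(self) -> str:
        return json.dumps(
            {
                "t_us": self.t_us,
                "component": self.component,
                "event": self.event,
                "from_state": self.from_state,
                "to_state": self.to_state,
            }
        )


class Scheduler:
    """Global discrete-event scheduler ordering all component interactions.

    Components are either :class:`ChartInstance` objects or plain handlers
    (callables ``(scheduler, event) -> None``) for plumbing such as the run
    manager.  The clock is non-decreasing; dispatch order for equal due times
    is insertion order.
    """

    def __init__(self, record_trace: bool = True, log_discarded: bool = True):
        self.clock: int = 0
        self._heap: list[Event] = []
        self._seq: int = 0
        self.components: dict[str, ChartInstance] = {}
        self.handlers: dict[str, Callable[["Scheduler", Event], None]] = {}
        self.trace: list[TransitionRecord] = []
        self.record_trace = record_trace
        self.log_discarded = log_discarded

    # -- registration -------------------------------------------------
    def add_chart(self, inst: ChartInstance) -> ChartInstance:
        if inst.comp_id in self.components or inst.comp_id in self.handlers:
            raise SchedulerError(f"duplicate component id {inst.comp_id!r}")
        self.components[inst.comp_id] = inst
        return inst

    def add_handler(self, comp_id: str, fn: Callable[["Scheduler", Event], None]) -> None:
        if comp_id in self.components or comp_id in self.handlers:
            raise SchedulerError(f"duplicate component id {comp_id!r}")
        self.handlers[comp_id] = fn

    # -- posting ------------------------------------------------------
    def post(self, event: Event, delay_us: int = 0) -> Event:
        """Enqueue ``event`` at ``clock + delay_us`` with a fresh sequence number."""
        if delay_us < 0:
            raise SchedulerError(f"negative delay {delay_us} µs")
        event.due_us = self.clock + delay_us
        event.seq = self._seq
        self._seq += 1
        heapq.heappush(self._heap, event)
        return event

    def post_to(self, kind: str, target_id: str, delay_us: int = 0,
                payload: Any = None, source_id: str | None = None) -> Event:
        return self.post(Event(kind, target_id, payload, source_id), delay_us)

    # -- state entry --------------------------------------------------
    def _enter_state(self, inst: ChartInstance, state_name: str) -> None:
        inst.state = state_name
        inst.entry_token += 1
        sdef = inst.chart.states[state_name]
        for tag, delay in sdef.timeouts.items():
            d = delay(inst) if callable(delay) else delay
            self.post(
                Event(
                    kind=f"tm:{tag}",
                    target_id=inst.comp_id,
                    payload=inst.entry_token,
                    source_id=inst.comp_id,
                ),
                d,
            )

    def start_chart(self, inst: ChartInstance) -> None:
        """Arm the initial state's timeouts (call once after registration)."""
        self._enter_state(inst, inst.state)

    # -- dispatch -----------------------------------------------------
    def dispatch(self) -> TransitionRecord | None:
        """Pop and deliver the earliest event; advance the clock to its due time.

        Returns the transition record for a fired transition, ``None`` for a
        handler delivery, a discarded event, or a stale timeout.
        """
        if not self._heap:
            raise SchedulerError("dispatch on empty queue")
        ev = heapq.heappop(self._heap)
        self.clock = ev.due_us

        handler = self.handlers.get(ev.target_id)
        if handler is not None:
            handler(self, ev)
            return None

        inst = self.components.get(ev.target_id)
        if inst is None:
            raise SchedulerError(f"event {ev.kind!r} addressed to unknown component {ev.target_id!r}")

        if ev.kind.startswith("tm:") and ev.payload != inst.entry_token:
            return None  # stale timeout from a state exited since it was armed

        sdef = inst.chart.states[inst.state]
        candidates = sdef.transitions.get(ev.kind)
        fired: Transition | None = None
        if candidates:
            for tr in candidates:
                if tr.guard is None or tr.guard(inst, ev):
                    fired = tr
                    break

        if fired is None:
            if self.record_trace and self.log_discarded:
                rec = TransitionRecord(self.clock, inst.comp_id, ev.kind, inst.state, None, "discarded")
                self.trace.append(rec)
                return rec
            return None

        from_state = inst.state
        for action in fired.actions:
            action(self, inst, ev)
        self._enter_state(inst, fired.target)
        if self.record_trace:
            rec = TransitionRecord(self.clock, inst.comp_id, ev.kind, from_state, fired.target, "fired")
            self.trace.append(rec)
            return rec
        return None

    def run_until(self, t_end_us: int) -> list[TransitionRecord]:
        """Dispatch every event with due time <= ``t_end_us``; clock ends at ``t_end_us``."""
        if t_end_us < self.clock:
            raise SchedulerError(f"t_end {t_end_us} precedes clock {self.clock}")
        while self._heap and self._heap[0].due_us <= t_end_us:
            self.dispatch()
        self.clock = max(self.clock, t_end_us)
        return self.trace

    @property
    def queue_empty(self) -> bool:
        return not self._heap

    def next_due(self) -> int | None:
        return self._heap[0].due_us if self._heap else None

    # -- export -------------------------------------------------------
    def write_trace_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.trace:
                fh.write(rec.to_json() + "\n")
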