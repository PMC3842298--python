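"""Neuron refractory dynamics, CPG cycling, fan-in draws and the
pressure-latency mapping."""

import numpy as np
import pytest

from whiskloop.engine import Event, Scheduler, ms
from whiskloop.neurons import (NeuronCfg, cpg_period_ms, deliver_stimulus,
                               draw_fanin, make_cpg, make_neuron,
                               pressure_latency)

CFG = dict(threshold=1.0, rrp_threshold=2.0, t_relay_ms=1.0, arp_ms=3.0,
           rrp_ms=15.0, tau_accum_ms=10.0)


def fresh_neuron(**over):
    sched = Scheduler(record_trace=False)
    log = []
    cfg = NeuronCfg.from_dict({**CFG, **over})
    n = make_neuron(sched, "n0", cfg, "MN", "Int", "A1", log)
    return sched, n, log


# ---------------------------------------------------------------------------
# threshold / refractory behaviour
# ---------------------------------------------------------------------------


def test_suprathreshold_stimulus_fires_after_relay():
    sched, n, log = fresh_neuron()
    deliver_stimulus(sched, n, 1.5, delay_us=ms(5))
    sched.run_until(ms(20))
    assert len(log) == 1
    assert log[0][0] == ms(6)  # stimulus at 5 ms + 1 ms relay


def test_subthreshold_accumulation_leaks_away():
    sched, n, log = fresh_neuron()
    deliver_stimulus(sched, n, 0.6, delay_us=ms(0))
    deliver_stimulus(sched, n, 0.6, delay_us=ms(30))  # leaked long before
    sched.run_until(ms(50))
    assert log == []
    # close in time, the same pair integrates past threshold
    sched2, n2, log2 = fresh_neuron()
    deliver_stimulus(sched2, n2, 0.6, delay_us=ms(0))
    deliver_stimulus(sched2, n2, 0.6, delay_us=ms(1))
    sched2.run_until(ms(10))
    assert len(log2) == 1


def test_stimulus_during_arp_is_ignored():
    sched, n, log = fresh_neuron()
    deliver_stimulus(sched, n, 1.5, delay_us=ms(1))   # fires at 2 ms, ARP to 5 ms
    deliver_stimulus(sched, n, 5.0, delay_us=ms(3))   # lands in ARP
    sched.run_until(ms(30))
    assert len(log) == 1
    assert n.params["accum"] == 0.0


def test_rrp_needs_stronger_stimulus():
    # during RRP a threshold-level input fails, an rrp_threshold-level fires
    sched, n, log = fresh_neuron()
    deliver_stimulus(sched, n, 1.5, delay_us=ms(1))    # AP at 2, ARP->5, RRP->20
    deliver_stimulus(sched, n, 1.2, delay_us=ms(8))    # < rrp_threshold: no AP
    sched.run_until(ms(50))
    assert len(log) == 1
    sched2, n2, log2 = fresh_neuron()
    deliver_stimulus(sched2, n2, 1.5, delay_us=ms(1))
    deliver_stimulus(sched2, n2, 2.5, delay_us=ms(8))  # >= rrp_threshold
    sched2.run_until(ms(50))
    assert len(log2) == 2


def test_min_interspike_interval_is_relay_plus_arp():
    """Dense stimulus train: spike spacing never beats t_relay + ARP."""
    sched, n, log = fresh_neuron()
    for k in range(0, 400):
        deliver_stimulus(sched, n, 3.0, delay_us=k * ms(0.2))
    sched.run_until(ms(100))
    times = np.array([t for t, *_ in log], dtype=float)
    assert len(times) > 3
    min_isi = np.diff(times).min() / 1000.0
    assert min_isi >= CFG["t_relay_ms"] + CFG["arp_ms"]
    assert min_isi <= CFG["t_relay_ms"] + CFG["arp_ms"] + 1.0


def test_inhibition_depletes_accumulator_and_vetoes():
    sched, n, log = fresh_neuron()
    # inhibitory burst with a 10 ms veto window
    sched.post(Event("stim", "n0", payload=(-5.0, ms(10))), ms(1))
    deliver_stimulus(sched, n, 1.5, delay_us=ms(5))   # vetoed
    deliver_stimulus(sched, n, 1.5, delay_us=ms(20))  # after veto: fires
    sched.run_until(ms(40))
    assert [t for t, *_ in log] == [ms(21)]
    assert n.params["accum"] == 0.0  # reset on firing


def test_accumulator_floors_at_zero_under_inhibition():
    sched, n, _ = fresh_neuron()
    deliver_stimulus(sched, n, 0.5, delay_us=0)
    sched.post(Event("stim", "n0", payload=(-9.0, 0)), ms(1))
    sched.run_until(ms(2))
    assert n.params["accum"] == 0.0


# ---------------------------------------------------------------------------
# CPG
# ---------------------------------------------------------------------------

CPG_PARAMS = dict(phase_start_ms=0.0, cycle_duration_ms=5.0, cycles_num=8,
                  silence_duration_ms=110.0)


def counting_cpg(cpg_params=CPG_PARAMS, weight=2.4):
    sched = Scheduler(record_trace=False)
    volleys = []
    sched.add_handler("mn", lambda s, ev: volleys.append(s.clock))
    cpg = make_cpg(sched, "CPG_Int", cpg_params, weight, ["mn"])
    sched.start_chart(cpg)
    return sched, cpg, volleys


def test_cpg_emits_cycles_num_bursts_then_relaxes():
    sched, cpg, volleys = counting_cpg()
    period = cpg_period_ms(CPG_PARAMS)
    assert period == 150.0
    sched.run_until(ms(2 * period))
    # closed form: cycles_num volleys per period
    assert len(volleys) == 2 * CPG_PARAMS["cycles_num"]
    # inter-burst period between corresponding volleys equals the closed form
    assert volleys[CPG_PARAMS["cycles_num"]] - volleys[0] == ms(period)


def test_cpg_boundary_cycle_enters_relax_without_extra_volley():
    sched, cpg, volleys = counting_cpg()
    sched.run_until(ms(60))  # active window is 8 x 5 = 40 ms + start offset
    n_active = len(volleys)
    sched.run_until(ms(100))  # still inside silence
    assert len(volleys) == n_active == CPG_PARAMS["cycles_num"]


def test_cpg_veto_pauses_bursts_and_keeps_the_rhythm_grid():
    sched, cpg, volleys = counting_cpg()
    # veto covering part of the active window of the second period
    sched.post(Event("stim", "CPG_Int", payload=(-3.0, ms(12))), ms(155))
    sched.run_until(ms(3 * 150))
    # the vetoed volleys are made up after the veto lifts (pause semantics):
    # every period still delivers its full stimulation budget
    assert len(volleys) == 3 * CPG_PARAMS["cycles_num"]
    # and the third period starts back on the nominal grid
    third = [v for v in volleys if v >= ms(300)]
    assert third[0] == volleys[0] + ms(300)


# ---------------------------------------------------------------------------
# fan-in and latency
# ---------------------------------------------------------------------------


def test_fanin_sizes_and_reproducibility():
    rng1 = np.random.default_rng(7)
    rng2 = np.random.default_rng(7)
    m1 = draw_fanin(rng1, pool_size=73, n_sn2=10, fraction=0.5)
    m2 = draw_fanin(rng2, pool_size=73, n_sn2=10, fraction=0.5)
    assert m1.shape == (10, 73)
    assert np.array_equal(m1, m2)
    assert (m1.sum(axis=1) == round(0.5 * 73)).all()  # without replacement


def test_pressure_latency_monotone_and_validated():
    assert pressure_latency(0.6) > pressure_latency(0.3)
    rs = np.linspace(0.05, 1.0, 20)
    lats = [pressure_latency(r) for r in rs]
    assert all(b > a for a, b in zip(lats, lats[1:]))
    for bad in (0.0, -0.1, 1.2):
        with pytest.raises(ValueError):
            pressure_latency(bad)
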