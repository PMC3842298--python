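"""Muscle calcium/force dynamics, rigid-whisker mechanics and contact logic."""

import math

import numpy as np
import pytest

from whiskloop.engine import ms
from whiskloop.plant import (ContactEpisode, MuscleParams, MuscleState,
                             Obstacle, WhiskerArrayPlant, contact_events,
                             muscle_force, whisker_step)

MP = dict(dca_volley=1.0, tau_ca_ms=10.0, ca0=0.8, ca_sat=0.3, ca_max=50.0,
          a_max=5.0, tau_act_ms=3.0, tau_deact_ms=3.0, trigger_frac=0.7,
          hold_ms=6.5)

PLANT = dict(dt_ms=0.5, theta_rest_deg=70.0, inertia=6.0, damping=9.5,
             stiffness=1.0, eps_contact_deg=2.0, rest_theta_tol_deg=0.5,
             rest_omega_tol=0.005)


def make_muscle(**over):
    return MuscleState(MuscleParams.from_dict({**MP, **over}))


# ---------------------------------------------------------------------------
# calcium dynamics
# ---------------------------------------------------------------------------


def test_calcium_decays_to_zero_without_stimulation():
    st = make_muscle()
    st.stimulate(0, 1.0)
    assert st.ca_at(ms(200)) < 1e-8


def test_single_subthreshold_volley_keeps_rest():
    st = make_muscle(ca0=1.4)
    st.stimulate(0, 1.0)
    assert not st.contracting_now
    assert muscle_force(st, ms(5)) == 0.0


def test_weak_volley_does_not_refresh_tetanus_hold():
    st = make_muscle()
    st.stimulate(0, 1.0)                       # full volley: hold armed
    hold0 = st.hold_until_us
    st.stimulate(ms(3), 0.5)                   # half volley: hold unchanged
    assert st.hold_until_us == hold0
    st.stimulate(ms(5), 1.0)
    assert st.hold_until_us == ms(5) + ms(MP["hold_ms"])


def test_ca_plateau_matches_geometric_series_closed_form():
    """Volley train at interval D: Ca just after volley n is
    d (1 - r^n) / (1 - r) with r = exp(-D/tau) — the independent oracle."""
    st = make_muscle()
    d, interval = 1.0, 5.0
    r = math.exp(-interval / MP["tau_ca_ms"])
    for n in range(1, 25):
        ca = st.stimulate(ms((n - 1) * interval), d)
        expected = d * (1 - r ** n) / (1 - r)
        assert ca == pytest.approx(expected, rel=1e-12)
    # plateau: contraction is sustained iff the plateau stays above ca0
    assert st.contracting_now == (d / (1 - r) * r >= MP["ca0"])


def test_ca_cap_models_sarcoplasmic_ceiling():
    st = make_muscle(ca_max=2.0)
    st.stimulate(0, 10.0)
    assert st.ca == 2.0


def test_force_zero_at_threshold_and_saturates_at_a_max():
    st = make_muscle()
    st.stimulate(0, MP["ca0"])        # exactly at threshold
    assert st.force_target(0) == pytest.approx(0.0)
    st2 = make_muscle(ca_max=1e9)
    st2.stimulate(0, 1e6)             # far above threshold
    assert st2.force_target(0) == pytest.approx(MP["a_max"], rel=1e-3)


def test_relax_time_is_min_of_hold_and_calcium_crossing():
    st = make_muscle()
    st.stimulate(0, 3.0)
    ca_cross = MP["tau_ca_ms"] * math.log(3.0 / MP["ca0"])
    assert st.ms_to_relax() == pytest.approx(min(MP["hold_ms"], ca_cross))


# ---------------------------------------------------------------------------
# whisker dynamics
# ---------------------------------------------------------------------------


def test_constant_torque_steady_state_matches_linear_ode_fixed_point():
    """theta* = theta_rest + A/k, from the analytic fixed point."""
    theta, omega = 70.0, 0.0
    A, k = 6.0, 1.0
    for _ in range(4000):
        theta, omega = whisker_step(theta, omega, A, 0.5, 6.0, 9.5, k, 70.0)
    assert theta == pytest.approx(70.0 + A / k, abs=1e-6)
    assert omega == pytest.approx(0.0, abs=1e-8)


def test_rest_state_is_global_attractor_from_random_states():
    rng = np.random.default_rng(0)
    for _ in range(20):
        theta = float(rng.uniform(40, 110))
        omega = float(rng.uniform(-2, 2))
        for _ in range(4000):
            theta, omega = whisker_step(theta, omega, 0.0, 0.5, 6.0, 9.5, 1.0, 70.0)
        assert theta == pytest.approx(70.0, abs=1e-6)
        assert omega == pytest.approx(0.0, abs=1e-8)


def test_zero_force_at_rest_stays_at_rest():
    plant = WhiskerArrayPlant(["A1"], PLANT)
    for step in range(100):
        plant.step((step + 1) * ms(0.5), np.zeros(1))
    assert plant.theta[0] == 70.0 and plant.omega[0] == 0.0
    assert not plant.is_moving()[0]


def test_nonfinite_force_aborts_with_diagnostic():
    plant = WhiskerArrayPlant(["A1"], PLANT)
    with pytest.raises(FloatingPointError, match="A1"):
        plant.step(ms(0.5), np.array([np.nan]))


# ---------------------------------------------------------------------------
# obstacle contact
# ---------------------------------------------------------------------------


def test_obstacle_radial_fraction_validated():
    with pytest.raises(ValueError):
        Obstacle("A4", 75.0, 0.0)
    with pytest.raises(ValueError):
        Obstacle("A4", 75.0, 1.5)


def drive_plant(torques):
    """Integrate a single whisker against an obstacle at 75 deg, returning
    (theta trace, notification list)."""
    plant = WhiskerArrayPlant(["A4"], PLANT, Obstacle("A4", 75.0, 0.4))
    notes, thetas = [], []
    for step, tq in enumerate(torques):
        ev = plant.step((step + 1) * ms(0.5), np.array([tq]))
        notes.extend((((step + 1) * 0.5), e) for e in ev)
        thetas.append(plant.theta[0])
    return np.array(thetas), notes, plant


def test_protraction_into_obstacle_clamps_and_presses():
    th, notes, plant = drive_plant([8.0] * 400)
    kinds = [k for _, k in notes]
    assert kinds[:2] == ["contact_onset", "press_on"]
    assert th.max() == pytest.approx(75.0)  # clamped at the obstacle
    assert plant.pressing


def test_full_retraction_generates_single_episode_with_detach():
    torques = [8.0] * 300 + [-4.0] * 400
    th, notes, plant = drive_plant(torques)
    kinds = [k for _, k in notes]
    assert kinds.count("contact_onset") == 1
    assert kinds.count("detach") == 1
    ep = plant.episodes[0]
    assert ep.offset_us is not None and ep.offset_us > ep.onset_us


def test_small_dip_keeps_contact_through_the_pump():
    """A retraction smaller than the bending reserve releases the press but
    neither detaches nor opens a new episode on re-press."""
    torques = [8.0] * 300 + [4.3] * 40 + [8.0] * 200  # dip ~0.7 deg < 2 deg
    th, notes, plant = drive_plant(torques)
    kinds = [k for _, k in notes]
    assert "detach" not in kinds
    assert kinds.count("contact_onset") == 1
    assert kinds.count("press_off") == 1 and kinds.count("press_on") == 2
    assert th.min() > 75.0 - 2.0 or th[:300].min() < 75.0  # never past reserve


def test_contact_events_recovered_from_sampled_trajectory():
    t = np.arange(0, 600, 0.5)
    theta = 70 + 8 * np.clip(np.sin(2 * np.pi * t / 300), 0, None)
    theta = np.minimum(theta, 75.0)
    eps = contact_events(theta, t, 75.0, eps_contact=2.0)
    assert len(eps) == 2  # one episode per protraction half-wave
    for (on1, off1), (on2, off2) in zip(eps[:-1], eps[1:]):
        assert on1 < off1 <= on2 < off2  # ordered, non-overlapping
    # no crossing at all -> empty
    assert contact_events(70 + 0 * t, t, 75.0) == []
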