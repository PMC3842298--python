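"""Musculoskeletal plant: calcium-gated muscle contraction, rigid-whisker
angular dynamics, and obstacle contact generation.

Muscle model
------------
Each muscle keeps a cytoplasmic calcium level ``Ca`` that jumps by a fixed
increment per motoneuron spike (capped at ``ca_max``, emulating sarcoplasmic
saturation) and decays exponentially with ``tau_ca_ms`` between spikes.  The
muscle is in its Contract regime while ``Ca >= ca0``.  The contractile force
tracks a saturating target ``a_max * (1 - exp(-(Ca - ca0)/ca_sat))`` through a
first-order activation filter with separate build-up (``tau_act_ms``) and
relaxation (``tau_deact_ms``) time constants; this separates the fast calcium
gate (which decides *whether* the muscle is on) from the slower cross-bridge
dynamics (which shape *how* force develops), and is what gives the whisk its
ramped protraction envelope.

Whisker model
-------------
Whiskers are rigid levers in a single plane:

    I dw/dt = sum_i s_i A_i - b w - k (theta - theta_rest)

integrated with fixed-step semi-implicit Euler.  An obstacle at azimuth
``theta_obs`` on one whisker clamps that whisker when protraction carries it
into the obstacle with net protractive torque; while clamped the whisker is
*pressing*.  When net torque turns retractive the whisker unclamps; contact
(the bending reserve of a real, non-rigid whisker) is considered maintained
until the angle falls below ``theta_obs - eps_contact``, at which point a
detach is generated and the contact episode closes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .engine import US_PER_MS


@dataclass
class MuscleParams:
    dca_volley: float      # Ca bump of one full synchronized volley
    tau_ca_ms: float
    ca0: float             # contraction threshold on Ca
    ca_sat: float          # force saturation scale above ca0
    ca_max: float          # sarcoplasmic ceiling
    a_max: float           # peak force (torque units)
    tau_act_ms: float      # force build-up time constant
    tau_deact_ms: float    # force relaxation time constant
    trigger_frac: float    # volley amplitude (fraction of dca_volley) that
                           # refreshes the tetanus hold
    hold_ms: float         # tetanus hold refreshed by each adequate volley

    @classmethod
    def from_dict(cls, d: dict) -> "MuscleParams":
        return cls(**{k: d[k] for k in (
            "dca_volley", "tau_ca_ms", "ca0", "ca_sat", "ca_max",
            "a_max", "tau_act_ms", "tau_deact_ms", "trigger_frac", "hold_ms")})


class MuscleState:
    """Dynamic state of one muscle: calcium, tetanus hold, activation force.

    Contraction requires *both* enough accumulated calcium (``Ca >= ca0``)
    and a live tetanus hold: each sufficiently synchronous motoneuron volley
    (total increment >= ``trigger_frac * dca_volley`` within one event
    timestamp) refreshes the hold for ``hold_ms``.  A muscle whose drive
    drops to a sub-threshold volley amplitude — e.g. when one of the two
    motoneuron pools sharing a sling is silenced — therefore relaxes within
    one hold window, while its calcium (and hence the force it redevelops if
    drive resumes) decays on the slower ``tau_ca_ms`` scale.
    """

    __slots__ = ("p", "ca", "ca_t_us", "force", "force_t_us",
                 "hold_until_us", "_volley_t_us", "_volley_sum")

    def __init__(self, p: MuscleParams):
        self.p = p
        self.ca = 0.0
        self.ca_t_us = 0
        self.force = 0.0
        self.force_t_us = 0
        self.hold_until_us = -1
        self._volley_t_us = -1
        self._volley_sum = 0.0

    # -- calcium ------------------------------------------------------
    def ca_at(self, t_us: int) -> float:
        dt_ms = (t_us - self.ca_t_us) / US_PER_MS
        if dt_ms <= 0:
            return self.ca
        return self.ca * math.exp(-dt_ms / self.p.tau_ca_ms)

    def stimulate(self, t_us: int, dca: float) -> float:
        """Register one spike worth ``dca`` of calcium; returns new Ca.

        Spikes sharing a timestamp aggregate into one volley for the
        tetanus-hold trigger.
        """
        self.ca = min(self.ca_at(t_us) + dca, self.p.ca_max)
        self.ca_t_us = t_us
        if t_us == self._volley_t_us:
            self._volley_sum += dca
        else:
            self._volley_t_us = t_us
            self._volley_sum = dca
        if self._volley_sum >= self.p.trigger_frac * self.p.dca_volley:
            self.hold_until_us = t_us + int(self.p.hold_ms * US_PER_MS)
        return self.ca

    def contracting_at(self, t_us: int) -> bool:
        return t_us <= self.hold_until_us and self.ca_at(t_us) >= self.p.ca0

    @property
    def contracting_now(self) -> bool:
        return self.contracting_at(self.ca_t_us)  # valid right after stimulate()

    def ms_to_relax(self) -> float:
        """Time until the Contract regime ends absent further volleys."""
        t = self.ca_t_us
        if not self.contracting_at(t):
            return 0.0
        hold_ms = (self.hold_until_us - t) / US_PER_MS
        ca_ms = self.p.tau_ca_ms * math.log(self.ca / self.p.ca0) if self.ca >= self.p.ca0 else 0.0
        return min(hold_ms, ca_ms)

    # -- force --------------------------------------------------------
    def force_target(self, t_us: int) -> float:
        if t_us > self.hold_until_us:
            return 0.0
        ca = self.ca_at(t_us)
        if ca < self.p.ca0:
            return 0.0
        return self.p.a_max * (1.0 - math.exp(-(ca - self.p.ca0) / self.p.ca_sat))

    def advance_force(self, t_us: int) -> float:
        """Relax the activation force toward its current target up to ``t_us``."""
        dt_ms = (t_us - self.force_t_us) / US_PER_MS
        if dt_ms > 0:
            target = self.force_target(t_us)
            tau = self.p.tau_act_ms if target > self.force else self.p.tau_deact_ms
            self.force = target + (self.force - target) * math.exp(-dt_ms / tau)
            self.force_t_us = t_us
        return self.force


def muscle_force(state: MuscleState, t_us: int) -> float:
    """Torque magnitude contributed by a muscle at ``t_us`` (Rest -> 0)."""
    return state.advance_force(t_us)


@dataclass
class Obstacle:
    """A static obstacle in one whisker's sweeping range.

    ``r`` is the radial fraction of whisker length at which contact occurs
    (0 < r <= 1); it sets the pressure-afferent response latency downstream.
    """

    whisker: str
    theta_obs_deg: float
    r: float
    present: bool = True

    def __post_init__(self):
        if not (0.0 < self.r <= 1.0):
            raise ValueError(f"radial fraction r={self.r} outside (0, 1]")


@dataclass
class ContactEpisode:
    onset_us: int
    offset_us: int | None = None


def whisker_step(theta: float, omega: float, torque: float, dt_ms: float,
                 inertia: float, damping: float, stiffness: float,
                 theta_rest: float) -> tuple[float, float]:
    """One semi-implicit Euler step of the rigid-whisker rotational dynamics."""
    domega = (torque - damping * omega - stiffness * (theta - theta_rest)) / inertia
    omega = omega + dt_ms * domega
    theta = theta + dt_ms * omega
    return theta, omega


class WhiskerArrayPlant:
    """Fixed-step integrator for the whole whisker array with one obstacle.

    Holds per-whisker angle/velocity and the contact bookkeeping for the
    obstacle whisker.  ``step`` returns the list of contact-state notifications
    generated during the step, for the sensory transducer to translate into
    afferent volleys.
    """

    def __init__(self, whisker_ids: list[str], plant_params: dict,
                 obstacle: Obstacle | None = None):
        self.ids = list(whisker_ids)
        self.index = {w: i for i, w in enumerate(self.ids)}
        n = len(self.ids)
        self.theta_rest = float(plant_params["theta_rest_deg"])
        self.inertia = float(plant_params["inertia"])
        self.damping = float(plant_params["damping"])
        self.stiffness = float(plant_params["stiffness"])
        self.dt_ms = float(plant_params["dt_ms"])
        self.eps_contact = float(plant_params["eps_contact_deg"])
        self.rest_theta_tol = float(plant_params["rest_theta_tol_deg"])
        self.rest_omega_tol = float(plant_params["rest_omega_tol"])
        self.theta = np.full(n, self.theta_rest, dtype=float)
        self.omega = np.zeros(n, dtype=float)
        self.obstacle = obstacle if (obstacle is not None and obstacle.present) else None
        self.obs_i = self.index[self.obstacle.whisker] if self.obstacle else -1
        self.pressing = False
        self.in_contact = False
        self.episodes: list[ContactEpisode] = []

    def is_moving(self) -> np.ndarray:
        return (np.abs(self.omega) > self.rest_omega_tol) | \
               (np.abs(self.theta - self.theta_rest) > self.rest_theta_tol)

    def step(self, t_us: int, torque: np.ndarray) -> list[str]:
        """Advance all whiskers by one dt.  Returns contact notifications
        among {"contact_onset", "press_on", "press_off", "detach"} for the
        obstacle whisker."""
        if not np.all(np.isfinite(torque)):
            bad = [self.ids[i] for i in np.flatnonzero(~np.isfinite(torque))]
            raise FloatingPointError(f"non-finite torque on whiskers {bad}")
        events: list[str] = []
        dt = self.dt_ms
        domega = (torque - self.damping * self.omega
                  - self.stiffness * (self.theta - self.theta_rest)) / self.inertia
        new_omega = self.omega + dt * domega
        new_theta = self.theta + dt * new_omega

        if self.obstacle is not None:
            i = self.obs_i
            tobs = self.obstacle.theta_obs_deg
            if self.pressing:
                # clamped: stays clamped while net torque is protractive
                net = torque[i] - self.stiffness * (tobs - self.theta_rest)
                if net >= 0.0:
                    new_theta[i] = tobs
                    new_omega[i] = 0.0
                else:
                    self.pressing = False
                    events.append("press_off")
                    # released this step: integrate from (tobs, 0)
                    w = dt * net / self.inertia
                    new_omega[i] = w
                    new_theta[i] = tobs + dt * w
            else:
                if new_theta[i] >= tobs and new_omega[i] > 0.0:
                    new_theta[i] = tobs
                    new_omega[i] = 0.0
                    self.pressing = True
                    if not self.in_contact:
                        self.in_contact = True
                        self.episodes.append(ContactEpisode(onset_us=t_us))
                        events.append("contact_onset")
                    events.append("press_on")
                elif self.in_contact and new_theta[i] < tobs - self.eps_contact:
                    self.in_contact = False
                    self.episodes[-1].offset_us = t_us
                    events.append("detach")

        self.theta = new_theta
        self.omega = new_omega
        return events

    def close_episodes(self, t_us: int) -> None:
        if self.episodes and self.episodes[-1].offset_us is None:
            self.episodes[-1].offset_us = t_us


def contact_events(theta: np.ndarray, t_ms: np.ndarray, theta_obs: float,
                   eps_contact: float = 2.0, tol: float = 1e-6) -> list[tuple[float, float]]:
    """Recover (onset, offset) contact episodes from a sampled trajectory.

    Onset: the whisker reaches the obstacle angle (clamp begins).  Offset: the
    angle falls below ``theta_obs - eps_contact``.  Episodes are
    non-overlapping and ordered; an episode still open at the end of the trace
    closes at the final sample.
    """
    episodes: list[tuple[float, float]] = []
    in_contact = False
    onset = 0.0
    for th, t in zip(theta, t_ms):
        if not in_contact:
            if th >= theta_obs - tol:
                in_contact = True
                onset = t
        else:
            if th < theta_obs - eps_contact:
                episodes.append((onset, t))
                in_contact = False
    if in_contact:
        episodes.append((onset, float(t_ms[-1])))
    return episodes
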