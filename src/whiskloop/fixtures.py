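"""Synthetic whisk-trace generator: sinusoid-like whisking with injected
pumps of known delay and amplitude, emulating tracked-whisker output.

The fixture stands in for video-tracked whisker angles when testing the
analysis layer without the simulator: each trace carries ground-truth
annotations (cycle boundaries, synthetic contact episodes, injected pump
parameters) against which segmentation and pump detection are scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PumpSpec:
    whisker: str
    delay_ms: float          # after the cycle's synthetic contact onset
    amplitude_deg: float
    width_ms: float = 20.0


@dataclass
class FixtureSpec:
    whiskers: tuple[str, ...] = ("C1", "C2", "C3", "C4")
    period_ms: float = 125.0          # 8 Hz default
    amplitude_deg: float = 10.0       # peak-to-trough
    set_point_deg: float = 75.0
    n_cycles: int = 8
    dt_ms: float = 0.5
    noise_sd_deg: float = 0.0
    seed: int = 0
    waveform: str = "sine"            # "sine" | "ramp"
    protraction_frac: float = 0.5     # for "ramp": protraction share of the cycle
    contact_phase: float = 0.25       # contact onset, as a fraction of the cycle
    contact_cycles: tuple[int, ...] = ()   # cycles carrying a contact episode
    pumps: list[PumpSpec] = field(default_factory=list)


@dataclass
class Fixture:
    spec: FixtureSpec
    t_ms: np.ndarray
    theta: dict[str, np.ndarray]
    episodes: list[tuple[float, float]]            # synthetic contact episodes
    truth_pumps: list[dict]                        # per injected pump, ground truth


def _base_wave(spec: FixtureSpec, t: np.ndarray) -> np.ndarray:
    phase = (t % spec.period_ms) / spec.period_ms
    half = spec.amplitude_deg / 2.0
    if spec.waveform == "sine":
        return spec.set_point_deg + half * np.sin(2 * np.pi * phase - np.pi / 2)
    if spec.waveform == "ramp":
        pf = spec.protraction_frac
        up = phase < pf
        w = np.empty_like(phase)
        w[up] = -half + spec.amplitude_deg * (phase[up] / pf)
        w[~up] = half - spec.amplitude_deg * ((phase[~up] - pf) / (1 - pf))
        return spec.set_point_deg + w
    raise ValueError(f"unknown waveform {spec.waveform!r}")


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Deterministic multi-whisker traces with ground-truth pump annotations.

    Raises ``ValueError`` if an injected pump would fall outside the
    protraction phase of its cycle.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.n_cycles * spec.period_ms / spec.dt_ms)) + 1
    t = np.arange(n) * spec.dt_ms
    prot_end = spec.period_ms * (spec.protraction_frac if spec.waveform == "ramp" else 0.5)

    contact_cycles = spec.contact_cycles or (tuple(range(1, spec.n_cycles))
                                             if spec.pumps else ())
    episodes = []
    for c in contact_cycles:
        on = c * spec.period_ms + spec.contact_phase * spec.period_ms
        off = c * spec.period_ms + prot_end + 0.1 * spec.period_ms
        episodes.append((float(on), float(off)))

    theta = {w: _base_wave(spec, t) for w in spec.whiskers}
    truth = []
    for pump in spec.pumps:
        if pump.whisker not in theta:
            raise ValueError(f"pump on unknown whisker {pump.whisker!r}")
        t_in_cycle = spec.contact_phase * spec.period_ms + pump.delay_ms
        if not (0.0 < t_in_cycle and t_in_cycle + pump.width_ms <= prot_end):
            raise ValueError(
                f"pump at delay {pump.delay_ms} ms falls outside the protraction phase")
        for c in contact_cycles:
            t0 = c * spec.period_ms + t_in_cycle
            mask = (t >= t0) & (t <= t0 + pump.width_ms)
            base = theta[pump.whisker]
            # clamp the base to its value at pump onset for the pump's span
            # (the whisker is against the object), then carve the dip out of
            # that plateau — this keeps the injected delay and amplitude
            # exactly recoverable
            plateau = np.interp(t0, t, base)
            dip = np.sin(np.pi * (t[mask] - t0) / pump.width_ms) ** 2
            base[mask] = np.minimum(base[mask], plateau) - pump.amplitude_deg * dip
            truth.append({"whisker": pump.whisker, "cycle": c,
                          "onset_ms": float(t0),
                          "delay_ms": float(pump.delay_ms),
                          "amplitude_deg": float(pump.amplitude_deg)})
    if spec.noise_sd_deg > 0:
        for w in spec.whiskers:
            theta[w] = theta[w] + rng.normal(0.0, spec.noise_sd_deg, size=n)
    return Fixture(spec, t, theta, episodes, truth)
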