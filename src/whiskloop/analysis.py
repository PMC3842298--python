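"""Kinematic analysis: whisk-cycle segmentation, touch-induced-pump (TIP)
detection and characterization, spatial-spread summaries, and the exact
binomial occurrence test.

A whisk cycle runs trough-to-trough; protraction is the trough-to-peak
sub-phase, retraction peak-to-trough, the set-point the cycle-mean angle.
A TIP is a brief retraction of at least ``delta_tip`` degrees that begins
after contact onset, inside the protraction phase, and is followed by a
re-protraction — distinguishing it from the cycle's terminal retraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats


@dataclass
class WhiskCycle:
    start_ms: float
    duration_ms: float
    protraction_ms: float
    retraction_ms: float
    amplitude_deg: float
    set_point_deg: float
    peak_ms: float
    peak_deg: float
    trough_deg: float


@dataclass
class TipEvent:
    whisker: str
    bout_index: int
    onset_ms: float
    delay_ms: float          # onset - contact onset
    amplitude_deg: float     # peak-to-trough of the pump retraction
    trough_ms: float
    contact_maintained: bool


# ---------------------------------------------------------------------------
# cycle segmentation
# ---------------------------------------------------------------------------


def lowpass(theta: np.ndarray, t_ms: np.ndarray, cutoff_hz: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass (cutoff as in tracked-whisker practice)."""
    if len(theta) < 30:
        return theta
    fs = 1000.0 / float(t_ms[1] - t_ms[0])
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        return theta
    b, a = signal.butter(4, cutoff_hz / nyq)
    return signal.filtfilt(b, a, theta)


def segment_cycles(t_ms: np.ndarray, theta: np.ndarray,
                   cutoff_hz: float = 40.0,
                   min_prominence_deg: float = 2.0) -> list[WhiskCycle]:
    """Delimit whisk cycles at retraction minima of the low-passed trace.

    Returns an empty list for a flat (non-oscillating) trace.
    """
    theta = np.asarray(theta, dtype=float)
    if len(theta) < 3 or float(np.ptp(theta)) < min_prominence_deg:
        return []
    th = lowpass(theta, t_ms, cutoff_hz)
    troughs, _ = signal.find_peaks(-th, prominence=min_prominence_deg)
    cycles: list[WhiskCycle] = []
    for a, b in zip(troughs[:-1], troughs[1:]):
        seg = th[a:b + 1]
        pk = a + int(np.argmax(seg))
        if pk == a or pk == b:
            continue
        cycles.append(WhiskCycle(
            start_ms=float(t_ms[a]),
            duration_ms=float(t_ms[b] - t_ms[a]),
            protraction_ms=float(t_ms[pk] - t_ms[a]),
            retraction_ms=float(t_ms[b] - t_ms[pk]),
            amplitude_deg=float(th[pk] - min(th[a], th[b])),
            set_point_deg=float(np.mean(seg)),
            peak_ms=float(t_ms[pk]),
            peak_deg=float(th[pk]),
            trough_deg=float(th[a]),
        ))
    return cycles


# ---------------------------------------------------------------------------
# TIP detection
# ---------------------------------------------------------------------------


def group_episodes(episodes: list[tuple[float, float]],
                   gap_ms: float = 50.0) -> list[list[tuple[float, float]]]:
    """Group contact episodes into bouts: pump-induced detach/re-contact pairs
    separated by less than ``gap_ms`` belong to the same whisk cycle's bout."""
    bouts: list[list[tuple[float, float]]] = []
    for ep in sorted(episodes):
        if bouts and ep[0] - bouts[-1][-1][1] < gap_ms:
            bouts[-1].append(ep)
        else:
            bouts.append([ep])
    return bouts


def detect_tips(t_ms: np.ndarray, theta: np.ndarray,
                episodes: list[tuple[float, float]],
                whisker: str = "",
                delta_tip: float = 0.3,
                w_max_ms: float = 80.0,
                rebound_frac: float = 0.05,
                rebound_window_ms: float = 45.0,
                max_descent_ms: float = 55.0,
                min_rate_deg_ms: float = 0.05,
                group_gap_ms: float = 50.0) -> list[TipEvent]:
    """Detect pumps in one whisker's trace relative to reference contact episodes.

    A TIP is a local maximum after contact onset followed, within
    ``w_max_ms``, by a retraction of at least ``delta_tip`` degrees and a
    subsequent re-protraction of at least ``rebound_frac`` of the retraction
    within ``rebound_window_ms`` of the trough.  The terminal retraction of
    the whisk cycle fails the re-protraction requirement and is not counted.

    A pump whose re-protraction drive is too weak to reverse the motion
    (e.g. a weakly-driven whisker pumping right before the retraction phase)
    is still confirmed by its *descent arrest*: the fall stalls for several
    milliseconds and then resumes as the terminal retraction takes over —
    a pattern a plain terminal retraction, which decelerates monotonically
    into the trough, never shows.
    """
    if delta_tip <= 0:
        raise ValueError("delta_tip must be positive")
    theta = np.asarray(theta, dtype=float)
    t_ms = np.asarray(t_ms, dtype=float)
    dt = float(t_ms[1] - t_ms[0]) if len(t_ms) > 1 else 1.0
    tips: list[TipEvent] = []
    bouts = group_episodes(episodes, group_gap_ms)
    for bi, bout in enumerate(bouts):
        contact_on = bout[0][0]
        bout_end = bout[-1][1]
        i0 = int(np.searchsorted(t_ms, contact_on))
        i1 = min(int(np.searchsorted(t_ms, contact_on + w_max_ms)), len(theta) - 1)
        j = i0
        while j < i1:
            # track the running maximum and its location
            run_max = theta[j]
            arg_max = j
            k = j + 1
            while k <= i1 and theta[k] >= run_max - delta_tip:
                # ">= run_max - eps" keeps the onset at the *end* of a clamped
                # plateau, where the descent actually begins
                if theta[k] >= run_max - 1e-9:
                    run_max = max(run_max, theta[k])
                    arg_max = k
                k += 1
            if k > i1:
                break
            # the onset must be a genuine local maximum (or the end of a
            # clamped plateau): a window that opens mid-descent — e.g. contact
            # scored during a retraction — offers no pump onset
            if arg_max > 0 and theta[arg_max - 1] > theta[arg_max] + 1e-6:
                j = k
                continue
            # descent of >= delta_tip began at arg_max; find the trough
            trough = theta[k]
            arg_trough = k
            m = k + 1
            reb_needed = None
            confirmed = False
            while m < len(theta):
                if theta[m] < trough:
                    trough = theta[m]
                    arg_trough = m
                reb_needed = max(rebound_frac * (run_max - trough), delta_tip / 2)
                if theta[m] - trough >= reb_needed:
                    confirmed = True
                    break
                if t_ms[m] - t_ms[arg_trough] > rebound_window_ms:
                    break
                m += 1
            # a pump retracts on the tens-of-ms scale; the cycle's terminal
            # retraction descends for the whole retraction phase and is
            # rejected by the descent-duration cap
            if t_ms[arg_trough] - t_ms[arg_max] > max_descent_ms:
                confirmed = False
            # pumps are *rapid* retractions; a slow sag of the protraction
            # envelope does not qualify
            descent_ms = max(t_ms[arg_trough] - t_ms[arg_max], dt)
            if (run_max - trough) / descent_ms < min_rate_deg_ms:
                confirmed = False
            if not confirmed:
                # arrest-then-renewal: the descent stalls (< arrest_rate for
                # >= arrest_ms) at least delta_tip below the onset maximum and
                # then re-accelerates downward
                arrest_rate, arrest_ms, renewal_deg = 0.035, 4.0, 0.5
                win = int(round(arrest_ms / dt))
                end = min(arg_max + int(round(max_descent_ms / dt)), len(theta) - 1 - win)
                for a in range(k, end):
                    seg = theta[a:a + win + 1]
                    if (run_max - seg[0] >= delta_tip
                            and np.all(np.abs(np.diff(seg)) < arrest_rate * dt)):
                        after = theta[a + win:min(a + win + int(20 / dt), len(theta))]
                        if len(after) and seg[-1] - after.min() >= renewal_deg:
                            trough = float(seg.min())
                            arg_trough = a + int(np.argmin(seg))
                            descent_ms = max(t_ms[arg_trough] - t_ms[arg_max], dt)
                            if (run_max - trough) / descent_ms >= min_rate_deg_ms:
                                confirmed = True
                                m = a + win
                                break
            if confirmed and run_max - trough >= delta_tip:
                tips.append(TipEvent(
                    whisker=whisker,
                    bout_index=bi,
                    onset_ms=float(t_ms[arg_max]),
                    delay_ms=float(t_ms[arg_max] - contact_on),
                    amplitude_deg=float(run_max - trough),
                    trough_ms=float(t_ms[arg_trough]),
                    contact_maintained=bool(t_ms[arg_trough] <= bout_end + dt),
                ))
                j = m
            else:
                j = arg_trough
    return tips


def first_tips(tips: list[TipEvent]) -> list[TipEvent]:
    """First TIP of each contact bout (the statistic reported per whisk cycle)."""
    seen: dict[int, TipEvent] = {}
    for tip in tips:
        if tip.bout_index not in seen:
            seen[tip.bout_index] = tip
    return [seen[k] for k in sorted(seen)]


def slowdown_flag(t_ms: np.ndarray, theta: np.ndarray,
                  contact_on_ms: float, window_ms: float = 60.0,
                  drop_frac: float = 0.5) -> bool:
    """Whether protraction velocity dropped by ``drop_frac`` after contact
    onset without a detectable retraction (the 'slowed down' response class
    used in tracked-whisker scoring)."""
    dt = float(t_ms[1] - t_ms[0])
    i = int(np.searchsorted(t_ms, contact_on_ms))
    pre = slice(max(0, i - int(20 / dt)), i)
    post = slice(i, min(len(theta), i + int(window_ms / dt)))
    v_pre = np.gradient(theta[pre], dt).mean() if i > 2 else 0.0
    v_post = np.gradient(theta[post], dt).mean() if len(theta[post]) > 2 else 0.0
    return bool(v_pre > 0 and v_post < (1 - drop_frac) * v_pre)


def tip_spread(result, delta_tip: float = 0.3, t_min_ms: float = 200.0,
               **detect_kwargs) -> dict:
    """Pumping-whisker identity for a single-obstacle run.

    Uses the touching whisker's contact episodes as the reference for every
    whisker and classifies the pumping set as ``touching+neighbors``,
    ``all_ipsilateral``, ``none`` or ``other``.
    """
    touching = None
    ref_eps: list[tuple[float, float]] = []
    for w, eps in result.episodes.items():
        if eps:
            touching = w
            ref_eps = [e for e in eps if e[0] >= t_min_ms]
    pumping: list[str] = []
    per_whisker: dict[str, list[TipEvent]] = {}
    if ref_eps:
        t = result.t_ms
        for w in result.whiskers:
            tips = detect_tips(t, result.theta[w].to_numpy(), ref_eps, whisker=w,
                               delta_tip=delta_tip, **detect_kwargs)
            per_whisker[w] = tips
            if tips:
                pumping.append(w)
    pump_set = set(pumping)
    if not pump_set:
        label = "none"
    elif pump_set == set(result.whiskers):
        label = "all_ipsilateral"
    elif touching is not None:
        from .network import PadLayout
        expected = {touching} | set(PadLayout().neighbors(touching))
        label = "touching+neighbors" if pump_set == (expected & set(result.whiskers)) \
            else "other"
    else:
        label = "other"
    return {"touching": touching, "pumping": sorted(pump_set), "label": label,
            "tips": per_whisker}


# ---------------------------------------------------------------------------
# occurrence statistics
# ---------------------------------------------------------------------------


def binom_test(k: int, n: int, p0: float, tail: str = "two-sided") -> float:
    """Exact binomial tail probability for TIP-occurrence comparisons.

    ``tail`` is one of "less", "greater", "two-sided".
    """
    if not (0 <= k <= n) or n <= 0:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"require 0 < p0 < 1, got {p0}")
    if tail not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    return float(stats.binomtest(k, n, p0, alternative=tail).pvalue)


# ---------------------------------------------------------------------------
# free-air summary helpers
# ---------------------------------------------------------------------------


def freeair_metrics(result, whisker: str = "C4", t_min_ms: float = 200.0,
                    cutoff_hz: float = 40.0) -> dict:
    """Cycle statistics of a free-air run (transient start excluded)."""
    t = result.t_ms
    sel = t >= t_min_ms
    th = result.theta[whisker].to_numpy()[sel]
    cycles = segment_cycles(t[sel], th, cutoff_hz=cutoff_hz)
    peaks = {}
    for w in result.whiskers:
        cw = segment_cycles(t[sel], result.theta[w].to_numpy()[sel], cutoff_hz=cutoff_hz)
        if cw:
            peaks[w] = float(np.mean([c.peak_deg for c in cw]))
    return {
        "cycles": cycles,
        "mean_cycle_ms": float(np.mean([c.duration_ms for c in cycles])) if cycles else np.nan,
        "mean_protraction_ms": float(np.mean([c.protraction_ms for c in cycles])) if cycles else np.nan,
        "mean_retraction_ms": float(np.mean([c.retraction_ms for c in cycles])) if cycles else np.nan,
        "mean_amplitude_deg": float(np.mean([c.amplitude_deg for c in cycles])) if cycles else np.nan,
        "peak_per_whisker": peaks,
    }
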