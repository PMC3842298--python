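"""Static plot helper for whisker trajectories."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_trajectories(result, whiskers=None, ax=None, t_range_ms=None):
    """Angle-vs-time traces for selected whiskers of a simulation result.

    Contact episodes of the touching whisker (if any) are shaded.
    Returns the matplotlib axes.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    whiskers = whiskers or result.whiskers[:7]
    t = result.t_ms
    sel = slice(None)
    if t_range_ms is not None:
        sel = (t >= t_range_ms[0]) & (t <= t_range_ms[1])
    for w in whiskers:
        ax.plot(t[sel], result.theta[w].to_numpy()[sel], lw=0.8, label=w)
    for w, eps in result.episodes.items():
        for onset, offset in eps:
            ax.axvspan(onset, offset, color="0.85", zorder=0)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("whisker angle (deg)")
    ax.legend(fontsize=7, ncol=2)
    return ax
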