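"""Growth-curve and condition-level plots (matplotlib)."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .growth import CellTrack, CubicGrowthResults
from .report import ConditionSummary

__all__ = ["plot_growth_curves", "plot_growth_period_box"]


def plot_growth_curves(
    tracks: Sequence[CellTrack],
    fits: Optional[Sequence[CubicGrowthResults]] = None,
    ax=None,
):
    """Raw (dots), smoothed (line) and fitted (dashed) volume curves."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    fit_by_id = {f.cell_id: f for f in fits} if fits else {}
    for tr in tracks:
        (line,) = ax.plot(tr.times, tr.raw_volumes, ".", ms=3, alpha=0.5)
        color = line.get_color()
        if tr.smoothed is not None:
            ax.plot(tr.times, tr.smoothed, "-", color=color, lw=1.2,
                    label=f"cell {tr.cell_id}")
        f = fit_by_id.get(tr.cell_id)
        if f is not None:
            tt = np.linspace(tr.times[0], tr.times[-1], 200)
            ax.plot(tt, f.predict(tt), "--", color=color, lw=1.0)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("cell volume (µm³)")
    ax.legend(fontsize=8)
    return ax


def plot_growth_period_box(summaries: Sequence[ConditionSummary], ax=None):
    """Box plot of growth periods (days) per flow condition."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ordered = sorted(summaries, key=lambda s: s.flow_rate_ul_min)
    data = [np.asarray(s.growth_periods_min) / 1440.0 for s in ordered]
    labels = [f"{s.flow_rate_ul_min:g}" for s in ordered]
    keep = [i for i, d in enumerate(data) if d.size > 0]
    ax.boxplot([data[i] for i in keep], tick_labels=[labels[i] for i in keep])
    ax.set_xlabel("flow rate (µL min$^{-1}$)")
    ax.set_ylabel("growth period (d)")
    return ax
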