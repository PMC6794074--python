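"""Figure generation: double-plotted actograms, profiles, periodograms,
timecourses.  All plotting uses the non-interactive Agg backend so output is
reproducible in batch runs."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .dam_io import bin_series
from .profiles import ProfileSummary
from .rhythmicity import Periodogram
from .schedule import MINUTES_PER_DAY, LightSchedule

__all__ = ["make_actogram", "plot_profile", "plot_periodogram", "plot_timecourse"]

_SAVEFIG_KW = dict(dpi=100, metadata={"Software": None})


def make_actogram(
    counts: np.ndarray,
    schedule: LightSchedule,
    out_path=None,
    bin_width_min: int = 30,
    title: str = "",
):
    """Double-plotted actogram: row r shows days r and r+1 side by side.

    ``counts`` is an aligned per-minute series (index 0 = ZT0 of day 0).
    Light phases are shaded; the rendering is deterministic for fixed input.
    """
    x = np.asarray(counts, dtype=float)
    n_days = x.size // MINUTES_PER_DAY
    if n_days < 1:
        raise ValueError("need at least one full day of data")
    x = x[: n_days * MINUTES_PER_DAY]
    binned = np.nan_to_num(bin_series(x, bin_width_min))
    bins_per_day = MINUTES_PER_DAY // bin_width_min
    vmax = binned.max() if binned.max() > 0 else 1.0

    fig, ax = plt.subplots(figsize=(6, 0.35 * n_days + 1.2))
    hours48 = np.arange(2 * bins_per_day) * bin_width_min / 60.0
    for r in range(n_days):
        left = binned[r * bins_per_day:(r + 1) * bins_per_day]
        right = (
            binned[(r + 1) * bins_per_day:(r + 2) * bins_per_day]
            if r + 1 < n_days
            else np.zeros(bins_per_day)
        )
        row = np.concatenate([left, right]) / vmax * 0.9
        base = n_days - 1 - r
        # shade darkness for each of the two plotted days
        for half, day in ((0, r), (1, r + 1)):
            if day >= schedule.n_days:
                continue
            phase = schedule.phase_of_day(day)
            x0 = 24.0 * half
            if phase.regime == "LD":
                ax.add_patch(
                    plt.Rectangle(
                        (x0 + phase.light_hours, base), 24.0 - phase.light_hours, 1.0,
                        facecolor="0.82", edgecolor="none", zorder=0,
                    )
                )
            else:
                ax.add_patch(
                    plt.Rectangle(
                        (x0, base), 24.0, 1.0,
                        facecolor="0.82", edgecolor="none", zorder=0,
                    )
                )
        ax.bar(
            hours48, row, width=bin_width_min / 60.0, bottom=base,
            align="edge", color="black", zorder=2,
        )
    ax.set_xlim(0, 48)
    ax.set_ylim(0, n_days)
    ax.set_xticks([0, 12, 24, 36, 48])
    ax.set_yticks(np.arange(n_days) + 0.5)
    ax.set_yticklabels([str(n_days - r) for r in range(n_days)])
    ax.set_xlabel("time (h)")
    ax.set_ylabel("day")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, **_SAVEFIG_KW)
        plt.close(fig)
        return out_path
    return fig


def plot_profile(
    summaries: Sequence[ProfileSummary], schedule: LightSchedule, out_path=None
):
    """Mean ± SEM daily profile(s) with the dark phase shaded."""
    fig, ax = plt.subplots(figsize=(6, 3))
    ld = [p for p in schedule.phases if p.regime == "LD"]
    light_hours = ld[0].light_hours if ld else 12.0
    ax.axvspan(light_hours, 24.0, color="0.85", zorder=0)
    for s in summaries:
        zt = (np.arange(s.mean.size) + 0.5) * s.bin_width_min / 60.0
        ax.errorbar(zt, s.mean, yerr=s.sem, label=f"{s.genotype} (n={s.n_flies})")
    ax.set_xlim(0, 24)
    ax.set_xticks(range(0, 25, 6))
    ax.set_xlabel("ZT (h)")
    ax.set_ylabel("activity / 30 min")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, **_SAVEFIG_KW)
        plt.close(fig)
        return out_path
    return fig


def plot_periodogram(pg: Periodogram, out_path=None, title: str = ""):
    """Q statistic vs candidate period with the significance line."""
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(pg.period_h, pg.Q, color="black", label="Q")
    ax.plot(
        pg.period_h, pg.threshold, color="red", linestyle="--",
        label=f"α={pg.alpha} ({pg.correction})",
    )
    if pg.rhythmic:
        ax.axvline(pg.peak_period_h, color="blue", linewidth=0.8)
    ax.set_xlabel("period (h)")
    ax.set_ylabel("Q")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, **_SAVEFIG_KW)
        plt.close(fig)
        return out_path
    return fig


def plot_timecourse(summaries, out_path=None, ylabel="intensity (a.u.)"):
    """Per-timepoint mean ± SEM curves, one per (genotype) summary frame.

    ``summaries`` maps label -> DataFrame from ``timecourse_summary``.
    """
    fig, ax = plt.subplots(figsize=(5, 3))
    for label, df in summaries.items():
        ax.errorbar(
            df["timepoint_h"], df["mean"], yerr=df["sem"], marker="o", label=label
        )
    ax.set_xlabel("time (h)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, **_SAVEFIG_KW)
        plt.close(fig)
        return out_path
    return fig
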