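"""Average daily activity profiles and morning/evening anticipation indices.

For each fly the minute-by-minute activity of the selected LD days (by
default the last three) is averaged across days, then summed into 48
half-hour ZT bins.  Anticipation is scored per fly on the averaged day as

    MA = Σ activity ZT[21, 24) / Σ activity ZT[18, 24)
    EA = Σ activity ZT[9, 12)  / Σ activity ZT[6, 12)

so 0.5 means no anticipation (uniform activity across the window) and values
above 0.5 indicate a rising ramp toward the light transition.  All ZT
windows are half-open, which keeps the startle minute at the transition
itself (masking) out of the numerator windows.  Group-level inference is a
one-sample t-test of the per-fly indices against 0.5; genotypes are compared
with a pooled-variance t-test (two groups) or one-way ANOVA plus Tukey HSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .schedule import MINUTES_PER_DAY, LightSchedule

__all__ = [
    "ActivityProfile",
    "ProfileSummary",
    "AnticipationIndices",
    "TestVsHalf",
    "GroupComparison",
    "mean_daily_profile",
    "anticipation_indices",
    "test_vs_half",
    "compare_groups",
    "profile_summary",
]

PROFILE_BIN_MIN = 30
N_BINS = MINUTES_PER_DAY // PROFILE_BIN_MIN  # 48

# Half-open ZT windows (hours) of the anticipation indices.
MA_NUM_WINDOW = (21.0, 24.0)
MA_DEN_WINDOW = (18.0, 24.0)
EA_NUM_WINDOW = (9.0, 12.0)
EA_DEN_WINDOW = (6.0, 12.0)


@dataclass
class ActivityProfile:
    """One fly's averaged daily profile.

    ``values`` holds 48 half-hour bins (bin b covers ZT [b/2, b/2+0.5)), each
    the sum of the 30 across-day-averaged minutes it contains.
    ``minute_means`` keeps the underlying 1440 averaged minutes so indices
    can be computed at minute resolution; ``minute_n`` tracks how many days
    contributed to each minute.
    """

    fly_id: str
    values: np.ndarray
    n_days_used: int
    minute_means: np.ndarray
    minute_n: np.ndarray
    bin_width_min: int = PROFILE_BIN_MIN


@dataclass
class ProfileSummary:
    """Across-fly per-bin mean ± SEM for one genotype."""

    genotype: str
    mean: np.ndarray
    sem: np.ndarray
    n_flies: int
    bin_width_min: int = PROFILE_BIN_MIN


class AnticipationIndices(NamedTuple):
    ma: float
    ea: float


class TestVsHalf(NamedTuple):
    t: float
    df: int
    p: float
    mean: float
    n: int
    degenerate: bool


@dataclass
class GroupComparison:
    """Genotype comparison: pooled t-test (2 groups) or ANOVA + Tukey (>=3)."""

    method: str  # "t-test" or "anova"
    statistic: float  # t or F
    df: tuple[int, ...]
    p: float
    pairwise: pd.DataFrame | None = None  # Tukey table when method == "anova"


def mean_daily_profile(
    counts: np.ndarray,
    schedule: LightSchedule,
    days: Sequence[int],
    fly_id: str = "",
) -> ActivityProfile:
    """Average the minute-by-minute activity of the selected days, then bin.

    ``counts`` is the fly's per-minute series aligned so index 0 is ZT0 of
    experiment day 0 (see ``MonitorData.aligned_counts``).  Missing minutes
    are excluded from the average with the per-minute day count tracked; a
    bin is missing only if one of its minutes has no data on any selected
    day.  Selected days must fall in an LD phase.
    """
    days = sorted(set(int(d) for d in days))
    if not days:
        raise ValueError("no days selected")
    x = np.asarray(counts, dtype=float)
    for d in days:
        if (d + 1) * MINUTES_PER_DAY > x.size:
            raise ValueError(f"day {d} not recorded")
        if schedule.regime_of_day(d) != "LD":
            raise ValueError(f"day {d} is not in an LD phase; profiles are ZT-based")
    stack = np.vstack([x[d * MINUTES_PER_DAY:(d + 1) * MINUTES_PER_DAY] for d in days])
    n_per_minute = np.sum(np.isfinite(stack), axis=0)
    if not n_per_minute.any():
        raise ValueError("no complete data on the selected days")
    with np.errstate(invalid="ignore"):
        minute_means = np.where(
            n_per_minute > 0, np.nansum(stack, axis=0) / np.maximum(n_per_minute, 1), np.nan
        )
    binned = minute_means.reshape(N_BINS, PROFILE_BIN_MIN)
    values = binned.sum(axis=1)  # NaN propagates: bin missing if any minute missing
    return ActivityProfile(
        fly_id=fly_id,
        values=values,
        n_days_used=len(days),
        minute_means=minute_means,
        minute_n=n_per_minute,
    )


def _window_sum(minute_means: np.ndarray, window: tuple[float, float]) -> float:
    lo, hi = (int(round(w * 60)) for w in window)
    return float(np.nansum(minute_means[lo:hi]))


def anticipation_indices(
    profile_or_counts: ActivityProfile | np.ndarray,
    schedule: LightSchedule | None = None,
    days: Sequence[int] | None = None,
) -> AnticipationIndices:
    """Morning and evening anticipation indices on the averaged day.

    Accepts either a precomputed :class:`ActivityProfile` or raw aligned
    per-minute counts plus (schedule, days).  An index is NaN when its
    denominator window sums to zero.
    """
    if isinstance(profile_or_counts, ActivityProfile):
        m = profile_or_counts.minute_means
    else:
        if schedule is None or days is None:
            raise ValueError("raw counts require schedule and days")
        m = mean_daily_profile(profile_or_counts, schedule, days).minute_means

    def index(num_w, den_w):
        den = _window_sum(m, den_w)
        if den <= 0:
            return float("nan")
        return _window_sum(m, num_w) / den

    return AnticipationIndices(
        ma=index(MA_NUM_WINDOW, MA_DEN_WINDOW),
        ea=index(EA_NUM_WINDOW, EA_DEN_WINDOW),
    )


def test_vs_half(values: Sequence[float]) -> TestVsHalf:
    """Two-sided one-sample t-test of anticipation indices against 0.5.

    NaN (undefined) indices are dropped.  A zero-variance sample is handled
    explicitly: t = 0, p = 1 when the mean is exactly 0.5, otherwise p = 0
    flagged degenerate.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("need >= 2 defined index values")
    mean = float(x.mean())
    if np.isclose(x.std(ddof=1), 0.0):
        if np.isclose(mean, 0.5):
            return TestVsHalf(0.0, n - 1, 1.0, mean, n, False)
        t = np.inf if mean > 0.5 else -np.inf
        return TestVsHalf(t, n - 1, 0.0, mean, n, True)
    res = stats.ttest_1samp(x, popmean=0.5)
    return TestVsHalf(float(res.statistic), n - 1, float(res.pvalue), mean, n, False)


# the name looks like a pytest test when imported into test modules; it is API
test_vs_half.__test__ = False  # type: ignore[attr-defined]
TestVsHalf.__test__ = False  # type: ignore[attr-defined]


def compare_groups(
    groups: Mapping[str, Sequence[float]], method: str = "auto"
) -> GroupComparison:
    """Compare index values across genotypes.

    Two groups: two-sided pooled-variance (Student) t-test.  Three or more:
    one-way ANOVA with post-hoc Tukey HSD pairwise p-values.
    """
    clean: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        x = np.asarray(vals, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 defined values")
        clean[name] = x
    k = len(clean)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if method == "auto":
        method = "t-test" if k == 2 else "anova"
    if method == "t-test":
        if k != 2:
            raise ValueError("t-test requires exactly 2 groups")
        a, b = clean.values()
        res = stats.ttest_ind(a, b, equal_var=True)
        return GroupComparison(
            "t-test", float(res.statistic), (a.size + b.size - 2,), float(res.pvalue)
        )
    return _anova_tukey(clean)


def _anova_tukey(clean: dict[str, np.ndarray]) -> GroupComparison:
    names = list(clean)
    allx = np.concatenate([clean[g] for g in names])
    n_total, k = allx.size, len(names)
    grand = allx.mean()
    ss_between = sum(x.size * (x.mean() - grand) ** 2 for x in clean.values())
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in clean.values())
    df_b, df_w = k - 1, n_total - k
    if np.isclose(ss_between, 0.0) and np.isclose(ss_within, 0.0):
        f_stat, p = 0.0, 1.0
    elif np.isclose(ss_within, 0.0):
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f_stat, df_b, df_w))
    pairwise = _tukey_table(clean, ss_within, df_w)
    return GroupComparison("anova", float(f_stat), (df_b, df_w), p, pairwise)


def _tukey_table(
    clean: dict[str, np.ndarray], ss_within: float, df_w: int
) -> pd.DataFrame:
    names = list(clean)
    k = len(names)
    degenerate = df_w <= 0 or np.isclose(ss_within, 0.0)
    hsd = None if degenerate else stats.tukey_hsd(*[clean[g] for g in names])
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = clean[names[i]], clean[names[j]]
            diff = b.mean() - a.mean()
            if hsd is not None:
                p = float(hsd.pvalue[i, j])
            else:
                p = 1.0 if np.isclose(diff, 0.0) else 0.0
            rows.append(
                {"group1": names[i], "group2": names[j], "meandiff": diff, "p_adj": p}
            )
    return pd.DataFrame(rows)


def profile_summary(
    profiles: Sequence[ActivityProfile], genotype: str = ""
) -> ProfileSummary:
    """Across-fly mean ± SEM of per-fly 30-min profiles."""
    if not profiles:
        raise ValueError("no profiles")
    mat = np.vstack([p.values for p in profiles])
    n = len(profiles)
    mean = np.nanmean(mat, axis=0)
    sd = np.nanstd(mat, axis=0, ddof=1) if n > 1 else np.full(mat.shape[1], np.nan)
    return ProfileSummary(genotype, mean, sd / np.sqrt(n), n)
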