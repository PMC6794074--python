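"""Fluorescence quantification and cycling statistics for clock neurons.

Staining intensity of a neuron is scored as the mean of the brightest fully
in-ROI 3×3 pixel block; three background intensities scored the same way are
averaged and subtracted (corrected values may go negative — clamping would
bias amplitude estimates downward).  Per-timepoint summaries are mean ± SEM
over brains; time/genotype dependence is assessed by two-way factorial ANOVA
and oscillation amplitude by the per-brain value at the peak timepoint minus
the minimum per-timepoint mean ("damping amplitude").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "IntensityTimecourse",
    "AnovaTable",
    "brightest_block_mean",
    "background_correct",
    "read_image",
    "score_rois",
    "timecourse_summary",
    "twoway_anova",
    "damping_amplitudes",
]

MIN_BRAINS_PER_TIMEPOINT = 5


@dataclass
class IntensityTimecourse:
    """Background-corrected ROI intensities for one neuron cluster/genotype.

    ``data`` has columns ``brain_id``, ``timepoint_h``, ``intensity`` (a.u.).
    ``backgrounds`` optionally records the raw background values used.
    """

    data: pd.DataFrame
    cluster: str = ""
    genotype: str = ""
    backgrounds: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        required = {"brain_id", "timepoint_h", "intensity"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"timecourse data missing columns {sorted(missing)}")

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(self.data["timepoint_h"].unique())

    def timepoint_means(self) -> pd.Series:
        return self.data.groupby("timepoint_h")["intensity"].mean().sort_index()


@dataclass
class AnovaTable:
    """Factorial ANOVA results: one row per effect plus the residual."""

    table: pd.DataFrame  # effect, df, F, p
    residual_df: int
    sum_sq: pd.Series | None = None

    def effect(self, name: str) -> pd.Series:
        row = self.table[self.table["effect"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]

    def p(self, name: str) -> float:
        return float(self.effect(name)["p"])


def brightest_block_mean(
    image: np.ndarray, roi: np.ndarray | None = None, k: int = 3
) -> float:
    """Mean of the brightest k×k block whose pixels all lie inside the ROI.

    ``roi`` is a boolean mask of the same shape as ``image`` (default: the
    whole frame).  Raises if no k×k block fits entirely inside the ROI.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if k < 1 or k > min(img.shape):
        raise ValueError(f"block size {k} does not fit a {img.shape} image")
    if roi is None:
        roi = np.ones(img.shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != img.shape:
        raise ValueError("roi mask must match image shape")
    valid = sliding_window_view(roi, (k, k)).all(axis=(2, 3))
    if not valid.any():
        raise ValueError(f"ROI contains no fully interior {k}x{k} block")
    # contiguous-slice means keep the reduction order of the block definition
    best = -np.inf
    for i, j in zip(*np.nonzero(valid)):
        m = img[i:i + k, j:j + k].mean()
        if m > best:
            best = m
    return float(best)


def background_correct(raw: float, backgrounds) -> float:
    """Subtract the mean of exactly three background intensities."""
    bg = np.asarray(backgrounds, dtype=float)
    if bg.shape != (3,):
        raise ValueError(f"exactly 3 background values required, got {bg.size}")
    return float(raw - bg.mean())


def read_image(path) -> np.ndarray:
    """Load a single 2-D grayscale section or projection (TIFF)."""
    import tifffile

    img = np.asarray(tifffile.imread(path), dtype=float)
    if img.ndim != 2:
        raise ValueError(
            f"{path}: expected a single 2-D section or max-projection, "
            f"got shape {img.shape}"
        )
    return img


def score_rois(
    image: np.ndarray,
    rois,
    backgrounds=None,
    k: int = 3,
) -> dict[str, float]:
    """Brightest-block intensity for each labeled ROI of one image.

    ``rois`` is either a mapping label -> boolean mask or a labeled integer
    mask image (0 = outside any ROI).  When three background intensities are
    given they are averaged and subtracted from every score.
    """
    if isinstance(rois, np.ndarray):
        labels = [int(v) for v in np.unique(rois) if v != 0]
        rois = {str(lab): rois == lab for lab in labels}
    out = {}
    for label, mask in rois.items():
        val = brightest_block_mean(image, mask, k=k)
        if backgrounds is not None:
            val = background_correct(val, backgrounds)
        out[str(label)] = val
    return out


def timecourse_summary(
    tc: IntensityTimecourse | pd.DataFrame,
    min_n: int = MIN_BRAINS_PER_TIMEPOINT,
) -> pd.DataFrame:
    """Per-timepoint mean ± SEM and n; warns when n falls below ``min_n``."""
    df = tc.data if isinstance(tc, IntensityTimecourse) else tc
    if df.empty:
        raise ValueError("empty timecourse")
    g = df.groupby("timepoint_h")["intensity"]
    out = pd.DataFrame(
        {
            "mean": g.mean(),
            "sem": g.sem(ddof=1),
            "n": g.size(),
        }
    ).reset_index()
    low = out[out["n"] < min_n]
    if not low.empty:
        warnings.warn(
            f"fewer than {min_n} brains at timepoint(s) "
            f"{low['timepoint_h'].tolist()}",
            UserWarning,
            stacklevel=2,
        )
    return out


def twoway_anova(records: pd.DataFrame, interaction: bool = True) -> AnovaTable:
    """Two-way factorial ANOVA of intensity on genotype × timepoint.

    ``records`` needs columns ``value`` (or ``intensity``), ``genotype`` and
    ``timepoint`` (or ``timepoint_h``).  Balanced designs reduce to the
    classical sums-of-squares decomposition; unbalanced designs use Type-II
    sums of squares.  Empty design cells make the interaction inestimable
    and raise an error naming the cells.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = records.rename(
        columns={"intensity": "value", "timepoint_h": "timepoint"}
    ).copy()
    for col in ("value", "genotype", "timepoint"):
        if col not in df.columns:
            raise ValueError(f"records missing column {col!r}")
    if df["genotype"].nunique() < 2 or df["timepoint"].nunique() < 2:
        raise ValueError("need >= 2 genotypes and >= 2 timepoints")
    cells = df.groupby(["genotype", "timepoint"], sort=True).size()
    full = pd.MultiIndex.from_product(
        [sorted(df["genotype"].unique()), sorted(df["timepoint"].unique())]
    )
    empty = full.difference(cells.index)
    if interaction and len(empty):
        raise ValueError(f"empty design cells with interaction requested: {list(empty)}")
    df["genotype"] = df["genotype"].astype(str)
    df["timepoint"] = df["timepoint"].astype(str)

    formula = "value ~ C(genotype) * C(timepoint)" if interaction else (
        "value ~ C(genotype) + C(timepoint)"
    )
    fit = ols(formula, data=df).fit()
    resid_df = int(fit.df_resid)
    if np.isclose(df["value"].var(ddof=0), 0.0):
        # degenerate flat data: every effect explains nothing
        names = ["genotype", "timepoint"] + (["genotype:timepoint"] if interaction else [])
        table = pd.DataFrame(
            {
                "effect": names,
                "df": [df["genotype"].nunique() - 1,
                       df["timepoint"].nunique() - 1,
                       ] + ([(df["genotype"].nunique() - 1) * (df["timepoint"].nunique() - 1)]
                            if interaction else []),
                "F": 0.0,
                "p": 1.0,
            }
        )
        return AnovaTable(table, resid_df)
    aov = sm.stats.anova_lm(fit, typ=2)
    aov = aov.drop(index="Residual")
    rename = {
        "C(genotype)": "genotype",
        "C(timepoint)": "timepoint",
        "C(genotype):C(timepoint)": "genotype:timepoint",
    }
    table = pd.DataFrame(
        {
            "effect": [rename.get(i, i) for i in aov.index],
            "df": aov["df"].astype(int).to_numpy(),
            "F": aov["F"].to_numpy(),
            "p": aov["PR(>F)"].to_numpy(),
        }
    )
    return AnovaTable(table, resid_df, sum_sq=aov["sum_sq"])


def damping_amplitudes(
    tc: IntensityTimecourse | pd.DataFrame,
    peak_timepoint: float | None = None,
) -> pd.DataFrame:
    """Per-brain oscillation amplitudes at the peak timepoint.

    Amplitude of a brain collected at the peak timepoint (the timepoint with
    the maximal mean, unless given) is its intensity minus the minimum
    per-timepoint mean — the trough of the cycling curve.  Returns a frame
    with ``brain_id`` and ``amplitude``; group comparisons are done
    downstream with :func:`circadam.profiles.compare_groups`.
    """
    df = tc.data if isinstance(tc, IntensityTimecourse) else tc
    means = df.groupby("timepoint_h")["intensity"].mean()
    if len(means) < 2:
        raise ValueError("need >= 2 timepoints to define peak and trough")
    trough = float(means.min())
    peak = float(means.idxmax()) if peak_timepoint is None else float(peak_timepoint)
    at_peak = df[df["timepoint_h"] == peak]
    if at_peak.empty:
        raise ValueError(f"no brains at peak timepoint {peak}")
    return pd.DataFrame(
        {
            "brain_id": at_peak["brain_id"].to_numpy(),
            "amplitude": at_peak["intensity"].to_numpy() - trough,
            "peak_timepoint_h": peak,
        }
    )
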