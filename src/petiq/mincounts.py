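"""Minimum counts needed to keep an error metric below a target level.

From the pooled long-format metric table (one value per case, region,
count level and metric) the analysis determines, per case, the smallest
count level N* at which the metric is at or below the allowed percent
level and stays below it at every higher available level — the guard
protects against non-monotone noise in individual series.  Per-case N*
values are pooled into histograms on 1 x 10^6-count bins, summarized by
their (bin-center weighted) mean, median and maximum, and swept over
percent levels to produce minimum-counts curves per region, per SUV
statistic and per lesion-size subgroup.

Cases whose series never meets the level are censored from the summaries;
their count is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExceedanceHistogram",
    "MinCountsCurve",
    "case_min_counts",
    "exceedance_histogram",
    "min_counts_curve",
    "nstar_per_case",
    "subgroup_curves",
]

DEFAULT_BIN = 1e6


@dataclass
class ExceedanceHistogram:
    """Distribution of per-case minimum count levels N* at one percent level."""

    metric: str
    percent_threshold: float
    region: str
    bin_width: float
    bin_centers: np.ndarray
    frequencies: np.ndarray
    mean_counts: float
    max_counts: float
    n_censored: int = 0


@dataclass
class MinCountsCurve:
    """Required counts vs allowed percent level for one region and statistic."""

    metric: str
    region: str
    statistic: str
    percent_levels: np.ndarray
    mean_counts: np.ndarray      # histogram-mean summary
    median_counts: np.ndarray    # "half of the cases" summary
    max_counts: np.ndarray       # worst-case summary
    n_cases: np.ndarray = field(default_factory=lambda: np.array([]))
    n_censored: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "metric": self.metric, "region": self.region, "statistic": self.statistic,
            "percent_level": self.percent_levels, "mean_counts": self.mean_counts,
            "median_counts": self.median_counts, "max_counts": self.max_counts,
            "n_cases": self.n_cases, "n_censored": self.n_censored,
        })


def case_min_counts(counts: Sequence[float], values: Sequence[float],
                    percent_threshold: float) -> float:
    """Smallest count level meeting the threshold at it and every level above.

    ``counts`` and ``values`` are one case's series across count levels
    (any order).  Returns ``math.inf`` when the threshold is never met at
    the top level.
    """
    c = np.asarray(counts, dtype=np.float64)
    v = np.asarray(values, dtype=np.float64)
    if c.size < 3:
        raise ValueError("need at least three count levels per case")
    order = np.argsort(c)
    c, v = c[order], v[order]
    passing = np.abs(v) <= percent_threshold
    # Longest all-passing suffix.
    nstar = math.inf
    for level, ok in zip(c[::-1], passing[::-1]):
        if not ok:
            break
        nstar = float(level)
    return nstar


def nstar_per_case(records: pd.DataFrame, metric: str, percent_threshold: float,
                   region: str | None = None, case_col: str = "case") -> pd.Series:
    """Per-case N* from a long-format table with columns case, counts, value."""
    df = records[records["metric"] == metric]
    if region is not None:
        df = df[df["region"] == region]
    if df.empty:
        raise ValueError(f"no records for metric {metric!r}" +
                         (f" in region {region!r}" if region else ""))
    return df.groupby(case_col, sort=True).apply(
        lambda g: case_min_counts(g["counts"].to_numpy(), g["value"].to_numpy(),
                                  percent_threshold),
        include_groups=False,
    )


def exceedance_histogram(records: pd.DataFrame, metric: str, percent_threshold: float,
                         region: str | None = None, bin_width: float = DEFAULT_BIN,
                         case_col: str = "case") -> ExceedanceHistogram:
    """Histogram of per-case N* on bins centered at multiples of ``bin_width``.

    The summary mean is the frequency-weighted mean of bin centers, the
    maximum is the highest occupied bin center; censored cases (threshold
    never met) are excluded from both and counted separately.
    """
    nstar = nstar_per_case(records, metric, percent_threshold, region, case_col)
    finite = nstar[np.isfinite(nstar)].to_numpy()
    n_censored = int(nstar.size - finite.size)
    if finite.size == 0:
        return ExceedanceHistogram(metric, percent_threshold, region or "all", bin_width,
                                   np.array([]), np.array([]), math.nan, math.nan, n_censored)
    idx = np.rint(finite / bin_width).astype(np.int64)
    centers = np.arange(idx.min(), idx.max() + 1) * bin_width
    freq = np.bincount(idx - idx.min())
    mean_counts = float(np.sum(centers * freq) / freq.sum())
    max_counts = float(centers[freq.nonzero()[0][-1]])
    return ExceedanceHistogram(metric, percent_threshold, region or "all", bin_width,
                               centers, freq, mean_counts, max_counts, n_censored)


def min_counts_curve(records: pd.DataFrame, metric: str,
                     percent_levels: Sequence[float], region: str,
                     statistic: str = "mean", bin_width: float = DEFAULT_BIN,
                     case_col: str = "case") -> MinCountsCurve:
    """Sweep allowed percent levels and summarize required counts.

    ``metric`` names the error family ('bias', 'cov' or 'ste'); the SUV
    statistic selects the '_mean' or '_max' variant of that metric in the
    table.  Required counts are non-increasing in the allowed level.
    """
    levels = np.asarray(sorted(float(p) for p in percent_levels))
    if levels.size < 2:
        raise ValueError("need at least two percent levels")
    metric_name = metric if metric.endswith(("_mean", "_max")) else f"{metric}_{statistic}"
    means, medians, maxes, ncases, ncens = [], [], [], [], []
    for level in levels:
        nstar = nstar_per_case(records, metric_name, level, region, case_col)
        finite = nstar[np.isfinite(nstar)].to_numpy()
        ncases.append(nstar.size)
        ncens.append(int(nstar.size - finite.size))
        if finite.size == 0:
            means.append(math.nan)
            medians.append(math.nan)
            maxes.append(math.nan)
            continue
        hist = exceedance_histogram(records, metric_name, level, region, bin_width, case_col)
        means.append(hist.mean_counts)
        medians.append(float(np.median(finite)))
        maxes.append(float(finite.max()))
    return MinCountsCurve(metric=metric_name, region=region, statistic=statistic,
                          percent_levels=levels,
                          mean_counts=np.asarray(means), median_counts=np.asarray(medians),
                          max_counts=np.asarray(maxes), n_cases=np.asarray(ncases),
                          n_censored=np.asarray(ncens))


def subgroup_curves(records: pd.DataFrame, volumes_ml: dict[str, float], metric: str,
                    percent_levels: Sequence[float], statistic: str = "mean",
                    region: str | None = None, volume_threshold_ml: float = 5.0,
                    case_col: str = "case") -> tuple[MinCountsCurve, MinCountsCurve]:
    """Minimum-counts curves for small (< threshold) and large (>= threshold) lesions.

    ``volumes_ml`` maps case id -> lesion volume.  Raises if either
    subgroup is empty.
    """
    small_ids = {c for c, v in volumes_ml.items() if v < volume_threshold_ml}
    large_ids = {c for c, v in volumes_ml.items() if v >= volume_threshold_ml}
    if not small_ids or not large_ids:
        raise ValueError("both lesion-volume subgroups must be nonempty")
    curves = []
    for ids, tag in ((small_ids, "small"), (large_ids, "large")):
        sub = records[records[case_col].isin(ids)]
        curve = min_counts_curve(sub, metric, percent_levels,
                                 region if region is not None else "lesion",
                                 statistic, case_col=case_col)
        curve.region = f"lesion_{tag}"
        curves.append(curve)
    return curves[0], curves[1]
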