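"""Ensemble image-quality metrics: SNR, CNR, bias, COV, STE.

All metrics operate on realization ensembles at one (subject, count
fraction).  SNR, CNR and bias are evaluated on the voxelwise mean image
across realizations; COV uses the voxelwise SD image across realizations;
STE summarizes the spread of a scalar SUV measurement over realizations.

Divisor conventions: the spatial SD inside a VOI uses the population
divisor N_VOI; SDs taken across the (small, typically R = 10) realization
ensemble use the sample divisor R - 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .voi import VOIMask, background_shell, threshold_voi

__all__ = [
    "Ensemble",
    "VOIStats",
    "bias",
    "cnr",
    "cov",
    "ensemble_metrics",
    "ensemble_stats",
    "ste",
    "threshold_sensitivity",
    "voi_stats",
]


@dataclass
class Ensemble:
    """R reconstructed SUV images of one subject at one count fraction."""

    realizations: np.ndarray          # stack (R, *grid)
    mean_image: np.ndarray
    sd_image: np.ndarray
    reference_full: np.ndarray        # full-statistics reconstruction
    subject_id: str = "subject"
    fraction: float = 1.0
    realized_counts: list[int] = field(default_factory=list)

    @property
    def n_realizations(self) -> int:
        return int(self.realizations.shape[0])

    @property
    def mean_counts(self) -> float:
        """Mean realized true counts across realizations — the count level."""
        return float(np.mean(self.realized_counts)) if self.realized_counts else math.nan


def ensemble_stats(realizations: np.ndarray | Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise mean and sample SD (divisor R-1) across realizations."""
    stack = np.stack([np.asarray(r, dtype=np.float64) for r in realizations]) \
        if not isinstance(realizations, np.ndarray) else np.asarray(realizations, dtype=np.float64)
    if stack.shape[0] < 2:
        raise ValueError("need at least two realizations for an SD image")
    return stack.mean(axis=0), stack.std(axis=0, ddof=1)


class VOIStats(NamedTuple):
    mean: float
    sd: float
    snr: float
    suvmax: float
    degenerate: bool


def voi_stats(image: np.ndarray, mask: np.ndarray | VOIMask) -> VOIStats:
    """Mean, spatial SD (population divisor), SNR = mean/SD and SUVmax in a VOI.

    A VOI with zero spatial SD is flagged degenerate and its SNR reported
    as +inf.
    """
    m = mask.mask if isinstance(mask, VOIMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty VOI mask")
    vals = np.asarray(image, dtype=np.float64)[m]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    if sd == 0.0:
        return VOIStats(mean, 0.0, math.inf, float(vals.max()), True)
    return VOIStats(mean, sd, mean / sd, float(vals.max()), False)


def cnr(mean_image: np.ndarray, lesion: np.ndarray | VOIMask,
        shell: np.ndarray | VOIMask) -> float:
    """Contrast-to-noise ratio on the ensemble mean image.

    (lesion mean - background mean) / background spatial SD, where the
    background is the dilated shell around the lesion.  Returns +/-inf if
    the shell SD is zero.
    """
    lm = lesion.mask if isinstance(lesion, VOIMask) else np.asarray(lesion, dtype=bool)
    sm = shell.mask if isinstance(shell, VOIMask) else np.asarray(shell, dtype=bool)
    if np.any(lm & sm):
        raise ValueError("lesion and background shell overlap")
    les = voi_stats(mean_image, lm)
    bg = voi_stats(mean_image, sm)
    if bg.sd == 0.0:
        return math.copysign(math.inf, les.mean - bg.mean) if les.mean != bg.mean else 0.0
    return (les.mean - bg.mean) / bg.sd


def bias(mean_frac: float, mean_full: float) -> float:
    """Percent deviation of a reduced-count SUV from its full-statistics value."""
    if mean_full <= 0:
        raise ValueError("full-statistics reference must be positive")
    return (mean_frac - mean_full) / mean_full * 100.0


def cov(mean_image: np.ndarray, sd_image: np.ndarray, mask: np.ndarray | VOIMask,
        as_printed: bool = False, statistic: str = "mean") -> float:
    """Ensemble (statistical) noise in percent.

    For ``statistic="mean"`` (the SUVmean variant): 100 x mean(SD image) /
    mean(mean image) over the VOI — the coefficient of variation across
    realizations.  For ``statistic="max"`` (the SUVmax variant) the SD
    image is read at the location of the mean-image maximum and divided by
    that maximum.  ``as_printed=True`` returns the reciprocal orientation
    (mean/SD) for strict comparability with sources that print the ratio
    inverted.
    """
    m = mask.mask if isinstance(mask, VOIMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty VOI mask")
    mean_vals = np.asarray(mean_image, dtype=np.float64)[m]
    sd_vals = np.asarray(sd_image, dtype=np.float64)[m]
    if statistic == "mean":
        mean_of_mean = float(mean_vals.mean())
        mean_of_sd = float(sd_vals.mean())
    elif statistic == "max":
        peak = int(np.argmax(mean_vals))
        mean_of_mean = float(mean_vals[peak])
        mean_of_sd = float(sd_vals[peak])
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    if as_printed:
        if mean_of_sd <= 0:
            raise ValueError("zero SD: inverted COV undefined")
        return mean_of_mean / mean_of_sd * 100.0
    if mean_of_mean <= 0:
        raise ValueError("zero mean: COV undefined")
    return mean_of_sd / mean_of_mean * 100.0


def ste(values_per_realization: Sequence[float]) -> float:
    """Reproducibility of a SUV measurement in percent.

    100 x sample SD (divisor R-1) of the per-realization values over their
    mean; scale invariant.
    """
    vals = np.asarray(values_per_realization, dtype=np.float64)
    if vals.size < 2:
        raise ValueError("need at least two realizations")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("zero mean: STE undefined")
    return float(vals.std(ddof=1) / mean * 100.0)


def threshold_sensitivity(ensemble: Ensemble, seed_voxel: tuple[int, ...],
                          voxel_size: tuple[float, ...],
                          pcts: Sequence[float] = (20.0, 40.0, 60.0, 80.0),
                          shell_radius_voxels: int = 2) -> pd.DataFrame:
    """CNR as a function of segmentation threshold, with its ensemble spread.

    Lesion masks are delineated at each threshold on the full-statistics
    reference image; the background shell derived from the lowest
    (default 20 %) threshold mask is shared by all thresholds.  For each
    threshold the CNR on the mean image is reported together with the COV
    (percent) of per-realization CNRs.
    """
    pcts = sorted(float(p) for p in pcts)
    masks = {p: threshold_voi(ensemble.reference_full, seed_voxel, p, voxel_size) for p in pcts}
    shell = background_shell(masks[pcts[0]], radius_voxels=shell_radius_voxels)
    rows = []
    for p in pcts:
        lesion = masks[p]
        shell_mask = shell.mask & ~lesion.mask   # keep shell disjoint from every mask
        cnr_mean = cnr(ensemble.mean_image, lesion.mask, shell_mask)
        per_real = [cnr(r, lesion.mask, shell_mask) for r in ensemble.realizations]
        finite = [v for v in per_real if math.isfinite(v)]
        mu = float(np.mean(finite)) if finite else math.nan
        cov_pct = float(np.std(finite, ddof=1) / abs(mu) * 100.0) \
            if len(finite) > 1 and mu != 0 else math.nan
        rows.append({"threshold_pct": p, "cnr": cnr_mean,
                     "cnr_realization_mean": mu, "cnr_cov_pct": cov_pct,
                     "n_voxels": lesion.n_voxels})
    return pd.DataFrame(rows)


def ensemble_metrics(ensemble: Ensemble, vois: dict[str, VOIMask],
                     lesion_shells: dict[str, VOIMask] | None = None) -> pd.DataFrame:
    """Long-format metric table for one ensemble.

    ``vois`` maps region name -> mask (delineated on the full-statistics
    image); ``lesion_shells`` maps lesion region names to their background
    shells, enabling CNR for those regions.  One row per (region, metric);
    counts is the mean realized true-count level of the ensemble.
    """
    lesion_shells = lesion_shells or {}
    rows = []
    counts = ensemble.mean_counts

    def add(region: str, metric: str, value: float, units: str = "") -> None:
        rows.append({"subject": ensemble.subject_id, "region": region,
                     "fraction": ensemble.fraction, "counts": counts,
                     "metric": metric, "value": value, "units": units})

    for region, mask in vois.items():
        st = voi_stats(ensemble.mean_image, mask)
        ref = voi_stats(ensemble.reference_full, mask)
        add(region, "suvmean", st.mean)
        add(region, "suvmax", st.suvmax)
        add(region, "snr", st.snr)
        add(region, "bias_mean", bias(st.mean, ref.mean), "%")
        add(region, "bias_max", bias(st.suvmax, ref.suvmax), "%")
        add(region, "cov_mean", cov(ensemble.mean_image, ensemble.sd_image, mask), "%")
        add(region, "cov_max", cov(ensemble.mean_image, ensemble.sd_image, mask,
                                   statistic="max"), "%")
        per_real = [voi_stats(r, mask) for r in ensemble.realizations]
        add(region, "ste_mean", ste([s.mean for s in per_real]), "%")
        add(region, "ste_max", ste([s.suvmax for s in per_real]), "%")
        if region in lesion_shells:
            add(region, "cnr", cnr(ensemble.mean_image, mask, lesion_shells[region]))
    return pd.DataFrame(rows)
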