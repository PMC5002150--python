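"""Count-response models.

Photon detection is Poisson, so the squared liver SNR is expected to grow
linearly with the number of detected counts N; per subject the slope lumps
scanner sensitivity, reconstruction noise reduction and attenuation into a
single composite factor K_i.  Dividing each subject's SNR^2 by its fitted
K_i pools all subjects onto a common unit-slope line over the mid-count
range where the Poisson approximation holds.

The normalized lesion CNR (CNR divided by its full-statistics value) is
described by the heuristic saturation curve

    y = 1 / (1 + a * x**(-b)),   x = counts in units of 10^6,

which rises toward the asymptote y = 1 as counts grow.  No interpretative
model is attached to this form; it is used to predict the count level
needed to retain a target fraction of the full-statistics CNR, via the
closed-form inverse x = (a / (1/y - 1))**(1/b).

All fits express counts in units of 10^6 on the x-axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FitResult",
    "SubjectSensitivity",
    "correct_snr2",
    "estimate_ki",
    "fit_linear",
    "fit_normalized_cnr",
    "fit_power",
    "invert_normalized_cnr",
    "predict_normalized_cnr",
]

COUNTS_UNIT = 1e6


@dataclass
class FitResult:
    """Fitted model form, coefficients and goodness of fit."""

    form: str                       # 'linear' | 'power' | 'cnr_saturation'
    coefficients: dict[str, float]
    r2: float
    count_range: tuple[float, float] | None = None
    x_units: str = "counts/1e6"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in self.coefficients.values()):
            raise ValueError("non-finite fit coefficients")


@dataclass
class SubjectSensitivity:
    """Per-subject composite sensitivity factor K_i (slope of SNR^2 vs counts)."""

    subject_id: str
    ki: float
    weight: float | None = None

    def __post_init__(self) -> None:
        if not self.ki > 0:
            raise ValueError(f"K_i must be positive, got {self.ki}")


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """1 - SS_res/SS_tot with SS_tot about the mean, for every model form."""
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_linear(counts: np.ndarray, snr2: np.ndarray, through_origin: bool = False) -> FitResult:
    """OLS fit of SNR^2 on counts (rescaled to units of 10^6)."""
    x = np.asarray(counts, dtype=np.float64) / COUNTS_UNIT
    y = np.asarray(snr2, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least three points")
    if np.any(x <= 0):
        raise ValueError("counts must be positive")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: constant x")
    if through_origin:
        slope = float(np.sum(x * y) / np.sum(x * x))
        intercept = 0.0
    else:
        A = np.column_stack([x, np.ones_like(x)])
        (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    yhat = slope * x + intercept
    return FitResult(form="linear",
                     coefficients={"slope": float(slope), "intercept": float(intercept)},
                     r2=_r2(y, yhat),
                     count_range=(float(x.min() * COUNTS_UNIT), float(x.max() * COUNTS_UNIT)))


def estimate_ki(counts: np.ndarray, liver_snr2: np.ndarray,
                count_range: tuple[float, float] = (1e6, 20e6),
                subject_id: str = "subject", weight: float | None = None) -> SubjectSensitivity:
    """K_i as the through-origin slope of liver SNR^2 on counts (10^6 units).

    Only points inside ``count_range`` (raw counts) enter the fit; the
    default range is the mid-count regime where the proportionality of
    SNR^2 with counts holds.
    """
    x = np.asarray(counts, dtype=np.float64)
    y = np.asarray(liver_snr2, dtype=np.float64)
    keep = (x >= count_range[0]) & (x <= count_range[1]) & np.isfinite(y)
    if keep.sum() < 2:
        raise ValueError(f"need >= 2 points within count range {count_range}")
    xs = x[keep] / COUNTS_UNIT
    ys = y[keep]
    ki = float(np.sum(xs * ys) / np.sum(xs * xs))
    return SubjectSensitivity(subject_id=subject_id, ki=ki, weight=weight)


def correct_snr2(snr2: np.ndarray, ki: SubjectSensitivity | float) -> np.ndarray:
    """Divide SNR^2 values by the subject's K_i, removing subject effects."""
    k = ki.ki if isinstance(ki, SubjectSensitivity) else float(ki)
    if not k > 0:
        raise ValueError("K_i must be positive")
    return np.asarray(snr2, dtype=np.float64) / k


def _saturation(x: np.ndarray, a: float, b: float) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + a * np.power(x, -b))


def fit_normalized_cnr(counts_millions: np.ndarray, normalized_cnr: np.ndarray) -> FitResult:
    """Nonlinear LS fit of y = 1/(1 + a x^-b), a > 0, b > 0.

    Multi-start over a log-spaced grid of (a, b) initial values; the start
    with the lowest residual sum of squares wins.  Raises on degenerate
    (constant) data or if no start converges.
    """
    x = np.asarray(counts_millions, dtype=np.float64)
    y = np.asarray(normalized_cnr, dtype=np.float64)
    if x.size < 4:
        raise ValueError("need at least four points")
    if np.any(x <= 0):
        raise ValueError("counts must be positive")
    if np.ptp(y) == 0:
        raise ValueError("degenerate fit: constant normalized CNR")

    def resid(theta):
        return _saturation(x, np.exp(theta[0]), np.exp(theta[1])) - y

    best = None
    for a0 in (0.5, 2.41, 10.0):
        for b0 in (0.3, 0.8, 1.5):
            try:
                sol = least_squares(resid, x0=np.log([a0, b0]), method="lm", xtol=1e-14, ftol=1e-14)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not best.success:
        raise RuntimeError("normalized-CNR fit did not converge from any start")
    a, b = np.exp(best.x)
    yhat = _saturation(x, a, b)
    return FitResult(form="cnr_saturation", coefficients={"a": float(a), "b": float(b)},
                     r2=_r2(y, yhat),
                     count_range=(float(x.min() * COUNTS_UNIT), float(x.max() * COUNTS_UNIT)),
                     meta={"n_points": int(x.size)})


def predict_normalized_cnr(fit: FitResult, counts_millions: float | np.ndarray):
    """Evaluate the fitted saturation curve at a count level (10^6 units)."""
    if fit.form != "cnr_saturation":
        raise ValueError("fit is not a cnr_saturation model")
    x = np.asarray(counts_millions, dtype=np.float64)
    if np.any(x <= 0):
        raise ValueError("counts must be positive")
    out = _saturation(x, fit.coefficients["a"], fit.coefficients["b"])
    return float(out) if np.isscalar(counts_millions) else out


def invert_normalized_cnr(fit: FitResult, target: float) -> float:
    """Counts (10^6 units) needed to retain ``target`` of the full CNR.

    Closed-form inverse x = (a / (1/y - 1))**(1/b); the asymptote y = 1 is
    unreachable.
    """
    if fit.form != "cnr_saturation":
        raise ValueError("fit is not a cnr_saturation model")
    if not 0.0 < target < 1.0:
        raise ValueError("target normalized CNR must be in (0, 1)")
    a, b = fit.coefficients["a"], fit.coefficients["b"]
    return float((a / (1.0 / target - 1.0)) ** (1.0 / b))


def fit_power(x: np.ndarray, y: np.ndarray) -> FitResult:
    """Descriptive power-law fit y = c x^p via log-log OLS (x, y > 0)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power fit requires positive data")
    if x.size < 3:
        raise ValueError("need at least three points")
    A = np.column_stack([np.log(x), np.ones_like(x)])
    (p, logc), *_ = np.linalg.lstsq(A, np.log(y), rcond=None)
    yhat = np.exp(logc) * x ** p
    return FitResult(form="power", coefficients={"c": float(np.exp(logc)), "p": float(p)},
                     r2=_r2(y, yhat), count_range=None, x_units="native")
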