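"""Quantification QC: calibration, detection limits, CVs.

Implements the targeted-assay arithmetic used to qualify the LC-MS
workflow: internal-standard normalization, linear calibration of spiked
standards, blank-based LOD/LLOQ thresholds, coefficients of variation,
extraction efficiency, and the physiological sweat-volume range implied
by published fingertip sweat rates.

Sample (n-1) standard deviations are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import DomainError, InputError

__all__ = [
    "CalibrationCurve",
    "normalize_to_standard",
    "fit_calibration",
    "lod",
    "lloq",
    "cv_percent",
    "extraction_efficiency",
    "sweat_volume_range",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Unweighted OLS line through calibration levels."""

    slope: float
    intercept: float
    r_squared: float
    residuals: np.ndarray
    conc_range: tuple[float, float]


def normalize_to_standard(raw_auc, standard_auc: float):
    """Signal normalized to the co-injected internal standard (ratio)."""
    if standard_auc <= 0:
        raise DomainError("standard AUC must be positive")
    return np.asarray(raw_auc, dtype=float) / standard_auc


def fit_calibration(levels, responses, weighted: bool = False
                    ) -> CalibrationCurve:
    """Least-squares calibration line response = slope*level + intercept.

    ``weighted=True`` uses 1/x^2 weights (common for wide calibration
    ranges); the default is the plain unweighted fit.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size:
        raise InputError("levels and responses must have equal length")
    if x.size < 3:
        raise InputError("need at least 3 calibration levels")
    if np.ptp(y) == 0:
        raise InputError("constant responses: R^2 undefined")
    if weighted:
        if np.any(x <= 0):
            raise InputError("1/x^2 weighting requires positive levels")
        w = 1.0 / x ** 2
        W = np.sum(w)
        xb, yb = np.sum(w * x) / W, np.sum(w * y) / W
        slope = np.sum(w * (x - xb) * (y - yb)) / np.sum(w * (x - xb) ** 2)
        intercept = yb - slope * xb
        fitted = slope * x + intercept
        r2 = 1.0 - np.sum(w * (y - fitted) ** 2) / np.sum(w * (y - yb) ** 2)
    else:
        res = stats.linregress(x, y)
        slope, intercept = res.slope, res.intercept
        fitted = slope * x + intercept
        r2 = res.rvalue ** 2
    return CalibrationCurve(
        slope=float(slope), intercept=float(intercept),
        r_squared=float(r2), residuals=y - fitted,
        conc_range=(float(x.min()), float(x.max())),
    )


def _blank_stats(blank_signals) -> tuple[float, float]:
    b = np.asarray(blank_signals, dtype=float)
    if b.size < 1 or not np.all(np.isfinite(b)):
        raise InputError("blank signals must be finite and non-empty")
    sd = float(np.std(b, ddof=1)) if b.size > 1 else 0.0
    return float(np.mean(b)), sd


def lod(blank_signals) -> float:
    """Limit of detection: blank mean + 3 * sample SD."""
    mean, sd = _blank_stats(blank_signals)
    return mean + 3.0 * sd


def lloq(blank_signals) -> float:
    """Lower limit of quantification: blank mean + 10 * sample SD."""
    mean, sd = _blank_stats(blank_signals)
    return mean + 10.0 * sd


def cv_percent(values) -> float:
    """Coefficient of variation, 100 * SD / mean (%)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InputError("need at least 2 values for a CV")
    mean = float(np.mean(v))
    if mean == 0:
        raise DomainError("CV undefined for zero mean")
    return 100.0 * float(np.std(v, ddof=1)) / mean


def extraction_efficiency(processed_signal: float,
                          direct_signal: float) -> float:
    """Recovery of a processed standard vs direct injection (%)."""
    if direct_signal <= 0:
        raise DomainError("direct signal must be positive")
    return 100.0 * processed_signal / direct_signal


def sweat_volume_range(duration_min: float, area_cm2: float,
                       rate_lo: float, rate_hi: float
                       ) -> tuple[float, float]:
    """Collected-volume range duration * area * rate (nL).

    Rates in nL/min/cm^2; with 2 min sampling over 2 cm^2 and fingertip
    secretion rates of 50-500 nL/min/cm^2 this gives 200-2000 nL.
    """
    if duration_min < 0 or area_cm2 < 0:
        raise InputError("duration and area must be non-negative")
    if rate_lo < 0 or rate_hi < rate_lo:
        raise InputError("need 0 <= rate_lo <= rate_hi")
    return (duration_min * area_cm2 * rate_lo,
            duration_min * area_cm2 * rate_hi)
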