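"""Linear calibration and HPLC method-validation computations.

Ordinary least-squares area-vs-concentration calibration with inverse
prediction, ICH-style detection/quantitation limits (3.3σ/S and 10σ/S),
percent recovery of spiked samples, and relative-standard-deviation
summaries for precision / repeatability / stability panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .refdata import STOCK_CONC_G_PER_ML

__all__ = [
    "CalibrationCurve",
    "ValidationSummary",
    "QuantResult",
    "fit_calibration",
    "quantify",
    "lod_loq",
    "rsd",
    "recovery",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear area = slope·conc + intercept model over a stated range."""

    slope: float                       # area per (µg/ml)
    intercept: float                   # area
    r: float                           # Pearson correlation
    linear_range: tuple[float, float]  # µg/ml
    lod: float | None = None           # µg/ml
    loq: float | None = None           # µg/ml

    def __post_init__(self) -> None:
        lo, hi = self.linear_range
        if not lo < hi:
            raise ValueError("linear_range low must be < high")
        if self.lod is not None and self.loq is not None and not self.lod < self.loq:
            raise ValueError("lod must be < loq")

    def predict(self, conc: float) -> float:
        """Forward prediction: expected area at a concentration (µg/ml)."""
        return self.slope * conc + self.intercept


@dataclass(frozen=True)
class QuantResult:
    """Inverse prediction for one sample injection."""

    conc_ug_per_ml: float
    extrapolated: bool
    content_mg_per_g: float | None = None


@dataclass(frozen=True)
class ValidationSummary:
    """Method-validation RSD panel plus spike-recovery summary (all %)."""

    precision_rsd: float
    repeatability_rsd: float
    stability_rsd: float
    recovery_mean: float
    recovery_rsd: float

    def __post_init__(self) -> None:
        for name in ("precision_rsd", "repeatability_rsd", "stability_rsd", "recovery_rsd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def fit_calibration(concs: Sequence[float], areas: Sequence[float],
                    noise_sd: float | None = None) -> CalibrationCurve:
    """OLS calibration fit; r is the Pearson correlation of the points.

    ``noise_sd`` (area units), when given, sets LOD/LOQ via the 3.3σ/S and
    10σ/S conventions.
    """
    x = np.asarray(concs, dtype=float)
    y = np.asarray(areas, dtype=float)
    if x.shape != y.shape:
        raise ValueError("concs and areas must have equal length")
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct concentrations")
    fit = stats.linregress(x, y)
    lod = loq = None
    if noise_sd is not None:
        lod, loq = lod_loq(noise_sd, float(fit.slope))
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        linear_range=(float(x.min()), float(x.max())),
        lod=lod, loq=loq,
    )


def quantify(area: float, curve: CalibrationCurve, dilution_factor: float = 1.0,
             stock_conc_g_per_ml: float | None = STOCK_CONC_G_PER_ML) -> QuantResult:
    """Invert the calibration: conc = (area - intercept)/slope × dilution.

    Results outside the calibrated range are flagged extrapolated, not
    rejected.  ``stock_conc_g_per_ml`` maps solution concentration back to
    content per gram of freeze-dried powder (mg/g); pass None to skip.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; cannot invert")
    conc = (area - curve.intercept) / curve.slope * dilution_factor
    lo, hi = curve.linear_range
    extrapolated = not (lo <= conc / dilution_factor <= hi)
    content = None
    if stock_conc_g_per_ml:
        # µg/ml divided by g/ml gives µg/g; report mg/g.
        content = conc / stock_conc_g_per_ml / 1000.0
    return QuantResult(conc_ug_per_ml=float(conc), extrapolated=extrapolated,
                       content_mg_per_g=content)


def lod_loq(noise_sd: float, slope: float) -> tuple[float, float]:
    """Detection and quantitation limits: (3.3·σ/S, 10·σ/S) in µg/ml."""
    if slope <= 0:
        raise ValueError("slope must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    return 3.3 * noise_sd / slope, 10.0 * noise_sd / slope


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation, %: 100·s/mean with the n−1 sample SD."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 values")
    mean = float(v.mean())
    if mean <= 0:
        raise ValueError("RSD requires a positive mean (areas/contents)")
    return 100.0 * float(v.std(ddof=1)) / mean


def recovery(measured_total: float, base_amount: float, spiked_amount: float) -> float:
    """Spike recovery, %: 100·(measured − base)/spiked."""
    if spiked_amount <= 0:
        raise ValueError("spiked_amount must be > 0")
    return 100.0 * (measured_total - base_amount) / spiked_amount
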