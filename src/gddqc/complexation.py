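"""Spectrophotometric inference of complex stoichiometry and thermodynamics.

Three classical procedures, applied to Cu(II)–ligand titrations:

* **Mole-ratio method** — absorbance vs titrant:analyte mole ratio; the
  abscissa of the turning point of the two best-fit line segments is the
  coordination ratio.
* **Equilibrium-shift method** — under excess ligand the linearization
  ``ln[(A0-Ae)/(Ae-A_inf)] = n·ln C + ln K`` yields the coordination number
  ``n`` (slope) and equilibrium constant ``K`` (exp(intercept)).
* **Van't Hoff / Gibbs** — ``ln K = -ΔrHm/(R·T) + ΔrSm/R`` fitted over
  temperature gives enthalpy and entropy; ``ΔrGm = ΔrHm - T·ΔrSm``.

Energies are reported in kJ/mol, entropies in J·mol⁻¹·K⁻¹, with
R = 8.314 J·mol⁻¹·K⁻¹ fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "R_GAS",
    "T_REF_DEFAULT",
    "RATIO_CATALOGUE",
    "TitrationSeries",
    "StoichiometryResult",
    "ShiftFitResult",
    "ThermoResult",
    "InteractionLabel",
    "NoBreakpointError",
    "DegenerateSeriesError",
    "mole_ratio_breakpoint",
    "equilibrium_shift_fit",
    "vant_hoff_fit",
    "gibbs_free_energy",
    "thermo_result",
    "classify_interaction",
]

#: Gas constant, J·mol⁻¹·K⁻¹ (fixed; energies in kJ/mol, entropies in J/mol/K).
R_GAS = 8.314

#: Default reference temperature for Gibbs energies (K).
T_REF_DEFAULT = 298.15

#: Small-integer ligand:Cu ratios a single-complex model plausibly produces.
RATIO_CATALOGUE: tuple[tuple[int, int], ...] = (
    (1, 2), (1, 1), (3, 2), (2, 1), (5, 2), (3, 1),
)


class NoBreakpointError(ValueError):
    """The titration curve has no statistically defensible turning point."""


class DegenerateSeriesError(ValueError):
    """The series carries no usable signal (e.g. A0 == A_inf)."""


@dataclass
class TitrationSeries:
    """One spectrophotometric titration at a fixed working wavelength.

    ``mode`` is ``"mole_ratio"`` (fixed ligand total, Cu titrated; abscissa is
    the Cu:ligand mole ratio) or ``"equilibrium_shift"`` (fixed Cu total,
    ligand titrated in large excess).  ``A0`` is the absorbance with zero
    titrant; ``A_inf`` the plateau at effectively infinite titrant excess
    (shift mode only).
    """

    mode: str
    fixed_conc: float                   # mol/L, the held-constant species total
    varied_concs: np.ndarray            # mol/L, titrated species totals
    absorbances: np.ndarray             # dimensionless A at each point
    A0: float | None = None
    A_inf: float | None = None
    temperature: float = 310.15         # K

    def __post_init__(self) -> None:
        if self.mode not in ("mole_ratio", "equilibrium_shift"):
            raise ValueError(f"unknown titration mode {self.mode!r}")
        self.varied_concs = np.asarray(self.varied_concs, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.varied_concs.shape != self.absorbances.shape:
            raise ValueError("varied_concs and absorbances must have equal length")
        if np.any(self.varied_concs < 0):
            raise ValueError("varied concentrations must be non-negative")
        if np.any(np.diff(self.varied_concs) <= 0):
            raise ValueError("varied concentrations must be strictly increasing")
        if self.fixed_conc <= 0:
            raise ValueError("fixed_conc must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")

    @property
    def mole_ratios(self) -> np.ndarray:
        """Titrant-total : fixed-total mole ratios (mole-ratio abscissa)."""
        return self.varied_concs / self.fixed_conc


@dataclass(frozen=True)
class StoichiometryResult:
    """Outcome of the mole-ratio turning-point analysis."""

    breakpoint_x: float                 # titrant:fixed mole ratio at the kink
    ligand_to_cu: tuple[int, int]       # reduced ligand:Cu ratio
    snapped: bool                       # True if snapped to RATIO_CATALOGUE
    f_statistic: float = float("inf")
    p_value: float = 0.0

    @property
    def ratio_value(self) -> float:
        """ligand:Cu as a decimal (2:1 -> 2.0)."""
        return self.ligand_to_cu[0] / self.ligand_to_cu[1]


@dataclass(frozen=True)
class ShiftFitResult:
    """Outcome of the equilibrium-shift log-linear fit."""

    n: float                            # coordination number (slope)
    K: float                            # equilibrium constant, (mol/L)^(-n) for m=1
    r_squared: float
    points_used: int
    points_excluded: int = 0


@dataclass(frozen=True)
class ThermoResult:
    """Van't Hoff / Gibbs thermodynamic summary."""

    delta_H: float                      # kJ/mol
    delta_S: float                      # J·mol⁻¹·K⁻¹
    delta_G: float                      # kJ/mol at T_ref
    T_ref: float                        # K
    R: float = R_GAS

    def __post_init__(self) -> None:
        expected = self.delta_H - self.T_ref * self.delta_S / 1000.0
        if abs(self.delta_G - expected) > 1e-9:
            raise ValueError("delta_G inconsistent with delta_H - T*delta_S")


@dataclass(frozen=True)
class InteractionLabel:
    """Sign-based qualitative driving-force classification."""

    label: str
    spontaneous: bool
    delta_G: float                      # kJ/mol at the classification temperature


def _two_segment_fit(x: np.ndarray, y: np.ndarray, k: int):
    """Fit disjoint segments x[:k], x[k:] by OLS; return (rss, lines)."""
    p1 = np.polyfit(x[:k], y[:k], 1)
    p2 = np.polyfit(x[k:], y[k:], 1)
    rss = (np.sum((np.polyval(p1, x[:k]) - y[:k]) ** 2)
           + np.sum((np.polyval(p2, x[k:]) - y[k:]) ** 2))
    return rss, (p1, p2)


def mole_ratio_breakpoint(series: TitrationSeries, *,
                          snap_tol: float = 0.15,
                          alpha: float = 0.01) -> StoichiometryResult:
    """Locate the turning point of a mole-ratio titration curve.

    An exhaustive two-segment piecewise-linear least-squares fit (every
    admissible split with >= 2 points per segment) is compared to a single
    straight line by an F-test; if the two-segment model is not better at
    level ``alpha`` the series is declared breakpoint-free (no complexation,
    or a range that never crosses saturation).  The breakpoint is the abscissa
    of the intersection of the two best-fit lines.

    The abscissa convention is titrant:fixed = Cu:ligand, so the ligand:Cu
    ratio is ``1 / breakpoint_x``; it is snapped to the small-integer
    catalogue when within ``snap_tol`` relative distance.
    """
    if series.mode != "mole_ratio":
        raise ValueError("series mode must be 'mole_ratio'")
    x = series.mole_ratios
    y = series.absorbances
    n_pts = len(x)
    if n_pts < 5:
        raise ValueError(f"need >= 5 titration points, got {n_pts}")

    # Single-line null model.
    p0 = np.polyfit(x, y, 1)
    rss0 = float(np.sum((np.polyval(p0, x) - y) ** 2))

    best = None
    for k in range(2, n_pts - 1):
        rss, lines = _two_segment_fit(x, y, k)
        if best is None or rss < best[0]:
            best = (rss, lines)
    rss1, (p1, p2) = best

    # Essentially flat or perfectly linear data carry no breakpoint signal.
    scale = max(float(np.ptp(y)), 1e-12)
    if rss0 <= (1e-10 * scale) ** 2 * n_pts:
        raise NoBreakpointError("titration curve is flat or a single line; no turning point")

    df_denom = n_pts - 4
    if rss1 <= 1e-24 * scale ** 2 * n_pts:
        f_stat, p_value = float("inf"), 0.0   # noiseless piecewise-linear data
    else:
        f_stat = ((rss0 - rss1) / 2.0) / (rss1 / df_denom)
        p_value = float(stats.f.sf(f_stat, 2, df_denom))
    if p_value >= alpha:
        raise NoBreakpointError(
            f"two-segment fit not better than a single line (F={f_stat:.3g}, p={p_value:.3g})"
        )

    if math.isclose(p1[0], p2[0], rel_tol=1e-12, abs_tol=1e-300):
        raise NoBreakpointError("fitted segments are parallel; no intersection")
    bx = (p2[1] - p1[1]) / (p1[0] - p2[0])
    if not (x[0] < bx < x[-1]):
        raise NoBreakpointError(
            f"segment intersection {bx:.4g} lies outside the titrated range"
        )

    ratio = 1.0 / bx  # ligand:Cu
    snapped = False
    best_pair = None
    best_rel = math.inf
    for p, q in RATIO_CATALOGUE:
        rel = abs(ratio - p / q) / (p / q)
        if rel < best_rel:
            best_rel, best_pair = rel, (p, q)
    if best_rel <= snap_tol:
        snapped = True
        pair = best_pair
    else:
        frac = Fraction(ratio).limit_denominator(6)
        pair = (frac.numerator, frac.denominator)
    return StoichiometryResult(breakpoint_x=float(bx), ligand_to_cu=pair,
                               snapped=snapped, f_statistic=float(f_stat),
                               p_value=p_value)


def equilibrium_shift_fit(series: TitrationSeries) -> ShiftFitResult:
    """Fit ``ln[(A0-Ae)/(Ae-A_inf)] = n·ln C + ln K`` by ordinary least squares.

    Points whose Ae lies outside the open interval (A_inf, A0) — i.e. where
    the log ratio is undefined because measurement scatter pushed Ae past
    either asymptote — are dropped and counted, not clamped.  Orientation
    (absorbance rising or falling with ligand) is detected from the sign of
    ``A_inf - A0`` and handled by the ratio itself.
    """
    if series.mode != "equilibrium_shift":
        raise ValueError("series mode must be 'equilibrium_shift'")
    if series.A0 is None or series.A_inf is None:
        raise ValueError("equilibrium-shift series requires both A0 and A_inf")
    a0, ainf = float(series.A0), float(series.A_inf)
    if math.isclose(a0, ainf, rel_tol=0.0, abs_tol=1e-12):
        raise DegenerateSeriesError("A0 == A_inf: series carries no saturation signal")

    ratio = (a0 - series.absorbances) / (series.absorbances - ainf)
    usable = (ratio > 0) & (series.varied_concs > 0)
    n_used = int(np.count_nonzero(usable))
    if n_used < 3:
        raise ValueError(f"need >= 3 usable points, got {n_used}")

    x = np.log(series.varied_concs[usable])
    y = np.log(ratio[usable])
    fit = stats.linregress(x, y)
    return ShiftFitResult(
        n=float(fit.slope),
        K=float(np.exp(fit.intercept)),
        r_squared=float(fit.rvalue ** 2),
        points_used=n_used,
        points_excluded=int(len(ratio) - n_used),
    )


def vant_hoff_fit(temperatures: Sequence[float],
                  K_values: Sequence[float]) -> tuple[float, float]:
    """OLS of ln K on 1/T; returns (ΔrHm in kJ/mol, ΔrSm in J·mol⁻¹·K⁻¹).

    ``ln K = -ΔrHm/(R·T) + ΔrSm/R`` so ΔrHm = -slope·R/1000 and
    ΔrSm = intercept·R.
    """
    T = np.asarray(temperatures, dtype=float)
    K = np.asarray(K_values, dtype=float)
    if T.shape != K.shape:
        raise ValueError("temperatures and K_values must have equal length")
    if len(np.unique(T)) < 3:
        raise ValueError("need >= 3 distinct temperatures")
    if np.any(T <= 0):
        raise ValueError("temperatures must be > 0 K")
    if np.any(K <= 0):
        raise ValueError("equilibrium constants must be > 0")
    fit = stats.linregress(1.0 / T, np.log(K))
    delta_H = -fit.slope * R_GAS / 1000.0
    delta_S = fit.intercept * R_GAS
    return float(delta_H), float(delta_S)


def gibbs_free_energy(delta_H: float, delta_S: float, T_ref: float) -> float:
    """ΔrGm = ΔrHm − T·ΔrSm, in kJ/mol (ΔrSm enters in J·mol⁻¹·K⁻¹)."""
    if T_ref <= 0:
        raise ValueError("T_ref must be > 0 K")
    return delta_H - T_ref * delta_S / 1000.0


def thermo_result(delta_H: float, delta_S: float,
                  T_ref: float = T_REF_DEFAULT) -> ThermoResult:
    """Bundle Van't Hoff output and the Gibbs energy at ``T_ref``."""
    return ThermoResult(delta_H=delta_H, delta_S=delta_S,
                        delta_G=gibbs_free_energy(delta_H, delta_S, T_ref),
                        T_ref=T_ref)


def classify_interaction(delta_H: float, delta_S: float,
                         T_ref: float = T_REF_DEFAULT) -> InteractionLabel:
    """Qualitative driving force from the signs of ΔH and ΔS.

    Standard Ross–Subramanian convention: ΔH<0, ΔS<0 → hydrogen bonding /
    van der Waals; ΔH<0, ΔS>0 → electrostatic; ΔH>0, ΔS>0 → hydrophobic.
    The remaining quadrant (ΔH>0, ΔS<0) is enthalpically and entropically
    unfavourable and is labelled as such.
    """
    if delta_H < 0 and delta_S < 0:
        label = "hydrogen bonding / van der Waals"
    elif delta_H < 0 and delta_S >= 0:
        label = "electrostatic"
    elif delta_H >= 0 and delta_S > 0:
        label = "hydrophobic"
    else:
        label = "unfavourable (no classical driving force)"
    dG = gibbs_free_energy(delta_H, delta_S, T_ref)
    return InteractionLabel(label=label, spontaneous=bool(dG < 0), delta_G=dG)
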