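"""Exact mass-action equilibrium and Beer–Lambert forward model for Cu_m L_n complexes.

A single complex species is assumed::

    m Cu + n L  <=>  Cu_m L_n,      K = [Cu_m L_n] / ([Cu]^m [L]^n)

with ``K`` in units of (mol/L)^(1 - m - n).  This is exactly the model that the
mole-ratio, equilibrium-shift and Van't Hoff analyses presuppose, and it serves
as the brute-force oracle against which those approximate estimators are
tested.  Stepwise intermediates, pH-dependent speciation and competing ligands
are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "BindingSystem",
    "EquilibriumState",
    "SolverError",
    "solve_equilibrium",
    "absorbance",
    "CONC_FLOOR",
]

#: Concentration floor (mol/L) used in ratios/logarithms to avoid division by
#: zero; far below any desk-scale concentration, so it never affects results.
CONC_FLOOR = 1e-30


class SolverError(RuntimeError):
    """Raised when the equilibrium root-finder fails to converge."""


@dataclass(frozen=True)
class BindingSystem:
    """A Cu_m L_n complexation system with its optical constants.

    Parameters
    ----------
    m, n
        Stoichiometric counts of Cu and ligand per complex (positive ints).
        A 2:1 ligand:Cu complex (e.g. the quercetin case) is ``m=1, n=2``;
        the anthraquinone 1:2 complexes are ``m=2, n=1``.
    K
        Equilibrium constant for ``m Cu + n L <=> Cu_m L_n``,
        units (mol/L)^(1-m-n).
    eps_L, eps_Cu, eps_complex
        Molar extinction coefficients at the working wavelength,
        L·mol⁻¹·cm⁻¹.
    path_length
        Optical path length in cm.
    """

    m: int = 1
    n: int = 1
    K: float = 0.0
    eps_L: float = 0.0
    eps_Cu: float = 0.0
    eps_complex: float = 0.0
    path_length: float = 1.0

    def __post_init__(self) -> None:
        if not (isinstance(self.m, int) and self.m >= 1):
            raise ValueError(f"m must be a positive integer, got {self.m!r}")
        if not (isinstance(self.n, int) and self.n >= 1):
            raise ValueError(f"n must be a positive integer, got {self.n!r}")
        if self.K < 0:
            raise ValueError(f"K must be >= 0, got {self.K!r}")
        for name in ("eps_L", "eps_Cu", "eps_complex"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.path_length <= 0:
            raise ValueError("path_length must be > 0")


@dataclass(frozen=True)
class EquilibriumState:
    """Speciation of one solved equilibrium (all concentrations mol/L)."""

    L_free: float
    Cu_free: float
    complex_conc: float
    residual: float  # dimensionless mass-action residual


def _mass_action_residual(c: float, L_total: float, Cu_total: float,
                          system: BindingSystem) -> float:
    """K·(L-n·c)^n·(Cu-m·c)^m - c; strictly decreasing in c on the physical bracket."""
    L_free = L_total - system.n * c
    Cu_free = Cu_total - system.m * c
    return system.K * (L_free ** system.n) * (Cu_free ** system.m) - c


def solve_equilibrium(L_total: float, Cu_total: float,
                      system: BindingSystem, *, rtol: float = 1e-14,
                      max_iter: int = 200) -> EquilibriumState:
    """Solve the single-complex mass-action equilibrium exactly.

    The complex concentration is the unique root of
    ``K (L_tot - n c)^n (Cu_tot - m c)^m = c`` on
    ``[0, min(L_tot/n, Cu_tot/m)]``; it is found by bracketed root-finding
    (Brent), which is guaranteed to converge because the residual is strictly
    decreasing on the bracket.

    Raises
    ------
    ValueError
        If a total concentration is negative.
    SolverError
        If the root-finder fails (does not occur for physical inputs).
    """
    if L_total < 0 or Cu_total < 0:
        raise ValueError(
            f"total concentrations must be >= 0 (L_total={L_total}, Cu_total={Cu_total})"
        )
    c_max = min(L_total / system.n, Cu_total / system.m)
    if system.K == 0.0 or c_max == 0.0:
        return EquilibriumState(L_free=L_total, Cu_free=Cu_total,
                                complex_conc=0.0, residual=0.0)

    try:
        c = brentq(_mass_action_residual, 0.0, c_max,
                   args=(L_total, Cu_total, system),
                   xtol=1e-30, rtol=8.9e-16, maxiter=max_iter)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - defensive
        raise SolverError(
            f"equilibrium solve failed for L_total={L_total}, Cu_total={Cu_total}, "
            f"system={system}"
        ) from exc

    L_free = max(L_total - system.n * c, 0.0)
    Cu_free = max(Cu_total - system.m * c, 0.0)
    residual = abs(system.K * L_free ** system.n * Cu_free ** system.m - c) / max(c, CONC_FLOOR)
    # Brent on the monotone residual gives machine-precision roots; a large
    # relative residual can only mean the bracket assumptions were violated.
    if residual > 1e-6 and c > 1e3 * CONC_FLOOR:
        raise SolverError(
            f"equilibrium residual {residual:.3e} exceeds tolerance for "
            f"L_total={L_total}, Cu_total={Cu_total}, system={system}"
        )
    return EquilibriumState(L_free=L_free, Cu_free=Cu_free,
                            complex_conc=c, residual=residual)


def absorbance(state: EquilibriumState, system: BindingSystem) -> float:
    """Beer–Lambert absorbance of a solved state at the working wavelength.

    ``A = b · (eps_L·[L] + eps_Cu·[Cu] + eps_complex·[Cu_m L_n])`` with path
    length ``b`` in cm.  The model is single-wavelength; spectra are handled
    as independent single-wavelength evaluations.
    """
    return system.path_length * (
        system.eps_L * state.L_free
        + system.eps_Cu * state.Cu_free
        + system.eps_complex * state.complex_conc
    )
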