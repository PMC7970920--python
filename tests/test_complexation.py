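"""Tests for the mole-ratio, equilibrium-shift and Van't Hoff/Gibbs estimators."""

import math

import numpy as np
import pytest

from gddqc.binding_model import BindingSystem
from gddqc.complexation import (
    R_GAS,
    DegenerateSeriesError,
    NoBreakpointError,
    TitrationSeries,
    classify_interaction,
    equilibrium_shift_fit,
    gibbs_free_energy,
    mole_ratio_breakpoint,
    thermo_result,
    vant_hoff_fit,
)
from gddqc.refdata import COMPLEXATION
from gddqc.synthetic import (
    TitrationScenario,
    generate_ideal_shift_series,
    generate_titration,
    generate_vant_hoff_series,
)


def make_mole_ratio_series(m=1, n=1, K=1e12, fixed=1e-4, noise_sd=0.0, seed=0):
    system = BindingSystem(m=m, n=n, K=K, eps_L=1e4, eps_complex=4e3)
    grid = np.arange(0.1, 3.0 + 1e-9, 0.1)
    return generate_titration(TitrationScenario(
        system=system, design="mole_ratio", fixed_total=fixed, grid=grid,
        noise_sd=noise_sd, seed=seed))


class TestMoleRatioBreakpoint:
    def test_tight_binding_1to1(self):
        res = mole_ratio_breakpoint(make_mole_ratio_series(m=1, n=1, K=1e12))
        assert res.breakpoint_x == pytest.approx(1.0, rel=0.02)
        assert res.ligand_to_cu == (1, 1) and res.snapped

    def test_quercetin_type_2to1(self):
        """A 2:1 ligand:Cu complex kinks at Cu:L = 0.5 (the flavonoid case)."""
        res = mole_ratio_breakpoint(make_mole_ratio_series(m=1, n=2, K=1e16))
        assert res.ligand_to_cu == (2, 1) and res.snapped

    def test_anthraquinone_type_1to2(self):
        res = mole_ratio_breakpoint(make_mole_ratio_series(m=2, n=1, K=1e16))
        assert res.ligand_to_cu == (1, 2) and res.snapped

    def test_flat_series_has_no_breakpoint(self):
        with pytest.raises(NoBreakpointError):
            mole_ratio_breakpoint(make_mole_ratio_series(K=0.0))

    def test_too_few_points_rejected(self):
        s = TitrationSeries(mode="mole_ratio", fixed_conc=1e-4,
                            varied_concs=[1e-5, 2e-5, 3e-5, 4e-5],
                            absorbances=[1.0, 0.9, 0.8, 0.8])
        with pytest.raises(ValueError, match="5"):
            mole_ratio_breakpoint(s)

    def test_noise_tolerated(self):
        res = mole_ratio_breakpoint(
            make_mole_ratio_series(m=1, n=1, K=1e12, noise_sd=0.005, seed=7))
        assert res.ligand_to_cu == (1, 1) and res.snapped


class TestEquilibriumShiftFit:
    def test_half_saturation_identity(self):
        """At C = K^(-1/n) the log ratio is zero: f/(1-f) = K·C = 1."""
        K = 1e4
        s = generate_ideal_shift_series(K, 1, [1e-5, 1.0 / K, 1e-3])
        ratio = (s.A0 - s.absorbances[1]) / (s.absorbances[1] - s.A_inf)
        assert ratio == pytest.approx(1.0, rel=1e-12)

    def test_ideal_series_exact_recovery(self):
        s = generate_ideal_shift_series(1.616e7, 2, np.geomspace(1e-5, 1e-3, 20))
        fit = equilibrium_shift_fit(s)
        assert fit.n == pytest.approx(2.0, abs=1e-9)
        assert fit.K == pytest.approx(1.616e7, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n,K", [(1, 1e5), (2, 1e7), (3, 5e9)])
    def test_exact_solver_round_trip_excess_ligand(self, n, K):
        """Fit on exact-solver data recovers (n, K) within 1% when L >= 100 Cu.

        The grid stays in the rising region (below ~10x half-saturation):
        deeper into saturation the finite realization of the A_inf plateau
        biases the log ratio, a documented limitation of the generator.
        """
        cu = 1e-10
        c_half = (1.0 / K) ** (1.0 / n)
        grid = np.geomspace(max(100 * cu, c_half / 30), c_half * 3, 15)
        system = BindingSystem(m=1, n=n, K=K, eps_Cu=500.0, eps_complex=1e6)
        series = generate_titration(TitrationScenario(
            system=system, design="equilibrium_shift", fixed_total=cu, grid=grid))
        fit = equilibrium_shift_fit(series)
        assert fit.n == pytest.approx(n, rel=0.01)
        assert fit.K == pytest.approx(K, rel=0.01)

    def test_bias_grows_as_excess_shrinks(self):
        """Ligand depletion biases K monotonically as the excess factor drops."""
        n, K = 2, 1e7
        c_half = (1.0 / K) ** (1.0 / n)
        grid = np.geomspace(c_half / 10, c_half * 10, 15)
        errors = []
        for cu in (1e-8, 1e-6, 1e-5):
            system = BindingSystem(m=1, n=n, K=K, eps_complex=1e6)
            series = generate_titration(TitrationScenario(
                system=system, design="equilibrium_shift", fixed_total=cu, grid=grid))
            fit = equilibrium_shift_fit(series)
            errors.append(abs(fit.K - K) / K)
        assert errors[0] < errors[1] < errors[2]

    def test_degenerate_series_rejected(self):
        s = TitrationSeries(mode="equilibrium_shift", fixed_conc=1e-6,
                            varied_concs=[1e-5, 1e-4, 1e-3],
                            absorbances=[0.5, 0.5, 0.5], A0=0.4, A_inf=0.4)
        with pytest.raises(DegenerateSeriesError):
            equilibrium_shift_fit(s)

    def test_out_of_interval_points_dropped_not_clamped(self):
        s = generate_ideal_shift_series(1e6, 1, np.geomspace(1e-7, 1e-4, 10))
        bad = np.array(s.absorbances)
        bad[0] = s.A0 - 0.01   # scatter past the zero-ligand asymptote
        s2 = TitrationSeries(mode="equilibrium_shift", fixed_conc=s.fixed_conc,
                             varied_concs=s.varied_concs, absorbances=bad,
                             A0=s.A0, A_inf=s.A_inf)
        fit = equilibrium_shift_fit(s2)
        assert fit.points_excluded == 1
        assert fit.points_used == 9
        assert fit.K == pytest.approx(1e6, rel=1e-6)


class TestVantHoffAndGibbs:
    def test_constant_K_gives_zero_enthalpy(self):
        dH, dS = vant_hoff_fit([288, 298, 308], [1e5, 1e5, 1e5])
        assert dH == pytest.approx(0.0, abs=1e-9)
        assert dS == pytest.approx(R_GAS * math.log(1e5), rel=1e-9)

    def test_exact_generated_series_recovers_inputs(self):
        kt = generate_vant_hoff_series(-11.683, -16.072, (288, 298, 308, 318))
        dH, dS = vant_hoff_fit([t for t, _ in kt], [k for _, k in kt])
        assert dH == pytest.approx(-11.683, rel=1e-6)
        assert dS == pytest.approx(-16.072, rel=1e-6)

    def test_unit_slope_check(self):
        # ln K drops by 1 when 1/T rises by 1 -> slope -1 -> dH = R/1000
        dH, _ = vant_hoff_fit([1.0, 2.0, 4.0], [math.e ** -1, math.e ** -0.5, math.e ** -0.25])
        assert dH == pytest.approx(R_GAS / 1000.0, rel=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            vant_hoff_fit([288, 298], [1.0, 2.0])
        with pytest.raises(ValueError):
            vant_hoff_fit([288, 298, 308], [1.0, -2.0, 3.0])

    @pytest.mark.parametrize("dH,dS,expected", [
        (-11.683, -16.072, -6.894),   # flavonoid 2:1 complex
        (-11.324, -2.567, -10.559),   # curcuminoid 2:1 complex
        (-14.453, -11.03, -11.166),   # anthraquinone 1:2 complex
    ])
    def test_gibbs_reported_values(self, dH, dS, expected):
        assert gibbs_free_energy(dH, dS, 298.0) == pytest.approx(expected, abs=0.005)

    def test_zero_entropy_identity(self):
        assert gibbs_free_energy(-7.5, 0.0, 310.0) == -7.5

    def test_gibbs_equals_minus_RTlnK_on_generated_series(self):
        """Identity of the linear model: refit thermodynamics reproduce
        -R·T·ln K(T)/1000 exactly for a Van't-Hoff-generated series."""
        dH0, dS0 = -13.1, -8.4
        kt = generate_vant_hoff_series(dH0, dS0, (288, 298, 308, 318))
        dH, dS = vant_hoff_fit([t for t, _ in kt], [k for _, k in kt])
        for T0, K0 in kt:
            assert gibbs_free_energy(dH, dS, T0) == pytest.approx(
                -R_GAS * T0 * math.log(K0) / 1000.0, rel=1e-9)

    def test_thermo_result_internal_consistency(self):
        res = thermo_result(-11.683, -16.072, 298.0)
        assert res.delta_G == pytest.approx(res.delta_H - 298.0 * res.delta_S / 1000.0,
                                            abs=1e-12)


class TestInteractionClassification:
    def test_all_catalogue_complexes_are_spontaneous_exothermic(self):
        """Every reported complex has dH < 0, dS < 0, dG < 0: spontaneous,
        exothermic, entropy-reducing, hydrogen-bond/van-der-Waals driven."""
        for params in COMPLEXATION.values():
            assert params.delta_H < 0 and params.delta_S < 0 and params.delta_G < 0
            label = classify_interaction(params.delta_H, params.delta_S, 298.0)
            assert label.label == "hydrogen bonding / van der Waals"
            assert label.spontaneous

    @pytest.mark.parametrize("dH,dS,expected", [
        (5.0, 20.0, "hydrophobic"),
        (-5.0, 20.0, "electrostatic"),
        (-5.0, -20.0, "hydrogen bonding / van der Waals"),
    ])
    def test_sign_convention(self, dH, dS, expected):
        assert classify_interaction(dH, dS).label == expected
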