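"""Forward models, residue functions and derived parameters.

Oracles: exponential convolution against fine-grid trapezoidal quadrature;
every compartment model against stiff numerical integration of its ODE
system; the extended Tofts model against direct quadrature of its defining
integral.
"""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from perfkit import (
    KineticParams,
    TimeGrid,
    TimeSeriesCurve,
    derive_parameters,
    exp_conv,
    forward_model,
    residue,
)
from perfkit.errors import GridError, InvalidParameterError

MODELS_CONV = ("1CP", "2CUM", "2CFM", "2CXM")
ALL_MODELS = MODELS_CONV + ("ETM",)


def params_of(model, truth_params, **override):
    d = dict(truth_params[model])
    d.update(override)
    return KineticParams.from_dict(model, d)


# --------------------------------------------------------------------------
# exponential convolution


class TestExpConv:
    def test_zero_input_gives_zero(self, zero_curve):
        assert np.all(exp_conv(10.0, zero_curve).values == 0.0)

    @pytest.mark.parametrize("T", [0.5, 1.5, 10.0, 300.0])
    def test_constant_input_closed_form(self, grid, T):
        one = TimeSeriesCurve(grid, np.ones(grid.n))
        expected = 1.0 - np.exp(-grid.t / T)
        np.testing.assert_allclose(exp_conv(T, one).values, expected, atol=1e-12)

    def test_matches_fine_grid_quadrature(self, grid):
        # piecewise-linear random input; oracle = trapezoid on a dt/100 grid
        rng = np.random.default_rng(7)
        a = rng.random(grid.n) * np.concatenate([[0], np.ones(grid.n - 1)])
        curve = TimeSeriesCurve(grid, a)
        T = 10.0
        y = exp_conv(T, curve).values
        tf = np.linspace(0, grid.t[-1], (grid.n - 1) * 100 + 1)
        af = np.interp(tf, grid.t, a)
        ref = np.array(
            [
                np.trapezoid(af[: i + 1] / T * np.exp(-(tf[i] - tf[: i + 1]) / T), tf[: i + 1])
                for i in range(0, tf.size, 100)
            ]
        )
        scale = np.abs(ref).max()
        assert np.abs(y - ref).max() / scale < 1e-4

    def test_invalid_time_constant_rejected(self, zero_curve):
        with pytest.raises(InvalidParameterError):
            exp_conv(0.0, zero_curve)
        with pytest.raises(InvalidParameterError):
            exp_conv(-1.0, zero_curve)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(0.1, 10.0), T=st.floats(1.0, 100.0))
    def test_linearity_in_amplitude(self, grid, scale, T):
        rng = np.random.default_rng(3)
        a = rng.random(grid.n)
        base = exp_conv(T, TimeSeriesCurve(grid, a)).values
        scaled = exp_conv(T, TimeSeriesCurve(grid, scale * a)).values
        np.testing.assert_allclose(scaled, scale * base, rtol=1e-12, atol=1e-14)


# --------------------------------------------------------------------------
# residue functions


class TestResidue:
    @pytest.mark.parametrize("model", MODELS_CONV)
    def test_starts_at_one_and_bounded(self, model, grid, truth_params):
        R = residue(model, params_of(model, truth_params), grid)
        assert R[0] == pytest.approx(1.0)
        assert np.all(R >= -1e-12) and np.all(R <= 1.0 + 1e-12)

    @pytest.mark.parametrize("model", ["1CP", "2CXM"])
    def test_monotone_nonincreasing(self, model, grid, truth_params):
        R = residue(model, params_of(model, truth_params), grid)
        assert np.all(np.diff(R) <= 1e-12)

    def test_uptake_asymptote_is_extraction_fraction(self, truth_params):
        p = dict(truth_params["2CUM"])
        Tp = p["vp"] / (p["Fp"] + p["PS"])
        E = p["PS"] / (p["Fp"] + p["PS"])
        grid = TimeGrid(np.array([0.0, 25.0 * Tp, 50.0 * Tp]))
        R = residue("2CUM", KineticParams.from_dict("2CUM", p), grid)
        assert abs(R[-1] - E) < 1e-6

    def test_exchange_matches_ode_oracle(self, grid):
        Fp, vp, PS, ve = 0.01, 0.05, 0.002, 0.2
        p = KineticParams.from_dict("2CXM", dict(Fp=Fp, vp=vp, PS=PS, ve=ve))
        R = residue("2CXM", p, grid)

        def rhs(_, y):
            cp, ce = y
            return [(-Fp * cp + PS * (ce - cp)) / vp, PS * (cp - ce) / ve]

        sol = solve_ivp(rhs, (0, grid.t[-1]), [Fp / vp, 0.0], t_eval=grid.t,
                        method="LSODA", rtol=1e-10, atol=1e-13)
        R_ode = (vp * sol.y[0] + ve * sol.y[1]) / Fp
        assert np.abs(R - R_ode).max() / np.abs(R_ode).max() < 1e-3

    def test_filtration_coalescent_limit_is_continuous(self, grid, truth_params):
        # Tt -> Tp: the closed form must hand over smoothly to the limit form
        p = dict(truth_params["2CFM"])
        Tp = p["vp"] / (p["Fp"] + p["Ft"])
        near = residue("2CFM", KineticParams.from_dict("2CFM", {**p, "Tt": Tp * (1 + 1e-6)}), grid)
        exact = residue("2CFM", KineticParams.from_dict("2CFM", {**p, "Tt": Tp}), grid)
        assert np.abs(near - exact).max() < 1e-5

    @pytest.mark.parametrize("model,bad", [
        ("1CP", {"Fp": 0.0, "vp": 0.05}),
        ("1CP", {"Fp": 0.01, "vp": -0.1}),
        ("2CXM", {"Fp": 0.01, "vp": 0.05, "PS": -0.001, "ve": 0.2}),
        ("2CFM", {"Fp": 0.01, "vp": 0.05, "Ft": 0.002, "Tt": 0.0}),
    ])
    def test_nonpositive_parameters_rejected(self, model, bad, grid):
        with pytest.raises(InvalidParameterError):
            residue(model, KineticParams.from_dict(model, bad), grid)

    # 2CUM is excluded: its residue does not decay (irreversible uptake),
    # so its conservation statement is the asymptote test above
    @pytest.mark.parametrize("model", ["1CP", "2CFM", "2CXM"])
    def test_conservation_integrals(self, model, truth_params):
        """F_p int R = v_p (1CP), v_p + v_e (2CXM); int R_2CFM = T_p + E T_t."""
        p = dict(truth_params[model])
        # integrate out to 50 of the longest time constant
        if model == "1CP":
            Tmax = p["vp"] / p["Fp"]
        elif model == "2CFM":
            Tmax = max(p["Tt"], p["vp"] / (p["Fp"] + p["Ft"]))
        else:
            Tmax = max(p["ve"] / p["PS"], p["vp"] / p["Fp"])
        grid = TimeGrid(np.linspace(0.0, 50.0 * Tmax, 20001))
        R = residue(model, KineticParams.from_dict(model, p), grid)
        integral = np.trapezoid(R, grid.t)
        if model == "1CP":
            expected = p["vp"] / p["Fp"]
        elif model == "2CFM":
            Tp = p["vp"] / (p["Fp"] + p["Ft"])
            E = p["Ft"] / (p["Fp"] + p["Ft"])
            expected = Tp + E * p["Tt"]
        else:
            expected = (p["vp"] + p["ve"]) / p["Fp"]
        assert abs(integral - expected) / expected < 1e-3


# --------------------------------------------------------------------------
# forward models


def _ode_tissue(model, p, aif):
    """Stiff-integrator oracle for the convolutional models."""
    t = aif.grid.t

    def ca(x):
        return np.interp(x, t, aif.values)

    if model == "1CP":
        Fp, vp = p["Fp"], p["vp"]

        def rhs(x, y):
            return [(Fp * ca(x) - Fp * y[0]) / vp]

        sol = solve_ivp(rhs, (0, t[-1]), [0.0], t_eval=t, method="LSODA",
                        rtol=1e-10, atol=1e-13)
        return vp * sol.y[0]
    if model == "2CUM":
        Fp, vp, PS = p["Fp"], p["vp"], p["PS"]

        def rhs(x, y):
            cp, ce = y
            return [(Fp * (ca(x) - cp) - PS * cp) / vp, PS * cp]

        sol = solve_ivp(rhs, (0, t[-1]), [0.0, 0.0], t_eval=t, method="LSODA",
                        rtol=1e-10, atol=1e-13)
        return vp * sol.y[0] + sol.y[1]
    if model == "2CFM":
        Fp, vp, Ft, Tt = p["Fp"], p["vp"], p["Ft"], p["Tt"]
        vt = Ft * Tt

        def rhs(x, y):
            cp, ct = y
            return [(Fp * ca(x) - (Fp + Ft) * cp) / vp, Ft * (cp - ct) / vt]

        sol = solve_ivp(rhs, (0, t[-1]), [0.0, 0.0], t_eval=t, method="LSODA",
                        rtol=1e-10, atol=1e-13)
        return vp * sol.y[0] + vt * sol.y[1]
    Fp, vp, PS, ve = p["Fp"], p["vp"], p["PS"], p["ve"]

    def rhs(x, y):
        cp, ce = y
        return [(Fp * (ca(x) - cp) + PS * (ce - cp)) / vp, PS * (cp - ce) / ve]

    sol = solve_ivp(rhs, (0, t[-1]), [0.0, 0.0], t_eval=t, method="LSODA",
                    rtol=1e-10, atol=1e-13)
    return vp * sol.y[0] + ve * sol.y[1]


def etm_quadrature(p, aif, refine=100):
    """Direct fine-grid quadrature of the extended Tofts integral."""
    t = aif.grid.t
    tf = np.linspace(0, t[-1], (t.size - 1) * refine + 1)
    caf = np.interp(tf, t, aif.values)
    kep = p["Ktrans"] / p["ve"]
    integral = np.array(
        [
            np.trapezoid(caf[: i + 1] * np.exp(-kep * (tf[i] - tf[: i + 1])), tf[: i + 1])
            for i in range(0, tf.size, refine)
        ]
    )
    return p["vp"] * aif.values + p["Ktrans"] * integral


class TestForwardModel:
    @pytest.mark.parametrize("model", ALL_MODELS)
    def test_zero_aif_gives_zero_tissue(self, model, zero_curve, truth_params):
        ct = forward_model(model, params_of(model, truth_params), zero_curve)
        assert np.all(ct.values == 0.0)

    @pytest.mark.parametrize("model", MODELS_CONV)
    def test_matches_ode_oracle(self, model, aif_plasma, truth_params):
        p = dict(truth_params[model])
        ct = forward_model(model, KineticParams.from_dict(model, p), aif_plasma).values
        ref = _ode_tissue(model, p, aif_plasma)
        assert np.abs(ct - ref).max() / np.abs(ref).max() < 1e-3

    def test_etm_matches_quadrature(self, aif_plasma, truth_params):
        p = dict(truth_params["ETM"])
        ct = forward_model("ETM", KineticParams.from_dict("ETM", p), aif_plasma).values
        ref = etm_quadrature(p, aif_plasma)
        assert np.abs(ct - ref).max() / np.abs(ref).max() < 1e-3

    def test_etm_without_plasma_term_and_linearity(self, aif_plasma):
        p = KineticParams.from_dict("ETM", dict(Ktrans=0.003, ve=0.25, vp=0.0))
        ct = forward_model("ETM", p, aif_plasma).values
        kep = 0.003 / 0.25
        conv = 0.25 * exp_conv(1.0 / kep, aif_plasma).values
        np.testing.assert_allclose(ct, conv, rtol=1e-12)
        doubled = forward_model("ETM", p, aif_plasma.with_values(2 * aif_plasma.values))
        np.testing.assert_allclose(doubled.values, 2 * ct, rtol=1e-12)

    def test_exchange_without_leakage_equals_one_compartment(self, aif_plasma):
        one = forward_model("1CP", KineticParams.from_dict("1CP", dict(Fp=0.015, vp=0.08)),
                            aif_plasma).values
        two = forward_model(
            "2CXM",
            KineticParams.from_dict("2CXM", dict(Fp=0.015, vp=0.08, PS=0.0, ve=0.2)),
            aif_plasma,
        ).values
        assert np.abs(one - two).max() < 1e-10

    def test_exchange_with_huge_interstitium_approaches_uptake(self, aif_plasma):
        vp = 0.08
        up = forward_model("2CUM",
                           KineticParams.from_dict("2CUM", dict(Fp=0.015, vp=vp, PS=0.003)),
                           aif_plasma).values
        xc = forward_model(
            "2CXM",
            KineticParams.from_dict("2CXM", dict(Fp=0.015, vp=vp, PS=0.003, ve=1e6 * vp)),
            aif_plasma,
        ).values
        assert np.abs(up - xc).max() / np.abs(up).max() < 1e-3

    @pytest.mark.parametrize("model", ALL_MODELS)
    def test_time_invariance(self, model, grid, truth_params):
        """Delaying the AIF by whole samples delays the tissue curve alike."""
        rng = np.random.default_rng(5)
        a = np.concatenate([[0, 0, 0, 0, 0], rng.random(grid.n - 5)])
        aif = TimeSeriesCurve(grid, a)
        shift = 4
        shifted = TimeSeriesCurve(grid, np.concatenate([np.zeros(shift), a[:-shift]]))
        p = params_of(model, truth_params)
        ct = forward_model(model, p, aif).values
        ct_shift = forward_model(model, p, shifted).values
        np.testing.assert_allclose(ct_shift[shift:], ct[:-shift], atol=1e-9)

    def test_grid_mismatch_rejected(self, grid, aif_plasma, truth_params):
        other = TimeSeriesCurve(TimeGrid.uniform(50, 1.5), np.zeros(50))
        from perfkit.curves import require_same_grid

        with pytest.raises(GridError):
            require_same_grid(aif_plasma, other)


# --------------------------------------------------------------------------
# derived parameters


class TestDeriveParameters:
    def test_ktrans_is_extraction_times_flow(self):
        # E = 0.5 at Fp = 100 ml/min/100 ml -> Ktrans = 50 ml/min/100 ml
        Fp = 100.0 / 6000.0  # internal 1/s
        PS = Fp  # E = PS/(Fp+PS) = 0.5
        d = derive_parameters("2CXM", KineticParams.from_dict(
            "2CXM", dict(Fp=Fp, vp=0.05, PS=PS, ve=0.2)))
        assert d["extraction_fraction"] == pytest.approx(50.0)
        assert d["ktrans"] == pytest.approx(50.0)

    def test_no_leakage_means_zero_extraction(self):
        d = derive_parameters("2CXM", KineticParams.from_dict(
            "2CXM", dict(Fp=0.01, vp=0.05, PS=0.0, ve=0.2)))
        assert d["extraction_fraction"] == 0.0
        assert "interstitial_mtt" in d.undefined  # ve / PS with PS = 0

    def test_one_compartment_unit_arithmetic(self):
        d = derive_parameters("1CP", KineticParams.from_dict("1CP", dict(Fp=0.01, vp=0.05)))
        assert d["plasma_mtt"] == pytest.approx(5.0)
        assert d["plasma_flow"] == pytest.approx(60.0)
        assert d["plasma_volume"] == pytest.approx(5.0)

    @pytest.mark.parametrize("model,expected", [
        ("1CP", {"plasma_flow", "plasma_mtt", "plasma_volume"}),
        ("2CUM", {"plasma_flow", "plasma_mtt", "plasma_volume",
                  "extraction_fraction", "ps", "ktrans"}),
        ("2CFM", {"plasma_flow", "plasma_mtt", "plasma_volume", "tubular_mtt",
                  "tubular_flow", "extraction_fraction", "ps", "ktrans"}),
        ("2CXM", {"plasma_flow", "plasma_mtt", "plasma_volume", "interstitial_mtt",
                  "interstitial_volume", "extraction_fraction", "ps", "ktrans"}),
        ("ETM", {"plasma_volume", "interstitial_volume", "interstitial_mtt",
                 "ps", "ktrans"}),
    ])
    def test_output_row_coverage(self, model, expected, truth_params):
        d = derive_parameters(model, params_of(model, truth_params))
        assert set(d.values) == expected

    def test_etm_reports_ps_equal_ktrans(self, truth_params):
        d = derive_parameters("ETM", params_of("ETM", truth_params))
        assert d["ps"] == d["ktrans"]
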