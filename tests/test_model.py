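"""Stationarity systems, solver, limit branch, oracle, classification."""

import math

import numpy as np
import pytest

from corticomp.model import (
    PrincipleSpec,
    TissueCompositionModel,
    spine_stationarity_sides,
    wire_limit_solution,
    wire_stationarity_sides,
)

from conftest import TABLE2_EXP_ED_ROW, TABLE2_EXP_MD_ROW, TABLE3_EXP_MD_ROW

SPINE_EXP = PrincipleSpec(family="exponential", f=0.0, gamma2=0.45, theta=0.321)
WIRE_EXP = PrincipleSpec(family="exponential", f=1.0, gamma1=0.0, r=1.0,
                         theta=0.321, gamma2=1.0)

# small matrix of principle/family cases exercised repeatedly
CASES = [
    SPINE_EXP,
    PrincipleSpec(family="gamma_n2", f=0.0, gamma2=0.50, theta=0.321),
    PrincipleSpec(family="loglogistic", shape=4.0, f=0.0, gamma2=0.60,
                  theta=0.321),
    PrincipleSpec(family="lognormal", shape=0.25, f=0.0, gamma2=0.35,
                  theta=0.321),
    WIRE_EXP,
    PrincipleSpec(family="rayleigh", f=1.0, gamma1=0.0, r=0.95, theta=0.321,
                  gamma2=1.0),
    PrincipleSpec(family="exponential", f=0.5, gamma1=0.0, gamma2=0.55,
                  r=1.0, theta=0.321),
    PrincipleSpec(family="exponential", f=0.1, gamma1=2 / 3, gamma2=1.0,
                  r=0.99, theta=0.321),
]


def fit(spec, reference=None):
    return TissueCompositionModel(spec, reference=reference).fit()


# -- spec validation ----------------------------------------------------


def test_principle_spec_validation():
    with pytest.raises(ValueError, match="mixing ratio"):
        PrincipleSpec(f=1.5)
    with pytest.raises(ValueError, match="gamma2"):
        PrincipleSpec(f=0.0, gamma2=0.0)
    with pytest.raises(ValueError, match="asymmetry"):
        PrincipleSpec(r=-0.5)
    with pytest.raises(ValueError, match="beta"):
        PrincipleSpec(family="loglogistic", shape=0.9)


# -- residuals ----------------------------------------------------------


def test_analytic_residuals_match_finite_differences(rng):
    """The lambda-free conditions agree with numeric gradients of F, C."""
    for spec in CASES:
        m = TissueCompositionModel(spec)

        def F(z):
            return m.objective(*z)

        def C(z):
            fr = m.composition(*z)
            return fr.total - 1.0

        for _ in range(5):
            z = np.array([rng.uniform(0.2, 0.5), rng.uniform(0.2, 0.5),
                          rng.uniform(0.2, 2.0)])
            gF, gC = np.zeros(3), np.zeros(3)
            for i in range(3):
                h = 1e-7 * max(1.0, z[i])
                zp, zm = z.copy(), z.copy()
                zp[i] += h
                zm[i] -= h
                gF[i] = (F(zp) - F(zm)) / (2 * h)
                gC[i] = (C(zp) - C(zm)) / (2 * h)
            expected = np.array(
                [gF[0] * gC[1] - gF[1] * gC[0],
                 gF[1] * gC[2] - gF[2] * gC[1],
                 C(z)]
            )
            got = m.stationarity_residuals(*z)
            np.testing.assert_allclose(got, expected, rtol=2e-5, atol=1e-8)


def test_printed_row_is_nearly_stationary_and_random_point_is_not():
    m = TissueCompositionModel(SPINE_EXP)
    row = TABLE3_EXP_MD_ROW
    r_at_row = m.stationarity_residuals(row["x"], row["y"], row["ubar"])
    assert np.linalg.norm(r_at_row) < 5e-3  # printed values are 3-d.p. rounded
    r_off = m.stationarity_residuals(0.30, 0.42, 1.4)
    assert np.linalg.norm(r_off) > 0.01


def test_reduced_wire_condition_on_printed_row():
    """Printed axon/dendrite condition balances on the wire-min row."""
    spec = PrincipleSpec(family="exponential", f=1.0, gamma1=0.0, r=0.96,
                         theta=0.321, gamma2=1.0)
    row = TABLE2_EXP_ED_ROW
    lhs, rhs = wire_stationarity_sides(spec, row["x"], row["y"], row["ubar"])
    assert lhs == pytest.approx(0.041, abs=2e-3)
    assert rhs == pytest.approx(0.040, abs=1e-12)
    assert lhs == pytest.approx(rhs, abs=2e-3)


def test_reduced_spine_condition_on_printed_row():
    row = TABLE3_EXP_MD_ROW
    lhs, rhs = spine_stationarity_sides(SPINE_EXP, row["x"], row["ubar"])
    assert lhs == pytest.approx(0.336, abs=2e-3)
    assert lhs == pytest.approx(rhs, abs=2e-3)


def test_general_solutions_satisfy_reduced_systems():
    """f=0 / f=1 solutions of the general system obey the printed
    reduced equations to high accuracy."""
    res = fit(SPINE_EXP)
    lhs, rhs = spine_stationarity_sides(SPINE_EXP, res.x, res.mean_spine_volume)
    assert lhs == pytest.approx(rhs, rel=1e-8)

    spec_w = PrincipleSpec(family="exponential", f=1.0, gamma1=0.0, r=0.96,
                           theta=0.321, gamma2=1.0)
    res_w = fit(spec_w)
    lhs, rhs = wire_stationarity_sides(spec_w, res_w.x, res_w.y,
                                       res_w.mean_spine_volume)
    assert lhs == pytest.approx(rhs, abs=1e-9)


# -- solving ------------------------------------------------------------


def test_spine_economy_reproduces_printed_optimum():
    res = fit(SPINE_EXP)
    row = TABLE3_EXP_MD_ROW
    assert res.converged
    fr = res.fractions
    assert fr.as_array() == pytest.approx(
        [row["x"], row["y"], row["s"], row["g"], row["c"]], abs=1e-3
    )
    assert res.mean_spine_volume == pytest.approx(row["ubar"], abs=1e-3)
    assert res.P == pytest.approx(row["P"], abs=1e-3)


@pytest.mark.parametrize(
    "r,row", [(1.00, TABLE2_EXP_MD_ROW), (0.96, TABLE2_EXP_ED_ROW)]
)
def test_wire_volume_minimization_reproduces_printed_optima(r, row):
    spec = PrincipleSpec(family="exponential", f=1.0, gamma1=0.0, r=r,
                         theta=0.321, gamma2=1.0)
    res = fit(spec)
    fr = res.fractions
    assert fr.as_array() == pytest.approx(
        [row["x"], row["y"], row["s"], row["g"], row["c"]], abs=1.5e-3
    )
    assert res.mean_spine_volume == pytest.approx(row["ubar"], abs=2e-3)


def test_converged_solutions_meet_tolerances_and_recompose_exactly():
    for spec in CASES:
        res = fit(spec)
        assert res.converged
        assert res.residual_norm < 1e-8
        fr = res.fractions
        assert abs(fr.residual) < 1e-9
        # s, g, c re-derive from (x, y, ubar) through the coupling laws
        m = res.model
        re = m.composition(res.x, res.y, res.mean_spine_volume)
        assert re.as_array() == pytest.approx(fr.as_array(), abs=1e-14)


def test_lagrange_multiplier_consistent_across_conditions():
    for spec in CASES:
        m = TissueCompositionModel(spec)
        res = m.fit()
        x, y, ub = res.params
        th = spec.theta
        P, dP = m._P(ub, th), m._dP(ub, th)
        from corticomp.model import _objective_grad, _pieces

        _, _, _, gC, _ = _pieces(spec, x, y, ub, P, dP)
        _, gF = _objective_grad(spec, x, y, ub, P, dP)
        lam = res.lagrange_multiplier
        scale = np.abs(gF).max() + abs(lam) * np.abs(gC).max()
        # one multiplier closes all three first-order conditions
        for Fi, Ci in zip(gF, gC):
            assert abs(Fi + lam * Ci) <= 1e-6 * scale


# -- divergent limit ----------------------------------------------------


def test_wire_limit_symmetric_closed_form():
    x, y = wire_limit_solution(1.0)
    assert x == pytest.approx(math.sqrt(2) - 1, rel=1e-12)
    assert y == pytest.approx(x, rel=1e-12)
    x, y = wire_limit_solution(0.95)
    assert x == pytest.approx(0.4510, abs=1e-4)
    assert y == pytest.approx(0.3785, abs=1e-4)


@pytest.mark.parametrize("family,shape", [("exponential", None),
                                          ("lognormal", 0.3)])
def test_pure_wire_minimization_with_positive_gamma1_diverges(family, shape):
    spec = PrincipleSpec(family=family, shape=shape, f=1.0, gamma1=0.65,
                         r=1.0, theta=0.321, gamma2=1.0)
    res = fit(spec)
    assert res.extremum_class == "divergent-limit"
    assert res.P == 1.0
    fr = res.fractions
    assert fr.g == 0.0 and fr.c == 0.0
    assert fr.s == pytest.approx(fr.x * fr.y, abs=1e-15)
    assert math.isinf(res.mean_spine_volume)


def test_limit_distance_to_data(reference):
    spec = PrincipleSpec(family="gamma_n2", f=1.0, gamma1=2 / 3, r=1.0,
                         theta=0.321, gamma2=1.0)
    d = fit(spec, reference).distance_to(reference)
    assert d.ed == pytest.approx(0.15, abs=0.01)
    assert d.md == pytest.approx(18.5, abs=0.4)


# -- oracle equivalence -------------------------------------------------


@pytest.mark.parametrize("spec", CASES[:2] + CASES[4:7])
def test_grid_oracle_agrees_with_stationarity_solver(spec):
    """Direct constrained optimization (grid + polish), which never sees
    the stationarity equations, lands on the same optimum."""
    m = TissueCompositionModel(spec)
    res = m.fit()
    params, on_boundary = m.grid_search(n_x=80, n_ubar=100)
    assert not on_boundary
    ora = m.composition(*params).as_array()
    sol = res.fractions.as_array()
    np.testing.assert_allclose(ora, sol, atol=1e-3)


def test_oracle_objective_decreases_with_cap_under_positive_gamma1():
    """(r x + y)/ubar^gamma1 keeps improving as the ubar grid cap grows:
    the direct search detects the runaway solution."""
    spec = PrincipleSpec(family="exponential", f=1.0, gamma1=2 / 3, r=1.0,
                         theta=0.321, gamma2=1.0)
    m = TissueCompositionModel(spec)
    vals = []
    for cap in (10.0, 100.0, 1000.0):
        params, on_boundary = m.grid_search(
            n_x=40, n_ubar=60, ubar_range=(0.01, cap), polish=False
        )
        assert on_boundary  # optimum pinned at the ubar cap
        vals.append(m.objective(*params))
    assert vals[0] > vals[1] > vals[2]


# -- extremum classification --------------------------------------------


def test_extremum_classes_match_principles():
    """Spine economy optima are maxima of F_s; wire-volume and mixed
    optima are minima of their fitness."""
    assert fit(SPINE_EXP).extremum_class == "max"
    assert fit(CASES[2]).extremum_class == "max"
    assert fit(WIRE_EXP).extremum_class == "min"
    assert fit(CASES[5]).extremum_class == "min"
    assert fit(CASES[6]).extremum_class == "min"


# -- results object -----------------------------------------------------


def test_summary_and_dict_roundtrip(reference):
    res = fit(SPINE_EXP, reference)
    text = res.summary()
    assert "x (axons)" in text and "MD" in text
    d = res.to_dict()
    assert d["converged"] is True
    assert d["spec"]["family"] == "exponential"
    assert d["x"] == pytest.approx(res.x)
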