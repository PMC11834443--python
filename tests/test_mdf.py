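"""Tests for the max-min driving force module, with a brute-force grid oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepflux.mdf import (
    ConcentrationBounds,
    MDFInfeasibleError,
    PathwayConditions,
    PathwaySpec,
    R_KJ_PER_MOL_K,
    ReactionSpec,
    cumulative_profile,
    driving_force,
    flux_force,
    format_reaction_formula,
    identify_bottlenecks,
    make_bounds_from_measured,
    parse_reaction_formula,
    solve_mdf,
)

RT = R_KJ_PER_MOL_K * 298.15


def simple_pathway(*reactions):
    return PathwaySpec(reactions=tuple(reactions), conditions=PathwayConditions())


def grid_maximin(pathway, bounds, n_points):
    """Brute-force maximin over a log-concentration grid (oracle)."""
    S, mets = pathway.stoichiometric_matrix()
    dg0 = np.array([r.dg0_prime for r in pathway.reactions])
    axes = [
        np.linspace(math.log(bounds.get(m)[0]), math.log(bounds.get(m)[1]), n_points)
        for m in mets
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    X = np.stack([m.ravel() for m in mesh])
    dg = dg0[:, None] + RT * (S @ X)
    half_steps = np.array([(ax[1] - ax[0]) / 2 if len(ax) > 1 else 0.0 for ax in axes])
    resolution = float((RT * np.abs(S) @ half_steps).max())
    return float((-dg).min(axis=0).max()), resolution


def random_instance(rng):
    n_met = int(rng.integers(3, 5))
    n_rxn = 3
    mets = [f"m{i}" for i in range(n_met)]
    reactions = []
    for j in range(n_rxn):
        coeffs = {}
        participants = rng.choice(n_met, size=min(n_met, int(rng.integers(2, 4))),
                                  replace=False)
        for idx, met_idx in enumerate(participants):
            sign = -1 if idx == 0 else 1
            coeffs[mets[met_idx]] = sign * int(rng.integers(1, 3))
        # guarantee both a consumed and a produced species
        if not any(v < 0 for v in coeffs.values()):
            coeffs[mets[participants[0]]] = -abs(coeffs[mets[participants[0]]])
        if not any(v > 0 for v in coeffs.values()):
            coeffs[mets[participants[-1]]] = abs(coeffs[mets[participants[-1]]])
        reactions.append(ReactionSpec(f"r{j}", coeffs, float(rng.uniform(-20, 20))))
    bounds = {}
    for m in mets:
        lo = float(10 ** rng.uniform(-6, -3.5))
        hi = lo * float(10 ** rng.uniform(0.5, 2.5))
        bounds[m] = (lo, hi)
    return simple_pathway(*reactions), ConcentrationBounds(bounds)


class TestDrivingForce:
    def test_standard_state_is_dg0(self):
        rxn = ReactionSpec("r", {"a": -1, "b": 1}, 0.0)
        assert driving_force(rxn, {"a": 1.0, "b": 1.0}) == 0.0

    def test_concentration_ratio_closed_form(self):
        rxn = ReactionSpec("r", {"a": -1, "b": 1}, 0.0)
        dg = driving_force(rxn, {"a": 1e-2, "b": 1e-6}, T=298.15)
        assert dg == pytest.approx(RT * math.log(1e-4), rel=1e-12)
        assert dg == pytest.approx(-22.83, abs=0.01)

    def test_balanced_reaction_scale_invariant(self):
        rxn = ReactionSpec("r", {"a": -1, "b": -1, "c": 1, "d": 1}, -5.0)
        conc = {"a": 1e-3, "b": 2e-4, "c": 5e-5, "d": 8e-3}
        doubled = {k: 2 * v for k, v in conc.items()}
        assert driving_force(rxn, conc) == pytest.approx(driving_force(rxn, doubled), rel=1e-12)

    def test_water_has_unit_activity(self):
        rxn = ReactionSpec("r", {"a": -1, "h2o": -1, "b": 1}, 3.0)
        dg = driving_force(rxn, {"a": 1e-3, "b": 1e-3})
        assert dg == 3.0  # water never enters the concentration term

    def test_missing_or_nonpositive_concentration(self):
        rxn = ReactionSpec("r", {"a": -1, "b": 1}, 0.0)
        with pytest.raises(KeyError):
            driving_force(rxn, {"a": 1e-3})
        with pytest.raises(ValueError):
            driving_force(rxn, {"a": 1e-3, "b": 0.0})


class TestSolveMDF:
    def test_fixed_concentrations_give_zero_mdf(self):
        rxn = ReactionSpec("r", {"a": -1, "b": 1}, 0.0)
        bounds = ConcentrationBounds({"a": (1e-3, 1e-3), "b": (1e-3, 1e-3)})
        sol = solve_mdf(simple_pathway(rxn), bounds)
        assert sol.mdf_B == pytest.approx(0.0, abs=1e-9)
        assert sol.dg_prime["r"] == pytest.approx(0.0, abs=1e-9)
        assert sol.bottlenecks == ["r"]

    def test_single_reaction_closed_form(self):
        rxn = ReactionSpec("r", {"a": -1, "b": 1}, 0.0)
        sol = solve_mdf(simple_pathway(rxn), ConcentrationBounds())
        # best case: substrate at 10 mM, product at 1 uM
        assert sol.mdf_B == pytest.approx(-RT * math.log(1e-4), rel=1e-9)
        assert sol.mdf_B == pytest.approx(22.83, abs=0.01)
        assert sol.concentrations_M["a"] == pytest.approx(1e-2, rel=1e-6)
        assert sol.concentrations_M["b"] == pytest.approx(1e-6, rel=1e-6)

    def test_matches_brute_force_grid_on_random_instances(self, rng):
        for _ in range(10):
            pathway, bounds = random_instance(rng)
            sol = solve_mdf(pathway, bounds)
            b_grid, resolution = grid_maximin(pathway, bounds, n_points=25)
            assert b_grid <= sol.mdf_B + 1e-7  # the grid is a feasible subset
            assert sol.mdf_B - b_grid <= resolution + 1e-7

    def test_widening_bounds_never_decreases_mdf(self, rng):
        for _ in range(5):
            pathway, bounds = random_instance(rng)
            base = solve_mdf(pathway, bounds).mdf_B
            for met in pathway.metabolites:
                widened = solve_mdf(pathway, bounds.widened(met, 3.0)).mdf_B
                assert widened >= base - 1e-9

    def test_infeasible_bounds_raise(self):
        rxn = ReactionSpec("r", {"a": -1, "b": 1}, 0.0)
        pathway = simple_pathway(rxn)
        with pytest.raises(ValueError):
            ConcentrationBounds({"a": (1e-3, 1e-4)})
        with pytest.raises(MDFInfeasibleError):
            solve_mdf(
                pathway,
                ConcentrationBounds({"a": (1e-3, 1e-3), "b": (1e-3, 1e-3)}),
                ratio_constraints=[("a", "b", 10.0)],
            )

    def test_log_concentrations_respect_bounds(self, rng):
        pathway, bounds = random_instance(rng)
        sol = solve_mdf(pathway, bounds)
        for met, x in sol.log_conc.items():
            lo, hi = bounds.get(met)
            assert math.log(lo) - 1e-9 <= x <= math.log(hi) + 1e-9

    def test_ratio_constraint_enforced(self):
        rxn = ReactionSpec("r", {"a": -1, "b": 1}, 0.0)
        sol = solve_mdf(simple_pathway(rxn), ConcentrationBounds(),
                        ratio_constraints=[("a", "b", 100.0)])
        ratio = sol.concentrations_M["a"] / sol.concentrations_M["b"]
        assert ratio == pytest.approx(100.0, rel=1e-6)
        assert sol.mdf_B == pytest.approx(-RT * math.log(1e-2), rel=1e-6)


class TestBottlenecksAndProfile:
    def test_unique_and_tied_bottlenecks(self):
        # two isolated A->B style reactions with different dg0: the larger
        # dg0 limits; equal dg0 ties.
        r1 = ReactionSpec("r1", {"a": -1, "b": 1}, 0.0)
        r2 = ReactionSpec("r2", {"c": -1, "d": 1}, 10.0)
        bounds = ConcentrationBounds({m: (1e-3, 1e-3) for m in "abcd"})
        sol = solve_mdf(simple_pathway(r1, r2), bounds)
        assert sol.mdf_B == pytest.approx(-10.0, abs=1e-9)
        assert sol.bottlenecks == ["r2"]
        r2_equal = ReactionSpec("r2", {"c": -1, "d": 1}, 0.0)
        sol = solve_mdf(simple_pathway(r1, r2_equal), bounds)
        assert sol.bottlenecks == ["r1", "r2"]

    def test_identify_bottlenecks_tolerance(self):
        r1 = ReactionSpec("r1", {"a": -1, "b": 1}, 0.0)
        r2 = ReactionSpec("r2", {"c": -1, "d": 1}, 0.05)
        bounds = ConcentrationBounds({m: (1e-3, 1e-3) for m in "abcd"})
        sol = solve_mdf(simple_pathway(r1, r2), bounds)
        assert identify_bottlenecks(sol, tol=0.001) == ["r2"]
        assert identify_bottlenecks(sol, tol=0.1) == ["r1", "r2"]

    def test_cumulative_profile_values(self):
        r1 = ReactionSpec("r1", {"a": -1, "b": 1}, -3.0)
        r2 = ReactionSpec("r2", {"b": -1, "c": 1}, -1.0)
        bounds = ConcentrationBounds({m: (1e-3, 1e-3) for m in "abc"})
        pathway = simple_pathway(r1, r2)
        sol = solve_mdf(pathway, bounds)
        opt, ref = cumulative_profile(sol, pathway)
        np.testing.assert_allclose(opt, [-3.0, -4.0], atol=1e-9)
        np.testing.assert_allclose(ref, [-3.0, -4.0], atol=1e-9)  # 1 mM = the fixed conc

    def test_total_cumulative_independent_of_intermediates(self, rng):
        # a linear chain: the telescoping sum depends only on the endpoints
        r1 = ReactionSpec("r1", {"a": -1, "b": 1}, -3.0)
        r2 = ReactionSpec("r2", {"b": -1, "c": 1}, 5.0)
        r3 = ReactionSpec("r3", {"c": -1, "d": 1}, -1.0)
        totals = []
        for _ in range(5):
            conc = {"a": 2e-3, "d": 1e-5,
                    "b": float(10 ** rng.uniform(-6, -2)),
                    "c": float(10 ** rng.uniform(-6, -2))}
            total = sum(driving_force(r, conc) for r in (r1, r2, r3))
            totals.append(total)
        np.testing.assert_allclose(totals, totals[0], atol=1e-9)


class TestBoundsFromMeasured:
    def test_percent_interpretation(self):
        b = make_bounds_from_measured({"x": 1e-3}, {"x": 40.0})
        assert b.get("x") == (pytest.approx(0.6e-3), pytest.approx(1.4e-3))

    def test_zero_percent_fixes_concentration(self):
        b = make_bounds_from_measured({"x": 1e-3}, {"x": 0.0})
        assert b.get("x") == (pytest.approx(1e-3), pytest.approx(1e-3))

    def test_hundred_percent_clips_lower_bound(self):
        # a 4 mM pool with 100% variation spans ~0 to 8 mM
        b = make_bounds_from_measured({"atp": 4e-3}, {"atp": 100.0}, floor_M=1e-9)
        lo, hi = b.get("atp")
        assert lo == pytest.approx(1e-9)
        assert hi == pytest.approx(8e-3)

    def test_unmeasured_metabolites_get_default(self):
        b = make_bounds_from_measured({"x": 1e-3}, 40.0)
        assert b.get("y") == (1e-6, 1e-2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_bounds_from_measured({"x": -1e-3}, 40.0)
        with pytest.raises(ValueError):
            make_bounds_from_measured({"x": 1e-3}, 250.0)


class TestFluxForce:
    def test_equilibrium(self):
        r = flux_force(0.0)
        assert r.net_ratio == 0.0
        assert r.forward_ratio == pytest.approx(0.5)
        assert r.reverse_ratio == pytest.approx(0.5)

    def test_moderate_driving_force_net_ratio(self):
        # at dG = -2.97 kJ/mol the net flux is ~54% of gross flux
        assert flux_force(-2.97).net_ratio == pytest.approx(0.54, abs=0.005)

    def test_near_equilibrium_value(self):
        # independent scalar evaluation of the printed formula at -0.27 kJ/mol
        x = math.exp(0.27 / RT)
        assert flux_force(-0.27).net_ratio == pytest.approx((x - 1) / (x + 1), rel=1e-12)
        assert flux_force(-0.27).net_ratio == pytest.approx(0.0544, abs=2e-4)

    @settings(derandomize=True, max_examples=100)
    @given(dg=st.floats(-60.0, 60.0), T=st.floats(250.0, 330.0))
    def test_identities(self, dg, T):
        r = flux_force(dg, T=T)
        assert r.forward_ratio + r.reverse_ratio == pytest.approx(1.0, abs=1e-12)
        assert r.net_ratio == pytest.approx(r.forward_ratio - r.reverse_ratio, abs=1e-12)
        assert r.net_ratio == pytest.approx(
            math.tanh(-dg / (2 * R_KJ_PER_MOL_K * T)), abs=1e-12
        )
        if dg != 0:
            assert math.copysign(1, r.net_ratio) == -math.copysign(1, dg)
        assert -1.0 <= r.net_ratio <= 1.0


class TestFormulaGrammar:
    @pytest.mark.parametrize("formula,expected", [
        ("a = b", {"a": -1.0, "b": 1.0}),
        ("2 pyruvate + atp = oaa + adp", {"pyruvate": -2.0, "atp": -1.0, "oaa": 1.0, "adp": 1.0}),
        ("pep + h2o = 2pg", {"pep": -1.0, "h2o": -1.0, "2pg": 1.0}),
    ])
    def test_parse(self, formula, expected):
        assert parse_reaction_formula(formula) == expected

    def test_roundtrip(self):
        stoich = {"pyruvate": -2.0, "atp": -1.0, "oaa": 1.0, "adp": 1.0}
        assert parse_reaction_formula(format_reaction_formula(stoich)) == stoich

    def test_malformed(self):
        with pytest.raises(ValueError):
            parse_reaction_formula("a + b")
        with pytest.raises(ValueError):
            parse_reaction_formula("a = = b")

    def test_reaction_needs_both_sides(self):
        with pytest.raises(ValueError):
            ReactionSpec("r", {"a": -1.0}, 0.0)
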