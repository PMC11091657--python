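"""FBA / pFBA / LAD correctness, solver cross-checks and LP invariants."""

import numpy as np
import pytest

from gabaflux.flux_analysis import (
    LadReferences,
    condition_references,
    fba,
    lad_fit,
    pfba,
    read_solution,
    simulate_condition,
    write_solution,
)
from gabaflux.model_core import (
    KnockoutSpec,
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_knockouts,
)
from gabaflux.synthetic_data import EXCHANGE_MAPPING, MEASURED_RATES, measured_constraints

from conftest import make_chain_model, random_small_model

MASS_TOL = 1e-6


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------


def test_fba_bottleneck_is_uptake_bound(chain_model):
    sol = fba(chain_model, objective="EX_C", sense="max")
    assert sol.optimal
    assert sol.objective_value == pytest.approx(10.0, abs=1e-9)
    assert sol.flux("EX_A") == pytest.approx(-10.0, abs=1e-9)
    assert sol.mass_balance_residual(chain_model) <= MASS_TOL


def test_fba_severed_path_gives_zero(chain_model):
    cut = apply_knockouts(chain_model, KnockoutSpec(reaction_ids={"R1"}))
    sol = fba(cut, objective="EX_C")
    assert sol.optimal
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


def test_fba_growth_matches_constrained_value(strain):
    """Pinning the measured neutral-row rates fixes growth at the measured mu."""
    constraints = measured_constraints("neutral-2gl")
    from gabaflux.model_core import set_exchange_bounds

    pinned = set_exchange_bounds(strain, constraints, EXCHANGE_MAPPING, mode="hard", tol=1e-9)
    pinned = pinned.with_bounds(
        {"BIOMASS": (constraints.growth_rate - 1e-9, constraints.growth_rate + 1e-9)}
    )
    for backend in ("highs", "glpk"):
        sol = fba(pinned, objective="BIOMASS", backend=backend)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(0.221086, abs=1e-6)


def test_fba_infeasible_status():
    # one metabolite produced with no consumer and forced production
    model = MetabolicModel(
        "bad", [Metabolite("a", compartment="c")],
        [Reaction("R", {"a": 1}, lower_bound=1, upper_bound=2)],
        objective_reaction_id="R",
    )
    sol = fba(model)
    assert sol.status == "infeasible"
    assert sol.fluxes == {}


# ---------------------------------------------------------------------------
# pFBA
# ---------------------------------------------------------------------------


def test_pfba_chain_total_flux():
    sol = pfba(make_chain_model(), objective="EX_C")
    assert sol.optimal
    assert sol.objective_value == pytest.approx(40.0, abs=1e-8)
    assert sol.meta["fba_objective"] == pytest.approx(10.0, abs=1e-9)


def test_pfba_parallel_routes_share_minimal_total():
    """A duplicated A->B step leaves total |v| at 40, however split."""
    base = make_chain_model()
    rxns = list(base.reactions) + [
        Reaction("R1b", {"A": -1, "B": 1}, lower_bound=0, upper_bound=1000)
    ]
    model = MetabolicModel("par", base.metabolites, rxns, objective_reaction_id="EX_C")
    sol = pfba(model, objective="EX_C")
    assert sol.objective_value == pytest.approx(40.0, abs=1e-8)
    assert sol.flux("R1") + sol.flux("R1b") == pytest.approx(10.0, abs=1e-8)


def test_pfba_suppresses_internal_cycle():
    """A balanced B<->D loop adds |v| without profit, so pFBA zeroes it."""
    base = make_chain_model()
    mets = list(base.metabolites) + [Metabolite("D", compartment="c")]
    rxns = list(base.reactions) + [
        Reaction("CYC1", {"B": -1, "D": 1}, lower_bound=-1000, upper_bound=1000),
        Reaction("CYC2", {"D": -1, "B": 1}, lower_bound=-1000, upper_bound=1000),
    ]
    model = MetabolicModel("cyc", mets, rxns, objective_reaction_id="EX_C")
    sol = pfba(model, objective="EX_C")
    assert abs(sol.flux("CYC1")) <= 1e-8
    assert abs(sol.flux("CYC2")) <= 1e-8
    assert sol.objective_value == pytest.approx(40.0, abs=1e-8)


def test_pfba_optimum_fraction_validates():
    with pytest.raises(ValueError):
        pfba(make_chain_model(), optimum_fraction=0.0)


# ---------------------------------------------------------------------------
# LAD
# ---------------------------------------------------------------------------


def test_lad_feasible_reference_reproduced(chain_model):
    sol = lad_fit(chain_model, LadReferences({"EX_C": 5.0}))
    assert sol.optimal
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
    assert sol.flux("EX_C") == pytest.approx(5.0, abs=1e-8)


def test_lad_clamps_to_polytope_boundary():
    """An out-of-reach reference is met at the nearest feasible point (L1)."""
    model = make_chain_model(ex_c_upper=10.0)
    sol = lad_fit(model, LadReferences({"EX_C": 15.0}))
    assert sol.flux("EX_C") == pytest.approx(10.0, abs=1e-8)
    assert sol.objective_value == pytest.approx(5.0, abs=1e-8)


def test_lad_weights_scale_residual(chain_model):
    heavy = lad_fit(chain_model, LadReferences({"EX_C": (15.0, 3.0)}))
    light = lad_fit(chain_model, LadReferences({"EX_C": (15.0, 1.0)}))
    assert heavy.objective_value == pytest.approx(3 * light.objective_value, rel=1e-9)


def test_lad_on_measured_row_reaches_zero_residual(strain):
    refs = condition_references(strain, measured_constraints("acidic-2gl"), EXCHANGE_MAPPING)
    sol = lad_fit(strain, refs)
    assert sol.objective_value == pytest.approx(0.0, abs=1e-8)
    assert sol.flux("EX_4abut_e") == pytest.approx(0.177000, abs=1e-7)


def test_lad_requires_references(chain_model):
    with pytest.raises(ValueError):
        lad_fit(chain_model, LadReferences({}))


def test_lad_zero_residual_iff_reference_feasible(chain_model):
    """Residual vanishes exactly when the reference lies in the flux polytope."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        target = float(rng.uniform(-5, 20))
        sol = lad_fit(chain_model, LadReferences({"EX_C": target}))
        feasible = 0.0 <= target <= 10.0
        if feasible:
            assert sol.objective_value <= 1e-8
        else:
            assert sol.objective_value > 1e-6


def test_lad_monotone_under_bound_tightening():
    """Shrinking the polytope can only hold or raise the L1 residual."""
    residuals = [
        lad_fit(make_chain_model(ex_c_upper=ub), LadReferences({"EX_C": 15.0})).objective_value
        for ub in (12.0, 10.0, 6.0, 2.0)
    ]
    assert residuals == sorted(residuals)


def test_lad_and_pfba_scale_invariance(chain_model):
    """Scaling all bounds and references by k scales every flux by k."""
    k = 3.7
    scaled = chain_model.with_bounds(
        {r.id: (k * r.lower_bound, k * r.upper_bound) for r in chain_model.reactions}
    )
    base = lad_fit(chain_model, LadReferences({"EX_C": 15.0}))
    big = lad_fit(scaled, LadReferences({"EX_C": 15.0 * k}))
    for rxn_id, flux in base.fluxes.items():
        assert big.flux(rxn_id) == pytest.approx(k * flux, abs=1e-7)


# ---------------------------------------------------------------------------
# Cross-backend agreement (independent LP implementations)
# ---------------------------------------------------------------------------


def test_backends_agree_on_random_small_models():
    """HiGHS and GLPK agree on FBA/pFBA/LAD objectives for 100+ random models."""
    rng = np.random.default_rng(2024)
    checked = 0
    while checked < 100:
        model = random_small_model(rng)
        sols = {b: fba(model, backend=b) for b in ("highs", "glpk")}
        assert sols["highs"].status == sols["glpk"].status
        if sols["highs"].status != "optimal":
            continue
        assert sols["highs"].objective_value == pytest.approx(
            sols["glpk"].objective_value, abs=1e-6
        )
        p = {b: pfba(model, backend=b) for b in ("highs", "glpk")}
        assert p["highs"].status == p["glpk"].status == "optimal"
        assert p["highs"].objective_value == pytest.approx(p["glpk"].objective_value, abs=1e-6)
        ref_rxn = model.reaction_ids[int(rng.integers(len(model.reactions)))]
        refs = LadReferences({ref_rxn: float(rng.uniform(-8, 8))})
        l = {b: lad_fit(model, refs, backend=b) for b in ("highs", "glpk")}
        assert l["highs"].status == l["glpk"].status == "optimal"
        assert l["highs"].objective_value == pytest.approx(l["glpk"].objective_value, abs=1e-6)
        checked += 1


def test_mass_balance_on_all_optimal_solutions(condition_solutions, strain):
    for label, sol in condition_solutions.items():
        assert sol.optimal, label
        assert sol.mass_balance_residual(strain) <= MASS_TOL


# ---------------------------------------------------------------------------
# simulate_condition
# ---------------------------------------------------------------------------


def test_strategies_agree_when_references_feasible(strain):
    """With jointly feasible measurements, LAD is a no-op and both strategies match."""
    constraints = measured_constraints("neutral-2gl")
    a = simulate_condition(strain, constraints, EXCHANGE_MAPPING, strategy="lad-then-pfba")
    b = simulate_condition(strain, constraints, EXCHANGE_MAPPING, strategy="hard-pfba")
    assert a.optimal and b.optimal
    assert a.objective_value == pytest.approx(b.objective_value, abs=1e-6)
    for rxn_id, pinned in a.meta["pinned"].items():
        assert b.meta["pinned"][rxn_id] == pytest.approx(pinned, abs=1e-6)


def test_infeasible_measurements_absorbed_by_lad(strain):
    """A deliberately impossible rate vector still yields an optimal solution."""
    broken = measured_constraints("neutral-2gl")
    broken.rates["glutamate"] = (50.0, "secretion")  # far beyond the carbon supply
    sol = simulate_condition(strain, broken, EXCHANGE_MAPPING, strategy="lad-then-pfba")
    assert sol.optimal
    assert sol.meta["lad_residual"] > 1e-3


@pytest.mark.parametrize("label,growth", [(k, v["growth_rate"]) for k, v in MEASURED_RATES.items()])
def test_simulated_growth_reproduces_measured(condition_solutions, label, growth):
    sol = condition_solutions[label]
    assert sol.flux("BIOMASS") == pytest.approx(growth, abs=1e-6)
    assert sol.meta["lad_residual"] == pytest.approx(0.0, abs=1e-8)


def test_knocked_reactions_carry_zero_flux(condition_solutions):
    for sol in condition_solutions.values():
        assert abs(sol.flux("AKGDH")) <= 1e-9
        assert abs(sol.flux("ABTA")) <= 1e-9


def test_solution_round_trips_through_files(condition_solutions, tmp_path):
    sol = condition_solutions["acidic-2gl"]
    write_solution(sol, tmp_path / "f.tsv", tmp_path / "f.json")
    back = read_solution(tmp_path / "f.tsv", tmp_path / "f.json")
    assert back.status == "optimal"
    for rxn_id, flux in sol.fluxes.items():
        assert back.flux(rxn_id) == pytest.approx(flux, abs=1e-9)
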