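"""Model representation, I/O round-trips, GPR evaluation and knockouts."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gabaflux.model_core import (
    KnockoutSpec,
    Metabolite,
    MetabolicModel,
    ModelFormatError,
    Reaction,
    UnknownIdError,
    apply_knockouts,
    evaluate_gpr,
    load_model,
    parse_gpr,
    set_exchange_bounds,
    signed_rate,
    write_model,
)
from gabaflux.fermentation_rates import ConditionConstraints
from gabaflux.synthetic_data import EXCHANGE_MAPPING, measured_constraints


# ---------------------------------------------------------------------------
# GPR parsing and evaluation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "rule,knocked,active",
    [
        ("g1 and g2", {"g1"}, False),
        ("g1 or g2", {"g1"}, True),
        ("g1 or g2", {"g1", "g2"}, False),
        ("g1 and (g2 or g3)", {"g3"}, True),
        ("g1 and (g2 or g3)", {"g2", "g3"}, False),
        ("(g1 and g2) or (g1 and g3)", {"g2"}, True),
        ("sucA and sucB and lpdA", {"sucA"}, False),
        ("", set(), True),
    ],
)
def test_gpr_semantics(rule, knocked, active):
    """AND = enzyme complex (all subunits), OR = isozymes (any one)."""
    assert evaluate_gpr(parse_gpr(rule), knocked) is active


def test_gpr_round_trips_through_text():
    rule = "gadA or (gadB and gadC)"
    expr = parse_gpr(rule)
    assert parse_gpr(expr.to_string()) == expr
    assert expr.genes() == {"gadA", "gadB", "gadC"}


@pytest.mark.parametrize("bad", ["g1 and", "(g1 or g2", "and g1", "g1 g2 or"])
def test_malformed_gpr_rejected(bad):
    with pytest.raises(ModelFormatError):
        parse_gpr(bad)


@st.composite
def gpr_trees(draw, depth=0):
    genes = [f"g{i}" for i in range(6)]
    if depth >= 3 or draw(st.booleans()):
        from gabaflux.model_core import GprExpression

        return GprExpression("gene", (draw(st.sampled_from(genes)),))
    from gabaflux.model_core import GprExpression

    op = draw(st.sampled_from(["and", "or"]))
    children = draw(st.lists(gpr_trees(depth=depth + 1), min_size=2, max_size=3))
    return GprExpression(op, tuple(children))


@settings(max_examples=200, derandomize=True)
@given(expr=gpr_trees(), knocked=st.sets(st.sampled_from([f"g{i}" for i in range(6)])))
def test_gpr_matches_boolean_eval_oracle(expr, knocked):
    """Tree evaluation agrees with Python's own boolean evaluation of the rule."""
    text = expr.to_string()
    for gene in sorted(expr.genes(), key=len, reverse=True):
        text = text.replace(gene, str(gene not in knocked))
    assert evaluate_gpr(expr, knocked) is eval(text)


# ---------------------------------------------------------------------------
# JSON / SBML round-trips
# ---------------------------------------------------------------------------


def test_bigg_json_round_trip_is_bit_identical(toy_model, tmp_path):
    first, second = tmp_path / "a.json", tmp_path / "b.json"
    write_model(toy_model, first)
    write_model(load_model(first), second)
    assert first.read_bytes() == second.read_bytes()


def test_sbml_round_trip_preserves_structure(toy_model, tmp_path):
    path = tmp_path / "toy.xml"
    write_model(toy_model, path, format="sbml")
    back = load_model(path, format="sbml")
    assert len(back.metabolites) == len(toy_model.metabolites)
    assert back.reaction_ids == toy_model.reaction_ids
    assert sorted(back.genes) == sorted(toy_model.genes)
    assert back.objective_reaction_id == toy_model.objective_reaction_id
    for rxn in toy_model.reactions:
        other = back.reaction(rxn.id)
        assert other.stoichiometry == pytest.approx(rxn.stoichiometry)
        assert (other.lower_bound, other.upper_bound) == (rxn.lower_bound, rxn.upper_bound)
        assert (other.gpr is None) == (rxn.gpr is None)
        if rxn.gpr is not None:
            assert other.gpr.genes() == rxn.gpr.genes()


def test_hand_written_json_transcribes_exactly(tmp_path):
    doc = {
        "id": "mini",
        "metabolites": [{"id": "a_c", "compartment": "c"}, {"id": "b_c", "compartment": "c"}],
        "reactions": [
            {"id": "EX_a", "metabolites": {"a_c": -1}, "lower_bound": -3, "upper_bound": 0},
            {"id": "R", "metabolites": {"a_c": -1, "b_c": 2}, "lower_bound": 0,
             "upper_bound": 5, "objective_coefficient": 1},
            {"id": "EX_b", "metabolites": {"b_c": -1}, "lower_bound": 0, "upper_bound": 10},
        ],
        "genes": [],
    }
    path = tmp_path / "mini.json"
    path.write_text(json.dumps(doc))
    model = load_model(path)
    S = model.stoichiometric_matrix()
    assert S.shape == (2, 3)
    np.testing.assert_array_equal(S, [[-1, -1, 0], [0, 2, -1]])
    assert model.objective_reaction_id == "R"


def test_unreadable_file_raises_format_error(tmp_path):
    bad = tmp_path / "bad.json"
    bad.write_text("{not json")
    with pytest.raises(ModelFormatError, match="bad.json"):
        load_model(bad)


def test_missing_objective_is_explicit(tmp_path):
    model = MetabolicModel(
        "noobj", [Metabolite("a", compartment="c")],
        [Reaction("EX_a", {"a": -1}, lower_bound=-1)],
    )
    from gabaflux.model_core import NoObjectiveError

    with pytest.raises(NoObjectiveError):
        model.objective_reaction()


# ---------------------------------------------------------------------------
# Knockouts
# ---------------------------------------------------------------------------


def test_reaction_knockouts_zero_bounds(toy_model):
    knocked = apply_knockouts(toy_model, KnockoutSpec(reaction_ids={"AKGDH", "ABTA"}))
    for rxn_id in ("AKGDH", "ABTA"):
        rxn = knocked.reaction(rxn_id)
        assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 0.0)
    # every other bound untouched, input not mutated
    for rxn in toy_model.reactions:
        if rxn.id not in ("AKGDH", "ABTA"):
            other = knocked.reaction(rxn.id)
            assert (other.lower_bound, other.upper_bound) == (rxn.lower_bound, rxn.upper_bound)
    assert toy_model.reaction("AKGDH").upper_bound > 0


def test_gene_and_reaction_knockouts_agree(toy_model):
    """Deleting the sucA/gabT loci disables exactly AKGDH and ABTA."""
    by_gene = apply_knockouts(toy_model, KnockoutSpec(gene_ids={"sucA", "gabT"}))
    by_rxn = apply_knockouts(toy_model, KnockoutSpec(reaction_ids={"AKGDH", "ABTA"}))
    zeroed = lambda m: {r.id for r in m.reactions if r.lower_bound == r.upper_bound == 0}
    assert zeroed(by_gene) == zeroed(by_rxn) == {"AKGDH", "ABTA"}


def test_knockouts_idempotent_and_noop_cases(toy_model):
    spec = KnockoutSpec(gene_ids={"sucA", "gabT"})
    once = apply_knockouts(toy_model, spec)
    twice = apply_knockouts(once, spec)
    assert [r.lower_bound for r in once.reactions] == [r.lower_bound for r in twice.reactions]
    assert [r.upper_bound for r in once.reactions] == [r.upper_bound for r in twice.reactions]

    empty = apply_knockouts(toy_model, KnockoutSpec())
    assert [(r.lower_bound, r.upper_bound) for r in empty.reactions] == [
        (r.lower_bound, r.upper_bound) for r in toy_model.reactions
    ]
    # a gene carried by the model but absent from the targeted complexes
    unused = apply_knockouts(toy_model, KnockoutSpec(gene_ids={"ppc"}))
    assert unused.reaction("PPC").upper_bound == 0  # ppc IS used by PPC
    isozyme = apply_knockouts(toy_model, KnockoutSpec(gene_ids={"pykA"}))
    assert isozyme.reaction("PYK").upper_bound > 0  # pykF still carries it


def test_knockout_of_gene_outside_all_gprs_is_noop():
    model = MetabolicModel(
        "m", [Metabolite("a", compartment="c")],
        [Reaction("EX_a", {"a": -1}, lower_bound=-1)],
        genes=["orphan"],
    )
    out = apply_knockouts(model, KnockoutSpec(gene_ids={"orphan"}))
    assert (out.reaction("EX_a").lower_bound, out.reaction("EX_a").upper_bound) == (-1, 1000.0)


def test_unknown_knockout_ids_listed():
    model = MetabolicModel(
        "m", [Metabolite("a", compartment="c")],
        [Reaction("EX_a", {"a": -1}, lower_bound=-1)],
    )
    with pytest.raises(UnknownIdError, match="nope"):
        apply_knockouts(model, KnockoutSpec(reaction_ids={"nope"}))
    with pytest.raises(UnknownIdError, match="ghost"):
        apply_knockouts(model, KnockoutSpec(gene_ids={"ghost"}))


def test_knockout_set_matches_brute_force_gpr_scan(toy_model):
    """Zero-bounded reactions equal an independent per-reaction GPR scan."""
    spec = KnockoutSpec(gene_ids={"sucA", "gabT", "pta", "zwf"})
    knocked = apply_knockouts(toy_model, spec)
    zeroed = {r.id for r in knocked.reactions if r.lower_bound == r.upper_bound == 0}
    expected = set()
    for rxn in toy_model.reactions:
        if rxn.gpr is None:
            continue
        text = rxn.gpr.to_string()
        for gene in sorted(rxn.gpr.genes(), key=len, reverse=True):
            text = text.replace(gene, str(gene not in spec.gene_ids))
        if not eval(text):
            expected.add(rxn.id)
    assert zeroed == expected


# ---------------------------------------------------------------------------
# Exchange bounds
# ---------------------------------------------------------------------------


def test_hard_exchange_bounds_follow_sign_convention(toy_model):
    constraints = measured_constraints("acidic-2gl")
    pinned = set_exchange_bounds(toy_model, constraints, EXCHANGE_MAPPING, mode="hard")
    glc = pinned.reaction("EX_glc__D_e")
    assert (glc.lower_bound, glc.upper_bound) == (-1.201905, -1.201905)
    gaba = pinned.reaction("EX_4abut_e")
    assert (gaba.lower_bound, gaba.upper_bound) == (0.177, 0.177)


def test_exchange_bounds_tolerance_and_reference_mode(toy_model):
    constraints = measured_constraints("neutral-2gl")
    widened = set_exchange_bounds(toy_model, constraints, EXCHANGE_MAPPING, mode="hard", tol=0.1)
    glc = widened.reaction("EX_glc__D_e")
    assert glc.lower_bound == pytest.approx(-1.906954)
    assert glc.upper_bound == pytest.approx(-1.706954)

    untouched = set_exchange_bounds(toy_model, constraints, EXCHANGE_MAPPING, mode="reference-only")
    assert [(r.lower_bound, r.upper_bound) for r in untouched.reactions] == [
        (r.lower_bound, r.upper_bound) for r in toy_model.reactions
    ]


def test_empty_constraints_change_nothing(toy_model):
    empty = ConditionConstraints(growth_rate=0.1, rates={})
    out = set_exchange_bounds(toy_model, empty, EXCHANGE_MAPPING, mode="hard")
    assert [(r.lower_bound, r.upper_bound) for r in out.reactions] == [
        (r.lower_bound, r.upper_bound) for r in toy_model.reactions
    ]


def test_unmapped_species_is_named(toy_model):
    constraints = ConditionConstraints(growth_rate=0.1, rates={"xylose": (1.0, "uptake")})
    with pytest.raises(UnknownIdError, match="xylose"):
        set_exchange_bounds(toy_model, constraints, EXCHANGE_MAPPING, mode="hard")


@pytest.mark.parametrize(
    "magnitude,direction,expected",
    [(1.8, "uptake", -1.8), (0.177, "secretion", 0.177), (0.0, "uptake", 0.0)],
)
def test_signed_rate_convention(magnitude, direction, expected):
    assert signed_rate(magnitude, direction) == expected
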