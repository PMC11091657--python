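import numpy as np
import pytest

from gabaflux.model_core import MetabolicModel, Metabolite, Reaction, apply_knockouts
from gabaflux.synthetic_data import (
    ENGINEERED_REACTION_KNOCKOUTS,
    build_toy_core,
)


def make_chain_model(ex_c_upper: float = 1000.0) -> MetabolicModel:
    """Linear pathway A -> B -> C with uptake capped at 10 mmol/gDCW/h.

    EX_A (lb -10) -> R1: A->B -> R2: B->C -> EX_C.  The unique optimal
    EX_C-maximising flux runs every step at 10.
    """
    mets = [Metabolite("A", compartment="c"), Metabolite("B", compartment="c"),
            Metabolite("C", compartment="c")]
    rxns = [
        Reaction("EX_A", {"A": -1}, lower_bound=-10, upper_bound=0),
        Reaction("R1", {"A": -1, "B": 1}, lower_bound=0, upper_bound=1000),
        Reaction("R2", {"B": -1, "C": 1}, lower_bound=0, upper_bound=1000),
        Reaction("EX_C", {"C": -1}, lower_bound=0, upper_bound=ex_c_upper),
    ]
    return MetabolicModel("chain", mets, rxns, objective_reaction_id="EX_C")


def random_small_model(rng: np.random.Generator) -> MetabolicModel:
    """Random stoichiometric model with <= 12 reactions for solver cross-checks."""
    n_mets = int(rng.integers(2, 6))
    n_internal = int(rng.integers(2, 8))
    mets = [Metabolite(f"m{i}", compartment="c") for i in range(n_mets)]
    rxns = []
    for j in range(n_internal):
        k = int(rng.integers(2, min(4, n_mets) + 1))
        picked = rng.choice(n_mets, size=k, replace=False)
        coeffs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=k)
        stoich = {f"m{i}": float(c) for i, c in zip(picked, coeffs)}
        reversible = rng.random() < 0.5
        rxns.append(
            Reaction(f"r{j}", stoich,
                     lower_bound=-10.0 if reversible else 0.0, upper_bound=10.0)
        )
    # exchanges keep most random networks from being trivially flux-free
    for i in range(n_mets):
        if rng.random() < 0.7 and len(rxns) < 12:
            rxns.append(Reaction(f"EX_m{i}", {f"m{i}": -1},
                                 lower_bound=-5.0, upper_bound=5.0))
    objective = str(rng.choice([r.id for r in rxns]))
    return MetabolicModel("random", mets, rxns, objective_reaction_id=objective)


@pytest.fixture(scope="session")
def toy_model():
    return build_toy_core()


@pytest.fixture(scope="session")
def strain(toy_model):
    """Toy model with the engineered AKGDH/ABTA knockouts applied."""
    return apply_knockouts(toy_model, ENGINEERED_REACTION_KNOCKOUTS)


@pytest.fixture(scope="session")
def condition_solutions(strain):
    """simulate_condition output for all three measured-rate rows."""
    from gabaflux.flux_analysis import simulate_condition
    from gabaflux.synthetic_data import EXCHANGE_MAPPING, MEASURED_RATES, measured_constraints

    return {
        label: simulate_condition(strain, measured_constraints(label), EXCHANGE_MAPPING)
        for label in MEASURED_RATES
    }


@pytest.fixture
def chain_model():
    return make_chain_model()
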