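"""Synthetic inputs: a hand-curated toy central-carbon network and batch profiles.

The toy network (``toy_core_gaba``) covers the pathways that matter for a
GABA-secreting *E. coli* knockout strain: glycolysis (PTS entry), the
oxidative and non-oxidative pentose phosphate pathway, the full TCA cycle
with the glyoxylate shunt, the acetate fermentation branch (PTAr/ACKr), the
GABA shunt (GLUDy → GLUDC → ABTA → SSALy) and a lumped biomass reaction.
Every internal reaction is elementally balanced (the lumped biomass drain is
exempt); respiration and transhydrogenation are lumped so that energy and
redox never dominate the carbon constraints.

The curated stoichiometry lives in this module as a literal table so that
worked-example fluxes are stable across releases; ``build_toy_core`` verifies
at build time that, with the strain's AKGDH/ABTA knockouts applied, each of
the three measured-rate vectors (the three culture conditions) is a feasible
point of the flux polytope.

Batch profiles are generated from closed-form exponential trajectories
(X = X₀·e^{μt}; concentrations linear in biomass), so the rate estimator has
an exact analytic target; measurement error is multiplicative lognormal.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fermentation_rates import (
    DEFAULT_BIOMASS_FACTOR,
    MOLAR_MASSES,
    ConditionConstraints,
    FermentationProfile,
)
from .flux_analysis import fba
from .model_core import (
    KnockoutSpec,
    Metabolite,
    MetabolicModel,
    Reaction,
    apply_knockouts,
    check_mass_balance,
    parse_gpr,
    set_exchange_bounds,
)

__all__ = [
    "ToySpec",
    "ProfileSpec",
    "ToyBuildError",
    "MEASURED_RATES",
    "EXCHANGE_MAPPING",
    "TOY_PATHWAYS",
    "ENGINEERED_REACTION_KNOCKOUTS",
    "ENGINEERED_GENE_KNOCKOUTS",
    "BIOMASS_ID",
    "build_toy_core",
    "measured_constraints",
    "generate_profile",
    "generate_phased_profile",
    "profile_spec_for_condition",
]


class ToyBuildError(RuntimeError):
    """The toy fixture failed one of its build-time validity checks."""


# ---------------------------------------------------------------------------
# Measured exchange rates and growth for the three culture conditions
# (magnitudes in mmol/gDCW/h, growth in 1/h; substrates are uptaken,
# products secreted).
# ---------------------------------------------------------------------------

MEASURED_RATES: dict[str, dict[str, float]] = {
    "neutral-2gl": {
        "glucose": 1.806954,
        "succinate": 0.086198,
        "gaba": 0.008443,
        "glutamate": 1.021887,
        "acetate": 0.306986,
        "growth_rate": 0.221086,
    },
    "acidic-2gl": {
        "glucose": 1.201905,
        "succinate": 0.272554,
        "gaba": 0.177000,
        "glutamate": 0.611939,
        "acetate": 0.000000,
        "growth_rate": 0.140696,
    },
    "acidic-4gl": {
        "glucose": 1.8382,
        "succinate": 1.785084,
        "gaba": 0.2756,
        "glutamate": 0.773662,
        "acetate": 0.000000,
        "growth_rate": 0.188196,
    },
}

SPECIES_DIRECTIONS = {
    "glucose": "uptake",
    "succinate": "uptake",
    "gaba": "secretion",
    "glutamate": "secretion",
    "acetate": "secretion",
}

#: measured species -> toy exchange reaction
EXCHANGE_MAPPING: dict[str, str] = {
    "glucose": "EX_glc__D_e",
    "succinate": "EX_succ_e",
    "gaba": "EX_4abut_e",
    "glutamate": "EX_glu__L_e",
    "acetate": "EX_ac_e",
}

BIOMASS_ID = "BIOMASS"

#: the in-silico strain: 2-oxoglutarate dehydrogenase and GABA transaminase off
ENGINEERED_REACTION_KNOCKOUTS = KnockoutSpec(reaction_ids={"AKGDH", "ABTA"})
#: the same strain expressed through its deleted loci
ENGINEERED_GENE_KNOCKOUTS = KnockoutSpec(gene_ids={"sucA", "gabT"})


def measured_constraints(condition: str) -> ConditionConstraints:
    """Measured-rate constraints for one condition of the bundled table."""
    row = MEASURED_RATES[condition]
    return ConditionConstraints(
        growth_rate=row["growth_rate"],
        rates={
            species: (row[species], SPECIES_DIRECTIONS[species])
            for species in SPECIES_DIRECTIONS
        },
        provenance="measured-table",
        label=condition,
    )


# ---------------------------------------------------------------------------
# The curated toy network
# ---------------------------------------------------------------------------

BIG = 1000.0

# id, name, compartment, formula
_METABOLITES = [
    ("glc__D_e", "D-glucose", "e", "C6H12O6"),
    ("succ_e", "succinate", "e", "C4H6O4"),
    ("4abut_e", "4-aminobutanoate (GABA)", "e", "C4H9NO2"),
    ("glu__L_e", "L-glutamate", "e", "C5H9NO4"),
    ("ac_e", "acetate", "e", "C2H4O2"),
    ("g6p_c", "glucose 6-phosphate", "c", "C6H13O9P"),
    ("f6p_c", "fructose 6-phosphate", "c", "C6H13O9P"),
    ("fdp_c", "fructose 1,6-bisphosphate", "c", "C6H14O12P2"),
    ("g3p_c", "glyceraldehyde 3-phosphate", "c", "C3H7O6P"),
    ("pep_c", "phosphoenolpyruvate", "c", "C3H5O6P"),
    ("pyr_c", "pyruvate", "c", "C3H4O3"),
    ("6pgc_c", "6-phospho-D-gluconate", "c", "C6H13O10P"),
    ("r5p_c", "ribose 5-phosphate", "c", "C5H11O8P"),
    ("accoa_c", "acetyl-CoA", "c", "C23H38N7O17P3S"),
    ("coa_c", "coenzyme A", "c", "C21H36N7O16P3S"),
    ("actp_c", "acetyl phosphate", "c", "C2H5O5P"),
    ("ac_c", "acetate", "c", "C2H4O2"),
    ("cit_c", "citrate", "c", "C6H8O7"),
    ("icit_c", "isocitrate", "c", "C6H8O7"),
    ("akg_c", "2-oxoglutarate", "c", "C5H6O5"),
    ("succoa_c", "succinyl-CoA", "c", "C25H40N7O19P3S"),
    ("succ_c", "succinate", "c", "C4H6O4"),
    ("fum_c", "fumarate", "c", "C4H4O4"),
    ("mal__L_c", "L-malate", "c", "C4H6O5"),
    ("oaa_c", "oxaloacetate", "c", "C4H4O5"),
    ("glx_c", "glyoxylate", "c", "C2H2O3"),
    ("glu__L_c", "L-glutamate", "c", "C5H9NO4"),
    ("4abut_c", "4-aminobutanoate (GABA)", "c", "C4H9NO2"),
    ("sucsal_c", "succinic semialdehyde", "c", "C4H6O3"),
    ("nad_c", "NAD+", "c", "C21H26N7O14P2"),
    ("nadh_c", "NADH", "c", "C21H28N7O14P2"),
    ("nadp_c", "NADP+", "c", "C21H27N7O17P3"),
    ("nadph_c", "NADPH", "c", "C21H29N7O17P3"),
    ("atp_c", "ATP", "c", "C10H16N5O13P3"),
    ("adp_c", "ADP", "c", "C10H15N5O10P2"),
    ("pi_c", "phosphate", "c", "H3O4P"),
    ("o2_c", "oxygen", "c", "O2"),
    ("co2_c", "carbon dioxide", "c", "CO2"),
    ("nh4_c", "ammonium", "c", "H3N"),
    ("h2o_c", "water", "c", "H2O"),
]

# id, name, stoichiometry, (lb, ub), gpr, subsystem
_REACTIONS: list[tuple] = [
    # --- glycolysis (PTS entry) ---
    ("GLCpts", "glucose PTS transport", {"glc__D_e": -1, "pep_c": -1, "g6p_c": 1, "pyr_c": 1},
     (0, BIG), "ptsG", "glycolysis"),
    ("PGI", "glucose-6-phosphate isomerase", {"g6p_c": -1, "f6p_c": 1},
     (-BIG, BIG), "pgi", "glycolysis"),
    ("PFK", "phosphofructokinase", {"f6p_c": -1, "atp_c": -1, "fdp_c": 1, "adp_c": 1},
     (0, BIG), "pfkA or pfkB", "glycolysis"),
    ("FBA", "fructose-bisphosphate aldolase (with triose isomerase)",
     {"fdp_c": -1, "g3p_c": 2}, (-BIG, BIG), "fbaA", "glycolysis"),
    ("GAPD", "lower glycolysis (GAP dehydrogenase through enolase, lumped)",
     {"g3p_c": -1, "nad_c": -1, "adp_c": -1, "pi_c": -1,
      "pep_c": 1, "nadh_c": 1, "atp_c": 1, "h2o_c": 1},
     (-BIG, BIG), "gapA", "glycolysis"),
    ("PYK", "pyruvate kinase", {"pep_c": -1, "adp_c": -1, "pyr_c": 1, "atp_c": 1},
     (0, BIG), "pykA or pykF", "glycolysis"),
    ("PDH", "pyruvate dehydrogenase",
     {"pyr_c": -1, "coa_c": -1, "nad_c": -1, "accoa_c": 1, "co2_c": 1, "nadh_c": 1},
     (0, BIG), "aceE and aceF and lpdA", "glycolysis"),
    # --- pentose phosphate pathway ---
    ("G6PDH2r", "glucose-6-phosphate dehydrogenase (with lactonase, lumped)",
     {"g6p_c": -1, "nadp_c": -1, "h2o_c": -1, "6pgc_c": 1, "nadph_c": 1},
     (0, BIG), "zwf", "pentose phosphate pathway"),
    ("GND", "6-phosphogluconate dehydrogenase (to ribose-5-P, lumped)",
     {"6pgc_c": -1, "nadp_c": -1, "r5p_c": 1, "co2_c": 1, "nadph_c": 1},
     (0, BIG), "gnd", "pentose phosphate pathway"),
    ("TKTTAL", "non-oxidative pentose phosphate shunt (transketolase/transaldolase, lumped)",
     {"r5p_c": -3, "f6p_c": 2, "g3p_c": 1}, (-BIG, BIG), "tktA or tktB", "pentose phosphate pathway"),
    # --- TCA cycle, glyoxylate shunt, anaplerosis ---
    ("CS", "citrate synthase",
     {"accoa_c": -1, "oaa_c": -1, "h2o_c": -1, "cit_c": 1, "coa_c": 1},
     (0, BIG), "gltA", "TCA cycle"),
    ("ACONT", "aconitase", {"cit_c": -1, "icit_c": 1}, (-BIG, BIG), "acnA or acnB", "TCA cycle"),
    ("ICDHyr", "isocitrate dehydrogenase (NADP)",
     {"icit_c": -1, "nadp_c": -1, "akg_c": 1, "co2_c": 1, "nadph_c": 1},
     (-BIG, BIG), "icdA", "TCA cycle"),
    ("AKGDH", "2-oxoglutarate dehydrogenase",
     {"akg_c": -1, "coa_c": -1, "nad_c": -1, "succoa_c": 1, "co2_c": 1, "nadh_c": 1},
     (0, BIG), "sucA and sucB and lpdA", "TCA cycle"),
    ("SUCOAS", "succinyl-CoA synthetase",
     {"succ_c": -1, "coa_c": -1, "atp_c": -1, "succoa_c": 1, "adp_c": 1, "pi_c": 1},
     (-BIG, BIG), "sucC and sucD", "TCA cycle"),
    ("SUCDi", "succinate dehydrogenase (respiration-coupled, lumped)",
     {"succ_c": -1, "o2_c": -0.5, "adp_c": -1, "pi_c": -1,
      "fum_c": 1, "atp_c": 1, "h2o_c": 2},
     (0, BIG), "sdhA and sdhB", "TCA cycle"),
    ("FUM", "fumarase", {"fum_c": -1, "h2o_c": -1, "mal__L_c": 1}, (-BIG, BIG),
     "fumA or fumC", "TCA cycle"),
    ("MDH", "malate dehydrogenase", {"mal__L_c": -1, "nad_c": -1, "oaa_c": 1, "nadh_c": 1},
     (-BIG, BIG), "mdh", "TCA cycle"),
    ("ME2", "malic enzyme (NADP)",
     {"mal__L_c": -1, "nadp_c": -1, "pyr_c": 1, "co2_c": 1, "nadph_c": 1},
     (0, BIG), "maeB", "TCA cycle"),
    ("PPC", "phosphoenolpyruvate carboxylase",
     {"pep_c": -1, "co2_c": -1, "h2o_c": -1, "oaa_c": 1, "pi_c": 1},
     (0, BIG), "ppc", "TCA cycle"),
    ("ICL", "isocitrate lyase", {"icit_c": -1, "glx_c": 1, "succ_c": 1}, (0, BIG),
     "aceA", "TCA cycle"),
    ("MALS", "malate synthase",
     {"accoa_c": -1, "glx_c": -1, "h2o_c": -1, "mal__L_c": 1, "coa_c": 1},
     (0, BIG), "aceB", "TCA cycle"),
    # --- acetate fermentation ---
    ("PTAr", "phosphotransacetylase", {"accoa_c": -1, "pi_c": -1, "actp_c": 1, "coa_c": 1},
     (-BIG, BIG), "pta", "acetate fermentation"),
    ("ACKr", "acetate kinase", {"actp_c": -1, "adp_c": -1, "ac_c": 1, "atp_c": 1},
     (-BIG, BIG), "ackA", "acetate fermentation"),
    ("ACt", "acetate transport", {"ac_c": -1, "ac_e": 1}, (-BIG, BIG), "", "acetate fermentation"),
    # --- GABA shunt and glutamate ---
    ("GLUDy", "glutamate dehydrogenase (NADP)",
     {"akg_c": -1, "nadph_c": -1, "nh4_c": -1, "glu__L_c": 1, "nadp_c": 1, "h2o_c": 1},
     (-BIG, BIG), "gdhA", "GABA shunt"),
    ("GLUDC", "glutamate decarboxylase", {"glu__L_c": -1, "4abut_c": 1, "co2_c": 1},
     (0, BIG), "gadA or gadB", "GABA shunt"),
    ("ABTA", "4-aminobutyrate transaminase",
     {"4abut_c": -1, "akg_c": -1, "glu__L_c": 1, "sucsal_c": 1},
     (0, BIG), "gabT", "GABA shunt"),
    ("SSALy", "succinate-semialdehyde dehydrogenase (NADP)",
     {"sucsal_c": -1, "h2o_c": -1, "nadp_c": -1, "succ_c": 1, "nadph_c": 1},
     (0, BIG), "gabD", "GABA shunt"),
    ("GLUt", "glutamate export", {"glu__L_c": -1, "glu__L_e": 1}, (0, BIG), "", "GABA shunt"),
    ("ABUTt", "GABA export", {"4abut_c": -1, "4abut_e": 1}, (0, BIG), "gadC", "GABA shunt"),
    # --- energy, redox, transport, biomass ---
    ("SUCCt", "succinate transport", {"succ_e": -1, "succ_c": 1}, (-BIG, BIG), "", "other"),
    ("NADHOR", "NADH oxidation / oxidative phosphorylation (lumped, P/O = 2)",
     {"nadh_c": -1, "o2_c": -0.5, "adp_c": -2, "pi_c": -2,
      "nad_c": 1, "atp_c": 2, "h2o_c": 3},
     (0, BIG), "", "other"),
    ("NADTRHD", "transhydrogenase", {"nad_c": -1, "nadph_c": -1, "nadh_c": 1, "nadp_c": 1},
     (-BIG, BIG), "", "other"),
    ("ATPM", "ATP maintenance", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
     (0, BIG), "", "other"),
    (BIOMASS_ID, "biomass (lumped drain; coefficients mmol per gDCW)",
     {"g6p_c": -0.2, "r5p_c": -0.1, "pep_c": -0.3, "pyr_c": -0.4, "accoa_c": -0.5,
      "oaa_c": -0.3, "glu__L_c": -0.5, "succoa_c": -0.15, "nh4_c": -0.2,
      "atp_c": -20.0, "h2o_c": -20.0, "nadph_c": -3.0,
      "adp_c": 20.0, "pi_c": 20.0, "nadp_c": 3.0, "coa_c": 0.65},
     (0, BIG), "", "other"),
    # --- exchanges (negative = uptake) ---
    ("EX_glc__D_e", "glucose exchange", {"glc__D_e": -1}, (-10, BIG), "", "exchange"),
    ("EX_succ_e", "succinate exchange", {"succ_e": -1}, (-5, BIG), "", "exchange"),
    ("EX_4abut_e", "GABA exchange", {"4abut_e": -1}, (0, BIG), "", "exchange"),
    ("EX_glu__L_e", "glutamate exchange", {"glu__L_e": -1}, (0, BIG), "", "exchange"),
    ("EX_ac_e", "acetate exchange", {"ac_e": -1}, (0, BIG), "", "exchange"),
    ("EX_o2", "oxygen exchange", {"o2_c": -1}, (-BIG, 0), "", "exchange"),
    ("EX_co2", "CO2 exchange", {"co2_c": -1}, (-BIG, BIG), "", "exchange"),
    ("EX_nh4", "ammonium exchange", {"nh4_c": -1}, (-BIG, BIG), "", "exchange"),
    ("EX_pi", "phosphate exchange", {"pi_c": -1}, (-BIG, BIG), "", "exchange"),
    ("EX_h2o", "water exchange", {"h2o_c": -1}, (-BIG, BIG), "", "exchange"),
]

_PPP_REACTIONS = {"G6PDH2r", "GND", "TKTTAL"}
_ACETATE_REACTIONS = {"PTAr", "ACKr", "ACt", "EX_ac_e"}

#: reaction id -> pathway label, for the Fig.-3-style pathway summaries
TOY_PATHWAYS: dict[str, str] = {
    rxn_id: subsystem
    for rxn_id, _, _, _, _, subsystem in _REACTIONS
    if subsystem not in ("other", "exchange")
}


@dataclass(frozen=True)
class ToySpec:
    """Switches for the toy network build.

    ``knockouts`` are direct reaction knockouts baked into the returned
    model; the engineered strain's AKGDH/ABTA deletions are usually applied
    afterwards with :func:`gabaflux.model_core.apply_knockouts` instead.
    """

    include_ppp: bool = True
    include_acetate_branch: bool = True
    knockouts: frozenset[str] = frozenset()
    exchange_caps: dict = field(default_factory=dict)  # species -> max uptake, mmol/gDCW/h
    validate: bool = True


def build_toy_core(spec: ToySpec | None = None) -> MetabolicModel:
    """Build the curated toy model and run its build-time validity checks.

    With the default spec the returned model (a) passes elemental balance on
    every internal reaction except the lumped biomass, and (b) admits every
    measured rate vector of the three culture conditions as a feasible flux
    state once AKGDH and ABTA are knocked out.  A violation raises
    :class:`ToyBuildError`, since it would be a fixture bug rather than a
    user error.
    """
    spec = spec or ToySpec()
    dropped: set[str] = set()
    if not spec.include_ppp:
        dropped |= _PPP_REACTIONS
    if not spec.include_acetate_branch:
        dropped |= _ACETATE_REACTIONS

    reactions = []
    for rxn_id, name, stoich, (lb, ub), gpr, subsystem in _REACTIONS:
        if rxn_id in dropped:
            continue
        if rxn_id in spec.knockouts:
            lb, ub = 0.0, 0.0
        reactions.append(
            Reaction(
                id=rxn_id,
                name=name,
                stoichiometry=stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                gpr=parse_gpr(gpr),
                subsystem=subsystem,
            )
        )
    for species, cap in spec.exchange_caps.items():
        ex_id = EXCHANGE_MAPPING[species]
        for i, rxn in enumerate(reactions):
            if rxn.id == ex_id:
                reactions[i] = rxn.with_bounds(-abs(cap), rxn.upper_bound)

    used = {met for rxn in reactions for met in rxn.stoichiometry}
    metabolites = [
        Metabolite(met_id, name, compartment, formula)
        for met_id, name, compartment, formula in _METABOLITES
        if met_id in used
    ]
    model = MetabolicModel(
        id="toy_core_gaba",
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction_id=BIOMASS_ID,
        compartments={"c": "cytosol", "e": "extracellular space"},
    )
    if spec.validate:
        _validate_toy(model, full_fixture=not dropped and not spec.knockouts)
    return model


def _validate_toy(model: MetabolicModel, full_fixture: bool) -> None:
    imbalance = check_mass_balance(model, skip=[BIOMASS_ID])
    if imbalance:
        raise ToyBuildError(f"elementally unbalanced reactions: {imbalance}")
    if not full_fixture:
        return
    strain = apply_knockouts(model, ENGINEERED_REACTION_KNOCKOUTS)
    for condition in MEASURED_RATES:
        constraints = measured_constraints(condition)
        pinned = set_exchange_bounds(
            strain, constraints, EXCHANGE_MAPPING, mode="hard", tol=1e-9
        ).with_bounds(
            {BIOMASS_ID: (constraints.growth_rate - 1e-9, constraints.growth_rate + 1e-9)}
        )
        check = fba(pinned, objective=BIOMASS_ID)
        if not check.optimal:
            raise ToyBuildError(
                f"measured rate vector for condition {condition!r} is not feasible "
                f"on the knockout strain (solver status: {check.status})"
            )


# ---------------------------------------------------------------------------
# Synthetic batch profiles
# ---------------------------------------------------------------------------


@dataclass
class ProfileSpec:
    """Truth parameters for one synthetic exponential batch profile."""

    mu: float  # 1/h
    x0: float = 0.1  # initial OD600
    q: dict[str, float] = field(default_factory=dict)  # signed, mmol/gDCW/h
    c0: dict[str, float] = field(default_factory=dict)  # g/l
    t_grid: np.ndarray = field(default_factory=lambda: np.arange(0.0, 12.1, 1.0))
    noise_cv: float = 0.0
    seed: int = 0
    biomass_factor: float = DEFAULT_BIOMASS_FACTOR
    molar_masses: dict[str, float] = field(default_factory=dict)
    condition_label: str = ""

    def __post_init__(self):
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if self.x0 <= 0:
            raise ValueError("x0 must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if np.any(np.diff(self.t_grid) <= 0):
            raise ValueError("t_grid must be strictly increasing")


def generate_profile(spec: ProfileSpec) -> FermentationProfile:
    """Closed-form exponential batch profile with lognormal measurement noise.

    OD follows X₀·e^{μt}; each species' concentration is linear in biomass
    with slope q·MW/μ (the exact balanced-growth solution), so a noiseless
    profile is recovered by the rate estimator to machine precision.  Noise
    is multiplicative lognormal with the requested coefficient of variation,
    drawn from ``spec.seed``; identical seeds give bit-identical profiles.
    """
    masses = dict(MOLAR_MASSES)
    masses.update(spec.molar_masses)
    times = spec.t_grid
    od = spec.x0 * np.exp(spec.mu * times)
    biomass = spec.biomass_factor * od  # gDCW/l
    concentrations: dict[str, np.ndarray] = {}
    for species, rate in spec.q.items():
        c0 = spec.c0.get(species, 0.0)
        if abs(spec.mu) < 1e-300:
            conc = np.full_like(times, c0)
        else:
            # dC/dt = q * MW/1000 * X(t)  ⇒  C = c0 + q*MW/(1000 μ) (X - X0)
            conc = c0 + rate * masses[species] / 1000.0 / spec.mu * (biomass - biomass[0])
        concentrations[species] = conc

    rng = np.random.default_rng(spec.seed)
    if spec.noise_cv > 0:
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))

        def jitter(values: np.ndarray) -> np.ndarray:
            factors = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=len(values))
            return values * factors

        od = jitter(od)
        concentrations = {k: jitter(v) for k, v in concentrations.items()}

    floored = {}
    for species, conc in concentrations.items():
        if np.any(conc < 0):
            warnings.warn(
                f"{species}: concentration trajectory crosses zero "
                f"(min {conc.min():.4g} g/l); flooring at 0",
                stacklevel=2,
            )
        floored[species] = np.maximum(conc, 0.0)
    return FermentationProfile(
        times=times,
        od600=od,
        concentrations=floored,
        condition_label=spec.condition_label,
    )


def generate_phased_profile(
    t_grid: np.ndarray,
    segments: list[tuple[float, float]],
    x0: float = 0.1,
) -> FermentationProfile:
    """Piecewise-exponential OD curve (lag / log / stationary shaping).

    ``segments`` is a list of (start time, growth rate); each segment's rate
    applies from its start time to the next segment's.  Used to emulate the
    shape of real batch growth curves, where only a limited window grows at
    the maximal rate.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    starts = [s for s, _ in segments]
    if starts != sorted(starts):
        raise ValueError("segments must be ordered by start time")
    od = np.empty_like(t_grid)
    for i, t in enumerate(t_grid):
        x = x0
        for (start, mu), nxt in zip(segments, starts[1:] + [np.inf]):
            if t <= start:
                break
            x *= np.exp(mu * (min(t, nxt) - start))
        od[i] = x
    return FermentationProfile(times=t_grid, od600=od, concentrations={})


def profile_spec_for_condition(
    condition: str,
    noise_cv: float = 0.0,
    seed: int = 0,
    t_grid: np.ndarray | None = None,
) -> ProfileSpec:
    """Profile truth for one culture condition of the bundled rate table."""
    row = MEASURED_RATES[condition]
    signed = {
        species: (-row[species] if SPECIES_DIRECTIONS[species] == "uptake" else row[species])
        for species in SPECIES_DIRECTIONS
    }
    c0 = {
        "glucose": 20.0,
        "succinate": 4.0 if condition == "acidic-4gl" else 2.0,
        "gaba": 0.0,
        "glutamate": 0.0,
        "acetate": 0.0,
    }
    kwargs = {} if t_grid is None else {"t_grid": t_grid}
    return ProfileSpec(
        mu=row["growth_rate"],
        q=signed,
        c0=c0,
        noise_cv=noise_cv,
        seed=seed,
        condition_label=condition,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Bundled data files
# ---------------------------------------------------------------------------


def bundled_path(name: str):
    """Path to a data file shipped with the package (e.g. measured_rates.tsv)."""
    return importlib.resources.files("gabaflux").joinpath("data", name)
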