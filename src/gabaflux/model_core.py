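"""Stoichiometric metabolic models: representation, I/O, validation, knockouts.

A :class:`MetabolicModel` is the in-silico strain: a stoichiometric matrix S
(one row per metabolite, one column per reaction), flux bounds in
mmol/gDCW/h, boolean gene-protein-reaction (GPR) rules, and a biomass
objective.  Gene knockouts act through GPR evaluation (a reaction is disabled
when its rule evaluates false with the knocked genes absent); direct reaction
knockouts are an explicit, separate list, because published strain designs
often pin the reactions rather than the loci.

The primary on-disk dialect is BiGG-style JSON; SBML Level 3 with the FBC
package is supported as a secondary dialect through libsbml.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "GprExpression",
    "MetabolicModel",
    "KnockoutSpec",
    "ModelFormatError",
    "NoObjectiveError",
    "UnknownIdError",
    "parse_gpr",
    "evaluate_gpr",
    "apply_knockouts",
    "load_model",
    "write_model",
    "set_exchange_bounds",
]

DEFAULT_BOUND = 1000.0


class ModelFormatError(ValueError):
    """A model file could not be parsed in the declared dialect."""


class NoObjectiveError(ValueError):
    """The model declares no objective reaction."""


class UnknownIdError(KeyError):
    """An identifier does not resolve against the model."""


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


@dataclass(frozen=True)
class GprExpression:
    """Boolean expression tree over gene ids.

    ``op`` is ``"gene"`` (leaf, ``children`` holds the gene id string),
    ``"and"`` or ``"or"`` (internal nodes, ``children`` holds sub-expressions).
    An empty rule is represented by ``None`` at the call sites, meaning the
    reaction is always active.
    """

    op: str
    children: tuple

    def genes(self) -> frozenset[str]:
        if self.op == "gene":
            return frozenset([self.children[0]])
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return frozenset(out)

    def to_string(self) -> str:
        if self.op == "gene":
            return self.children[0]
        sep = f" {self.op} "
        parts = []
        for child in self.children:
            text = child.to_string()
            if child.op != "gene" and child.op != self.op:
                text = f"({text})"
            parts.append(text)
        return sep.join(parts)


def parse_gpr(rule: str | None) -> GprExpression | None:
    """Parse a textual GPR rule ('g1 and (g2 or g3)') into an expression tree.

    Returns None for an empty rule (always-active reaction).  ``and`` binds
    tighter than ``or``; both keywords are case-insensitive.
    """
    if rule is None or not rule.strip():
        return None
    tokens = _GPR_TOKEN.findall(rule)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GprExpression:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        if len(terms) == 1:
            return terms[0]
        return GprExpression("or", tuple(terms))

    def parse_and() -> GprExpression:
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            terms.append(parse_atom())
        if len(terms) == 1:
            return terms[0]
        return GprExpression("and", tuple(terms))

    def parse_atom() -> GprExpression:
        tok = peek()
        if tok is None:
            raise ModelFormatError(f"truncated GPR rule: {rule!r}")
        if tok == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise ModelFormatError(f"unbalanced parentheses in GPR rule: {rule!r}")
            take()
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelFormatError(f"unexpected token {tok!r} in GPR rule: {rule!r}")
        return GprExpression("gene", (take(),))

    expr = parse_or()
    if pos != len(tokens):
        raise ModelFormatError(f"trailing tokens in GPR rule: {rule!r}")
    return expr


def evaluate_gpr(gpr: GprExpression | None, knocked: Iterable[str]) -> bool:
    """Is the reaction still catalysed when ``knocked`` genes are deleted?

    AND nodes (enzyme complexes) require every child; OR nodes (isozymes)
    require any child.  An absent rule means the reaction is always active.
    """
    if gpr is None:
        return True
    knocked = frozenset(knocked)
    if gpr.op == "gene":
        return gpr.children[0] not in knocked
    if gpr.op == "and":
        return all(evaluate_gpr(child, knocked) for child in gpr.children)
    if gpr.op == "or":
        return any(evaluate_gpr(child, knocked) for child in gpr.children)
    raise ValueError(f"unknown GPR node {gpr.op!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("metabolite id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """One column of S, with bounds in mmol/gDCW/h and an optional GPR."""

    id: str
    stoichiometry: Mapping[str, float]
    name: str = ""
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GprExpression | None = None
    subsystem: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"{self.id}: lower_bound {self.lower_bound} > upper_bound {self.upper_bound}"
            )
        object.__setattr__(
            self, "stoichiometry", {k: float(v) for k, v in self.stoichiometry.items()}
        )

    @property
    def is_exchange(self) -> bool:
        """Boundary pseudo-reactions touch a single metabolite."""
        return len(self.stoichiometry) <= 1

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=lower, upper_bound=upper)


@dataclass(frozen=True)
class KnockoutSpec:
    """Genes to delete (acting through GPRs) and reactions to pin to zero."""

    gene_ids: frozenset[str] = frozenset()
    reaction_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))
        object.__setattr__(self, "reaction_ids", frozenset(self.reaction_ids))


class MetabolicModel:
    """A stoichiometric model: metabolites, reactions, genes, objective."""

    def __init__(
        self,
        id: str,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        genes: Sequence[str] | None = None,
        objective_reaction_id: str | None = None,
        compartments: Mapping[str, str] | None = None,
    ):
        self.id = id
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._met_index) != len(self.metabolites):
            raise ValueError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ValueError("duplicate reaction ids")
        gpr_genes: set[str] = set()
        for rxn in self.reactions:
            if rxn.gpr is not None:
                gpr_genes |= rxn.gpr.genes()
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ValueError(
                        f"reaction {rxn.id} references unknown metabolite {met_id!r}"
                    )
        self.genes = sorted(set(genes or []) | gpr_genes)
        if objective_reaction_id is not None and objective_reaction_id not in self._rxn_index:
            raise ValueError(f"objective reaction {objective_reaction_id!r} not in model")
        self.objective_reaction_id = objective_reaction_id
        self.compartments = dict(compartments or {})

    # -- lookups ------------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self.metabolites[self._met_index[met_id]]
        except KeyError:
            raise UnknownIdError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise UnknownIdError(f"unknown reaction {rxn_id!r}") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def objective_reaction(self) -> Reaction:
        if self.objective_reaction_id is None:
            raise NoObjectiveError(f"model {self.id!r} declares no objective reaction")
        return self.reaction(self.objective_reaction_id)

    # -- matrices -----------------------------------------------------------

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S with one row per metabolite and one column per reaction."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                S[self._met_index[met_id], j] = coeff
        return S

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # -- copies -------------------------------------------------------------

    def with_reactions(self, new_reactions: Sequence[Reaction]) -> "MetabolicModel":
        return MetabolicModel(
            self.id,
            self.metabolites,
            new_reactions,
            genes=self.genes,
            objective_reaction_id=self.objective_reaction_id,
            compartments=self.compartments,
        )

    def with_bounds(self, new_bounds: Mapping[str, tuple[float, float]]) -> "MetabolicModel":
        """Copy of the model with selected reaction bounds replaced."""
        for rxn_id in new_bounds:
            if rxn_id not in self._rxn_index:
                raise UnknownIdError(f"unknown reaction {rxn_id!r}")
        updated = [
            r.with_bounds(*new_bounds[r.id]) if r.id in new_bounds else r
            for r in self.reactions
        ]
        return self.with_reactions(updated)

    def __repr__(self) -> str:
        return (
            f"MetabolicModel({self.id!r}, {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes)"
        )


# ---------------------------------------------------------------------------
# Knockouts
# ---------------------------------------------------------------------------


def apply_knockouts(model: MetabolicModel, spec: KnockoutSpec) -> MetabolicModel:
    """Return a copy of ``model`` with knocked-out reactions bounded to [0, 0].

    A reaction is disabled if it is listed directly in ``spec.reaction_ids``
    or if its GPR evaluates inactive once ``spec.gene_ids`` are deleted.
    The input model is never mutated.
    """
    known_genes = set(model.genes)
    unknown_genes = sorted(set(spec.gene_ids) - known_genes)
    if unknown_genes:
        raise UnknownIdError(f"unknown gene ids in knockout spec: {unknown_genes}")
    unknown_rxns = sorted(r for r in spec.reaction_ids if not model.has_reaction(r))
    if unknown_rxns:
        raise UnknownIdError(f"unknown reaction ids in knockout spec: {unknown_rxns}")

    new_bounds: dict[str, tuple[float, float]] = {}
    for rxn in model.reactions:
        dead = rxn.id in spec.reaction_ids or not evaluate_gpr(rxn.gpr, spec.gene_ids)
        if dead:
            new_bounds[rxn.id] = (0.0, 0.0)
    return model.with_bounds(new_bounds) if new_bounds else model.with_reactions(model.reactions)


# ---------------------------------------------------------------------------
# Exchange-bound constraints
# ---------------------------------------------------------------------------


def signed_rate(magnitude: float, direction: str) -> float:
    """Convert (magnitude, direction) to model sign convention.

    Uptake is negative, secretion positive (BiGG exchange convention).
    """
    if direction not in ("uptake", "secretion"):
        raise ValueError(f"direction must be 'uptake' or 'secretion', got {direction!r}")
    return -abs(magnitude) if direction == "uptake" else abs(magnitude)


def set_exchange_bounds(model, constraints, mapping, mode="hard", tol=0.0):
    """Apply measured exchange rates from one culture condition to the model.

    Parameters
    ----------
    constraints : ConditionConstraints
        Measured magnitudes plus uptake/secretion directions.
    mapping : mapping species name -> exchange reaction id
    mode : {"hard", "reference-only"}
        ``hard`` pins each mapped exchange to ``[rate - tol, rate + tol]``
        (signed, uptake negative).  ``reference-only`` leaves the bounds at
        their physiological defaults; callers attach the rates as LAD
        references instead (see :func:`gabaflux.flux_analysis.condition_references`).
    """
    if mode not in ("hard", "reference-only"):
        raise ValueError(f"unknown mode {mode!r}")
    unmapped = sorted(set(constraints.rates) - set(mapping))
    if unmapped:
        raise UnknownIdError(f"no exchange-reaction mapping for species: {unmapped}")
    if mode == "reference-only" or not constraints.rates:
        return model.with_reactions(model.reactions)
    new_bounds = {}
    for species, (magnitude, direction) in constraints.rates.items():
        rxn_id = mapping[species]
        if not model.has_reaction(rxn_id):
            raise UnknownIdError(f"mapped exchange reaction {rxn_id!r} not in model")
        rate = signed_rate(magnitude, direction)
        new_bounds[rxn_id] = (rate - tol, rate + tol)
    return model.with_bounds(new_bounds)


# ---------------------------------------------------------------------------
# BiGG-style JSON I/O
# ---------------------------------------------------------------------------


def _model_from_bigg_dict(doc: dict, source: str) -> MetabolicModel:
    try:
        raw_mets = doc["metabolites"]
        raw_rxns = doc["reactions"]
    except KeyError as exc:
        raise ModelFormatError(f"{source}: missing top-level key {exc}") from None
    mets = []
    for entry in raw_mets:
        if "id" not in entry:
            raise ModelFormatError(f"{source}: metabolite entry without id: {entry}")
        mets.append(
            Metabolite(
                id=entry["id"],
                name=entry.get("name", ""),
                compartment=entry.get("compartment", ""),
                formula=entry.get("formula"),
            )
        )
    reactions = []
    objective = None
    for entry in raw_rxns:
        if "id" not in entry or "metabolites" not in entry:
            raise ModelFormatError(f"{source}: reaction entry missing id/metabolites: {entry}")
        try:
            gpr = parse_gpr(entry.get("gene_reaction_rule", ""))
        except ModelFormatError as exc:
            raise ModelFormatError(f"{source}: reaction {entry['id']}: {exc}") from None
        reactions.append(
            Reaction(
                id=entry["id"],
                name=entry.get("name", ""),
                stoichiometry={k: float(v) for k, v in entry["metabolites"].items()},
                lower_bound=float(entry.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(entry.get("upper_bound", DEFAULT_BOUND)),
                gpr=gpr,
                subsystem=entry.get("subsystem") or None,
            )
        )
        coeff = entry.get("objective_coefficient", 0)
        if coeff:
            objective = entry["id"]
    genes = [g["id"] if isinstance(g, dict) else str(g) for g in doc.get("genes", [])]
    try:
        return MetabolicModel(
            id=doc.get("id", "model"),
            metabolites=mets,
            reactions=reactions,
            genes=genes,
            objective_reaction_id=objective,
            compartments=doc.get("compartments", {}),
        )
    except ValueError as exc:
        raise ModelFormatError(f"{source}: {exc}") from None


def _model_to_bigg_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "compartments": model.compartments,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula else {}),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr.to_string() if r.gpr else "",
                **({"subsystem": r.subsystem} if r.subsystem else {}),
                **(
                    {"objective_coefficient": 1.0}
                    if r.id == model.objective_reaction_id
                    else {}
                ),
            }
            for r in model.reactions
        ],
        "genes": [{"id": g, "name": g} for g in model.genes],
        "version": "1",
    }


def load_model(path, format: str = "bigg-json") -> MetabolicModel:
    """Read a metabolic model from disk.

    ``format`` is ``"bigg-json"`` (primary dialect) or ``"sbml"`` (Level 3
    with the FBC package, through libsbml).  Counts, bounds and GPR rules are
    preserved exactly.
    """
    path = str(path)
    if format == "bigg-json":
        try:
            with open(path) as handle:
                doc = json.load(handle)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"{path}: not valid JSON ({exc})") from None
        if not isinstance(doc, dict):
            raise ModelFormatError(f"{path}: expected a JSON object at top level")
        return _model_from_bigg_dict(doc, path)
    if format == "sbml":
        from . import sbml_io

        return sbml_io.read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path, format: str = "bigg-json") -> None:
    """Write a model in BiGG JSON or SBML L3+FBC."""
    path = str(path)
    if format == "bigg-json":
        with open(path, "w") as handle:
            json.dump(_model_to_bigg_dict(model), handle, indent=1, sort_keys=False)
            handle.write("\n")
        return
    if format == "sbml":
        from . import sbml_io

        sbml_io.write_sbml(model, path)
        return
    raise ValueError(f"unknown model format {format!r}")


def check_mass_balance(model: MetabolicModel, skip: Iterable[str] = ()) -> dict[str, dict]:
    """Elemental-balance report for every non-exchange reaction.

    Returns a map reaction id -> {element: net coefficient} for reactions
    that do not balance.  Reactions listed in ``skip`` (e.g. the lumped
    biomass) and reactions touching a metabolite without a formula are
    ignored.
    """
    skip = set(skip)
    elements = re.compile(r"([A-Z][a-z]?)(\d*)")

    def parse_formula(formula: str) -> dict[str, float]:
        counts: dict[str, float] = {}
        for element, number in elements.findall(formula):
            counts[element] = counts.get(element, 0.0) + (float(number) if number else 1.0)
        return counts

    report = {}
    for rxn in model.reactions:
        if rxn.id in skip or rxn.is_exchange:
            continue
        net: dict[str, float] = {}
        ok = True
        for met_id, coeff in rxn.stoichiometry.items():
            formula = model.metabolite(met_id).formula
            if not formula:
                ok = False
                break
            for element, count in parse_formula(formula).items():
                net[element] = net.get(element, 0.0) + coeff * count
        if not ok:
            continue
        residual = {el: val for el, val in net.items() if not math.isclose(val, 0.0, abs_tol=1e-9)}
        if residual:
            report[rxn.id] = residual
    return report
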