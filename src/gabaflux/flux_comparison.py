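"""Per-reaction flux-change classification between two culture conditions.

A reaction's flux change between condition A and condition B is classified
by a pure function of the two fluxes, a relative threshold (default 20%) and
a zero tolerance ε:

* both |flux| < ε            → ``unchanged``
* |a| < ε ≤ |b|              → ``de-novo``   (off → on)
* |b| < ε ≤ |a|              → ``abolished`` (on → off)
* opposite signs, both ≥ ε   → ``inverted``  (direction flip)
* else r = (|b| − |a|)/|a|:  r > threshold → ``induced``,
  r < −threshold → ``suppressed``, otherwise ``unchanged``

The three extra classes (inverted / de-novo / abolished) exist because a
plain induced/suppressed/unchanged scheme cannot express a direction flip;
reports can collapse them back to three groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .flux_analysis import FluxSolution

__all__ = [
    "FluxChange",
    "PathwaySummary",
    "CLASSES",
    "classify_change",
    "compare_conditions",
    "summarize_by_pathway",
    "collapse_to_three_groups",
    "write_change_table",
    "write_pathway_summaries",
    "load_pathway_map",
]

CLASSES = ("induced", "suppressed", "unchanged", "inverted", "de-novo", "abolished")

DEFAULT_THRESHOLD = 0.20
DEFAULT_ZERO_TOL = 1e-6


@dataclass(frozen=True)
class FluxChange:
    reaction_id: str
    flux_a: float
    flux_b: float
    relative_change: float
    classification: str


@dataclass
class PathwaySummary:
    pathway: str
    counts: dict[str, int]
    members: list[str]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def classify_change(
    flux_a: float,
    flux_b: float,
    threshold: float = DEFAULT_THRESHOLD,
    zero_tol: float = DEFAULT_ZERO_TOL,
    reaction_id: str = "",
) -> FluxChange:
    """Classify one reaction's flux change from condition A to condition B."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    abs_a, abs_b = abs(flux_a), abs(flux_b)
    if abs_a < zero_tol and abs_b < zero_tol:
        cls, ratio = "unchanged", 0.0
    elif abs_a < zero_tol:
        cls, ratio = "de-novo", float("inf")
    elif abs_b < zero_tol:
        cls, ratio = "abolished", -1.0
    elif (flux_a > 0) != (flux_b > 0):
        cls, ratio = "inverted", (abs_b - abs_a) / abs_a
    else:
        ratio = (abs_b - abs_a) / abs_a
        if ratio > threshold:
            cls = "induced"
        elif ratio < -threshold:
            cls = "suppressed"
        else:
            cls = "unchanged"
    return FluxChange(reaction_id, flux_a, flux_b, ratio, cls)


def compare_conditions(
    solution_a: FluxSolution,
    solution_b: FluxSolution,
    threshold: float = DEFAULT_THRESHOLD,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> list[FluxChange]:
    """One FluxChange per shared reaction, ordered by reaction id."""
    if not solution_a.optimal or not solution_b.optimal:
        raise ValueError(
            f"both solutions must be optimal (got {solution_a.status!r}, {solution_b.status!r})"
        )
    shared = sorted(set(solution_a.fluxes) & set(solution_b.fluxes))
    return [
        classify_change(
            solution_a.fluxes[rxn_id],
            solution_b.fluxes[rxn_id],
            threshold,
            zero_tol,
            reaction_id=rxn_id,
        )
        for rxn_id in shared
    ]


def collapse_to_three_groups(change: FluxChange) -> str:
    """Map the six-way class onto induced / suppressed / unchanged.

    Direction flips and de-novo activations count as induced, abolitions as
    suppressed, mirroring a three-colour flux map.
    """
    return {
        "inverted": "induced",
        "de-novo": "induced",
        "abolished": "suppressed",
    }.get(change.classification, change.classification)


def summarize_by_pathway(
    changes: Iterable[FluxChange],
    pathway_map: Mapping[str, str],
    collapse: bool = False,
) -> list[PathwaySummary]:
    """Group classifications by pathway; unmapped reactions go to "other"."""
    groups: dict[str, PathwaySummary] = {}
    for change in changes:
        pathway = pathway_map.get(change.reaction_id, "other")
        summary = groups.setdefault(pathway, PathwaySummary(pathway, {}, []))
        label = collapse_to_three_groups(change) if collapse else change.classification
        summary.counts[label] = summary.counts.get(label, 0) + 1
        summary.members.append(change.reaction_id)
    return [groups[k] for k in sorted(groups)]


def flag_degenerate_changes(
    changes: Sequence[FluxChange],
    model,
    constraints_a,
    constraints_b,
    mapping: Mapping[str, str],
    strategy: str = "lad-then-pfba",
    backend: str = "highs",
    objective_tol: float = 1e-6,
) -> set[str]:
    """Reactions whose classification is fragile under solver degeneracy.

    pFBA optima need not be unique in flux space.  For every non-`unchanged`
    reaction this re-solves each condition with that reaction's flux pinned
    to the *other* condition's value; if either re-solve stays optimal
    without worsening that condition's parsimony objective (within
    ``objective_tol``, relative), that condition admits an alternate optimum
    in which the reaction already carries the other condition's flux, so the
    observed classification is not forced by the data and is reported as
    degenerate.  Expensive (up to two LPs per reaction), hence opt-in.
    """
    from .flux_analysis import pfba, pinned_condition_model

    sides = []
    for constraints in (constraints_a, constraints_b):
        constrained, _, _ = pinned_condition_model(
            model, constraints, mapping, strategy=strategy, backend=backend
        )
        if constrained is None:
            raise ValueError("condition could not be pinned (LAD stage failed)")
        baseline = pfba(constrained, backend=backend)
        if not baseline.optimal:
            raise ValueError("baseline pFBA not optimal; cannot assess degeneracy")
        sides.append((constrained, baseline.objective_value))

    fragile: set[str] = set()
    by_id = {c.reaction_id: c for c in changes}
    for rxn_id, change in by_id.items():
        if change.classification == "unchanged":
            continue
        for (constrained, baseline_total), alt_flux in zip(
            sides, (change.flux_b, change.flux_a)
        ):
            rxn = constrained.reaction(rxn_id)
            if not (rxn.lower_bound - 1e-9 <= alt_flux <= rxn.upper_bound + 1e-9):
                continue
            pinned = constrained.with_bounds(
                {rxn_id: (alt_flux - 1e-9, alt_flux + 1e-9)}
            )
            re_solved = pfba(pinned, backend=backend)
            if re_solved.optimal and re_solved.objective_value <= baseline_total * (
                1 + objective_tol
            ) + objective_tol:
                fragile.add(rxn_id)
                break
    return fragile


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_change_table(changes: Sequence[FluxChange], path) -> None:
    frame = pd.DataFrame(
        {
            "reaction_id": [c.reaction_id for c in changes],
            "flux_a": [c.flux_a for c in changes],
            "flux_b": [c.flux_b for c in changes],
            "relative_change": [c.relative_change for c in changes],
            "class": [c.classification for c in changes],
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_pathway_summaries(summaries: Sequence[PathwaySummary], path) -> None:
    doc = {
        s.pathway: {"counts": s.counts, "members": s.members} for s in summaries
    }
    with open(path, "w") as handle:
        json.dump(doc, handle, indent=1)
        handle.write("\n")


def load_pathway_map(path) -> dict[str, str]:
    """Read a 2-column (reaction id, pathway label) delimited file."""
    out: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rxn_id, label = line.split("\t")
            out[rxn_id] = label
    return out
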