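"""FBA, parsimonious FBA and least-absolute-deviation flux fitting.

All three methods are expressed as one abstract linear program
(:class:`LinearProgram`) handed to a pluggable backend.  Two independent
backends are provided — scipy's HiGHS ``linprog`` (default) and GLPK through
optlang — so that any result can be cross-checked against a solver with a
completely separate code path.

Conventions
-----------
* steady state: S·v = 0, lb ≤ v ≤ ub
* exchange fluxes: negative = uptake, positive = secretion
* pFBA: among solutions with c·v ≥ optimum_fraction · Z*, minimise Σ|v|
* LAD: minimise Σ wᵢ·|vᵢ − v̂ᵢ| subject to steady state and bounds; a zero
  residual means the measured vector is jointly feasible and is reproduced
  exactly.

Absolute values are linearised with auxiliary variables tᵢ ≥ ±(expression),
which is exact at any LP optimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from .model_core import MetabolicModel, UnknownIdError, signed_rate

__all__ = [
    "LinearProgram",
    "FluxSolution",
    "LadReferences",
    "solve_lp",
    "fba",
    "pfba",
    "lad_fit",
    "condition_references",
    "simulate_condition",
    "write_solution",
    "read_solution",
]

FEASIBILITY_TOL = 1e-9
MASS_BALANCE_TOL = 1e-6


# ---------------------------------------------------------------------------
# Abstract LP + backends
# ---------------------------------------------------------------------------


@dataclass
class LinearProgram:
    """min c·x  s.t.  A_eq·x = b_eq,  A_ub·x ≤ b_ub,  lb ≤ x ≤ ub."""

    c: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    a_eq: sp.csr_matrix | None = None
    b_eq: np.ndarray | None = None
    a_ub: sp.csr_matrix | None = None
    b_ub: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.c)


def _solve_highs(lp: LinearProgram) -> tuple[str, np.ndarray | None, float | None]:
    res = scipy.optimize.linprog(
        lp.c,
        A_eq=lp.a_eq,
        b_eq=lp.b_eq,
        A_ub=lp.a_ub,
        b_ub=lp.b_ub,
        bounds=np.column_stack([lp.lb, lp.ub]),
        method="highs",
    )
    status = {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(res.status, "failed")
    if status != "optimal":
        return status, None, None
    return "optimal", np.asarray(res.x), float(res.fun)


def _solve_glpk(lp: LinearProgram) -> tuple[str, np.ndarray | None, float | None]:
    import optlang.glpk_interface as glpk

    model = glpk.Model()
    variables = [
        glpk.Variable(f"x{i}", lb=float(lp.lb[i]), ub=float(lp.ub[i]))
        for i in range(lp.n)
    ]
    model.add(variables)
    constraints = []

    def add_rows(matrix, rhs, equality):
        if matrix is None:
            return
        coo = matrix.tocoo()
        rows: dict[int, dict[int, float]] = {}
        for i, j, value in zip(coo.row, coo.col, coo.data):
            rows.setdefault(int(i), {})[int(j)] = rows.setdefault(int(i), {}).get(int(j), 0.0) + value
        for i in range(matrix.shape[0]):
            terms = rows.get(i, {})
            expr = sum(value * variables[j] for j, value in terms.items())
            bound = float(rhs[i])
            if equality:
                constraints.append(glpk.Constraint(expr, lb=bound, ub=bound))
            else:
                constraints.append(glpk.Constraint(expr, ub=bound))

    add_rows(lp.a_eq, lp.b_eq, equality=True)
    add_rows(lp.a_ub, lp.b_ub, equality=False)
    model.add(constraints)
    model.objective = glpk.Objective(
        sum(float(c) * v for c, v in zip(lp.c, variables) if c != 0.0), direction="min"
    )
    status = model.optimize()
    if status in ("infeasible", "undefined"):
        return "infeasible", None, None
    if status == "unbounded":
        return "unbounded", None, None
    if status != "optimal":
        return "failed", None, None
    x = np.array([v.primal for v in variables])
    return "optimal", x, float(model.objective.value)


_BACKENDS = {"highs": _solve_highs, "glpk": _solve_glpk}


def solve_lp(lp: LinearProgram, backend: str = "highs"):
    """Solve an abstract LP; returns (status, x or None, objective or None)."""
    try:
        solver = _BACKENDS[backend]
    except KeyError:
        raise ValueError(f"unknown LP backend {backend!r}; choose from {sorted(_BACKENDS)}")
    return solver(lp)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class FluxSolution:
    """A flux vector with solver status; units mmol/gDCW/h (growth h⁻¹)."""

    fluxes: dict[str, float]
    objective_value: float | None
    status: str
    method: str
    meta: dict = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]

    def mass_balance_residual(self, model: MetabolicModel) -> float:
        """max |S·v| over metabolites; ≤ 1e-6 for any optimal solution."""
        v = np.array([self.fluxes[r.id] for r in model.reactions])
        return float(np.max(np.abs(model.stoichiometric_matrix() @ v))) if len(v) else 0.0


@dataclass(frozen=True)
class LadReferences:
    """Measured reference fluxes v̂ and weights for LAD fitting."""

    references: Mapping[str, tuple[float, float]]  # id -> (value, weight)

    def __post_init__(self):
        clean = {}
        for rxn_id, entry in dict(self.references).items():
            if isinstance(entry, (int, float)):
                entry = (float(entry), 1.0)
            value, weight = entry
            if weight < 0:
                raise ValueError(f"negative LAD weight for {rxn_id}")
            clean[rxn_id] = (float(value), float(weight))
        object.__setattr__(self, "references", clean)

    def __len__(self):
        return len(self.references)

    def items(self):
        return self.references.items()


# ---------------------------------------------------------------------------
# Core methods
# ---------------------------------------------------------------------------


def _steady_state_lp(model: MetabolicModel, n_extra: int = 0) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """S·v = 0 rows padded with ``n_extra`` zero columns for auxiliaries."""
    S = sp.csr_matrix(model.stoichiometric_matrix())
    if n_extra:
        S = sp.hstack([S, sp.csr_matrix((S.shape[0], n_extra))]).tocsr()
    lb, ub = model.bounds()
    return S, lb, ub


def _solution(model, x, objective, status, method, meta) -> FluxSolution:
    fluxes = {} if x is None else {r.id: float(x[j]) for j, r in enumerate(model.reactions)}
    return FluxSolution(fluxes, objective, status, method, meta)


def fba(
    model: MetabolicModel,
    objective: str | None = None,
    sense: str = "max",
    backend: str = "highs",
) -> FluxSolution:
    """Flux balance analysis: optimise one reaction's flux at steady state."""
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    objective = objective or model.objective_reaction().id
    j_obj = model.reaction_ids.index(model.reaction(objective).id)
    n = len(model.reactions)
    S, lb, ub = _steady_state_lp(model)
    c = np.zeros(n)
    c[j_obj] = -1.0 if sense == "max" else 1.0
    status, x, fun = solve_lp(
        LinearProgram(c=c, lb=lb, ub=ub, a_eq=S, b_eq=np.zeros(S.shape[0])), backend
    )
    value = None if fun is None else (-fun if sense == "max" else fun)
    return _solution(model, x, value, status, "fba", {"objective_reaction": objective, "sense": sense, "backend": backend})


def pfba(
    model: MetabolicModel,
    objective: str | None = None,
    optimum_fraction: float = 1.0,
    backend: str = "highs",
) -> FluxSolution:
    """Parsimonious FBA: fix c·v ≥ optimum_fraction·Z*, then minimise Σ|v|.

    The returned ``objective_value`` is the minimal total absolute flux; the
    stage-1 optimum is recorded in ``meta["fba_objective"]``.
    """
    if not 0 < optimum_fraction <= 1:
        raise ValueError("optimum_fraction must lie in (0, 1]")
    stage1 = fba(model, objective=objective, sense="max", backend=backend)
    if not stage1.optimal:
        return FluxSolution({}, None, stage1.status, "pfba", dict(stage1.meta))
    z_star = stage1.objective_value
    objective = stage1.meta["objective_reaction"]
    j_obj = model.reaction_ids.index(objective)

    n = len(model.reactions)
    S, lb, ub = _steady_state_lp(model, n_extra=n)
    # variables: v (n) then t (n) with t_j >= |v_j|
    lb_all = np.concatenate([lb, np.zeros(n)])
    ub_all = np.concatenate([ub, np.full(n, np.inf)])
    eye = sp.identity(n, format="csr")
    # v - t <= 0 ; -v - t <= 0 ; -c·v <= -fraction*Z*
    growth_row = sp.csr_matrix(
        (np.array([-1.0]), (np.array([0]), np.array([j_obj]))), shape=(1, 2 * n)
    )
    a_ub = sp.vstack(
        [
            sp.hstack([eye, -eye]),
            sp.hstack([-eye, -eye]),
            growth_row,
        ]
    ).tocsr()
    b_ub = np.concatenate([np.zeros(2 * n), [-optimum_fraction * z_star]])
    c = np.concatenate([np.zeros(n), np.ones(n)])
    status, x, fun = solve_lp(
        LinearProgram(c=c, lb=lb_all, ub=ub_all, a_eq=S, b_eq=np.zeros(S.shape[0]), a_ub=a_ub, b_ub=b_ub),
        backend,
    )
    meta = {
        "objective_reaction": objective,
        "fba_objective": z_star,
        "optimum_fraction": optimum_fraction,
        "backend": backend,
    }
    return _solution(model, None if x is None else x[:n], fun, status, "pfba", meta)


def lad_fit(
    model: MetabolicModel,
    refs: LadReferences,
    backend: str = "highs",
) -> FluxSolution:
    """Least-absolute-deviation fit of fluxes to measured reference rates.

    Minimises Σ wᵢ·|vᵢ − v̂ᵢ| over the flux polytope.  With a jointly
    feasible reference vector the residual is exactly zero and every
    referenced flux equals its reference.
    """
    if len(refs) == 0:
        raise ValueError("LAD requires at least one reference flux")
    for rxn_id in refs.references:
        if not model.has_reaction(rxn_id):
            raise UnknownIdError(f"LAD reference on unknown reaction {rxn_id!r}")
    n = len(model.reactions)
    ref_ids = list(refs.references)
    m = len(ref_ids)
    ref_cols = np.array([model.reaction_ids.index(r) for r in ref_ids])
    ref_vals = np.array([refs.references[r][0] for r in ref_ids])
    weights = np.array([refs.references[r][1] for r in ref_ids])

    S, lb, ub = _steady_state_lp(model, n_extra=m)
    lb_all = np.concatenate([lb, np.zeros(m)])
    ub_all = np.concatenate([ub, np.full(m, np.inf)])
    # deviations: t_i >= v_i - ref_i and t_i >= ref_i - v_i
    rows = np.repeat(np.arange(m), 1)
    pick = sp.csr_matrix((np.ones(m), (rows, ref_cols)), shape=(m, n))
    eye = sp.identity(m, format="csr")
    a_ub = sp.vstack([sp.hstack([pick, -eye]), sp.hstack([-pick, -eye])]).tocsr()
    b_ub = np.concatenate([ref_vals, -ref_vals])
    c = np.concatenate([np.zeros(n), weights])
    status, x, fun = solve_lp(
        LinearProgram(c=c, lb=lb_all, ub=ub_all, a_eq=S, b_eq=np.zeros(S.shape[0]), a_ub=a_ub, b_ub=b_ub),
        backend,
    )
    meta = {"references": {r: refs.references[r] for r in ref_ids}, "backend": backend}
    return _solution(model, None if x is None else x[:n], fun, status, "lad", meta)


# ---------------------------------------------------------------------------
# Condition simulation (the per-condition pipeline stage)
# ---------------------------------------------------------------------------


def condition_references(
    model: MetabolicModel,
    constraints,
    mapping: Mapping[str, str],
    include_growth: bool = True,
    weight: float = 1.0,
) -> LadReferences:
    """Turn one condition's measured rates into signed LAD references."""
    refs: dict[str, tuple[float, float]] = {}
    for species, (magnitude, direction) in constraints.rates.items():
        if species not in mapping:
            raise UnknownIdError(f"no exchange-reaction mapping for species {species!r}")
        refs[mapping[species]] = (signed_rate(magnitude, direction), weight)
    if include_growth:
        refs[model.objective_reaction().id] = (constraints.growth_rate, weight)
    return LadReferences(refs)


def pinned_condition_model(
    model: MetabolicModel,
    constraints,
    mapping: Mapping[str, str],
    strategy: str = "lad-then-pfba",
    backend: str = "highs",
    pin_tol: float = FEASIBILITY_TOL,
):
    """Model with one condition's six rates pinned as hard bounds.

    Returns ``(constrained model, pinned values, LAD residual or None)``;
    the pinned values are LAD-fitted under ``lad-then-pfba`` and the raw
    measurements under ``hard-pfba``.
    """
    if strategy not in ("lad-then-pfba", "hard-pfba"):
        raise ValueError(f"unknown strategy {strategy!r}")
    refs = condition_references(model, constraints, mapping, include_growth=True)
    if strategy == "lad-then-pfba":
        lad = lad_fit(model, refs, backend=backend)
        if not lad.optimal:
            return None, None, lad
        pinned = {rxn_id: lad.flux(rxn_id) for rxn_id in refs.references}
        lad_residual = lad.objective_value
    else:
        pinned = {rxn_id: value for rxn_id, (value, _) in refs.items()}
        lad_residual = None
    constrained = model.with_bounds(
        {rxn_id: (value - pin_tol, value + pin_tol) for rxn_id, value in pinned.items()}
    )
    return constrained, pinned, lad_residual


def simulate_condition(
    model: MetabolicModel,
    constraints,
    mapping: Mapping[str, str],
    strategy: str = "lad-then-pfba",
    optimum_fraction: float = 1.0,
    backend: str = "highs",
    pin_tol: float = FEASIBILITY_TOL,
) -> FluxSolution:
    """Reconcile one condition's measured rates with the model and solve pFBA.

    ``lad-then-pfba`` first LAD-fits the six measured rates (five exchanges
    plus growth), then pins the fitted values as hard bounds and runs pFBA on
    growth.  ``hard-pfba`` pins the measured values directly.  Both stage
    objectives are recorded in ``meta``.
    """
    growth_id = model.objective_reaction().id
    constrained, pinned, lad_residual = pinned_condition_model(
        model, constraints, mapping, strategy=strategy, backend=backend, pin_tol=pin_tol
    )
    if constrained is None:
        return FluxSolution({}, None, lad_residual.status, strategy, {"stage": "lad"})

    parsimonious = pfba(
        constrained, objective=growth_id, optimum_fraction=optimum_fraction, backend=backend
    )
    meta = dict(parsimonious.meta)
    meta.update(
        strategy=strategy,
        lad_residual=lad_residual,
        pfba_total_flux=parsimonious.objective_value,
        pinned=pinned,
        condition=getattr(constraints, "label", None),
    )
    return FluxSolution(
        parsimonious.fluxes,
        parsimonious.objective_value,
        parsimonious.status,
        strategy,
        meta,
    )


# ---------------------------------------------------------------------------
# Solution I/O: 2-column table + JSON header
# ---------------------------------------------------------------------------


def write_solution(solution: FluxSolution, table_path, header_path=None) -> None:
    """Write fluxes as a 2-column TSV plus a JSON sidecar with metadata."""
    with open(table_path, "w") as handle:
        handle.write("reaction_id\tflux\n")
        for rxn_id in sorted(solution.fluxes):
            handle.write(f"{rxn_id}\t{solution.fluxes[rxn_id]:.12g}\n")
    if header_path is not None:
        header = {
            "status": solution.status,
            "method": solution.method,
            "objective_value": solution.objective_value,
            "meta": _jsonable(solution.meta),
        }
        with open(header_path, "w") as handle:
            json.dump(header, handle, indent=1)
            handle.write("\n")


def read_solution(table_path, header_path=None) -> FluxSolution:
    fluxes = {}
    with open(table_path) as handle:
        next(handle)  # header row
        for line in handle:
            rxn_id, value = line.rstrip("\n").split("\t")
            fluxes[rxn_id] = float(value)
    status, method, objective, meta = "optimal", "file", None, {}
    if header_path is not None:
        with open(header_path) as handle:
            header = json.load(handle)
        status = header.get("status", status)
        method = header.get("method", method)
        objective = header.get("objective_value")
        meta = header.get("meta", {})
    return FluxSolution(fluxes, objective, status, method, meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
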