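"""SBML Level 3 + FBC reader/writer (secondary model dialect).

Thin adapters between :class:`~gabaflux.model_core.MetabolicModel` and
libsbml.  Flux bounds travel as FBC parameters, GPRs as gene-product
associations, the objective as the active FBC objective.  Identifiers are
round-tripped through standard SBML id mangling (``M_``/``R_``/``G_``
prefixes, ``__`` escapes for characters SBML ids forbid).
"""

from __future__ import annotations

import libsbml

from .model_core import (
    GprExpression,
    Metabolite,
    MetabolicModel,
    ModelFormatError,
    Reaction,
)

_SBML_BAD = {"-": "__DASH__", ".": "__FULLSTOP__"}


def _encode_id(prefix: str, raw: str) -> str:
    out = raw
    for char, escape in _SBML_BAD.items():
        out = out.replace(char, escape)
    return prefix + out


def _decode_id(prefix: str, sid: str) -> str:
    out = sid[len(prefix):] if sid.startswith(prefix) else sid
    for char, escape in _SBML_BAD.items():
        out = out.replace(escape, char)
    return out


def _gpr_from_association(assoc) -> GprExpression | None:
    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        gene = assoc.getGeneProduct()
        return GprExpression("gene", (_decode_id("G_", gene),))
    if assoc.isFbcAnd():
        children = tuple(
            _gpr_from_association(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        )
        return GprExpression("and", children)
    if assoc.isFbcOr():
        children = tuple(
            _gpr_from_association(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        )
        return GprExpression("or", children)
    raise ModelFormatError("unsupported FBC gene association node")


def read_sbml(path: str) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        first = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(f"{path}: {first.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError(f"{path}: no <model> element")
    fbc = sbml_model.getPlugin("fbc")

    parameters = {
        p.getId(): p.getValue() for p in (sbml_model.getParameter(i) for i in range(sbml_model.getNumParameters()))
    }

    metabolites = [
        Metabolite(
            id=_decode_id("M_", species.getId()),
            name=species.getName(),
            compartment=species.getCompartment(),
            formula=(species.getPlugin("fbc").getChemicalFormula() or None)
            if species.getPlugin("fbc")
            else None,
        )
        for species in (sbml_model.getSpecies(i) for i in range(sbml_model.getNumSpecies()))
    ]

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        sbml_rxn = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sbml_rxn.getNumReactants()):
            ref = sbml_rxn.getReactant(j)
            met = _decode_id("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(sbml_rxn.getNumProducts()):
            ref = sbml_rxn.getProduct(j)
            met = _decode_id("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        rxn_fbc = sbml_rxn.getPlugin("fbc")
        if rxn_fbc is None:
            raise ModelFormatError(f"{path}: reaction {sbml_rxn.getId()} lacks FBC bounds")
        lb = parameters.get(rxn_fbc.getLowerFluxBound(), -1000.0)
        ub = parameters.get(rxn_fbc.getUpperFluxBound(), 1000.0)
        gpa = rxn_fbc.getGeneProductAssociation()
        gpr = _gpr_from_association(gpa.getAssociation()) if gpa is not None else None
        reactions.append(
            Reaction(
                id=_decode_id("R_", sbml_rxn.getId()),
                name=sbml_rxn.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
            )
        )

    genes = []
    objective = None
    if fbc is not None:
        genes = [
            _decode_id("G_", fbc.getGeneProduct(i).getId())
            for i in range(fbc.getNumGeneProducts())
        ]
        active = fbc.getActiveObjective()
        if active is not None and active.getNumFluxObjectives() > 0:
            objective = _decode_id("R_", active.getFluxObjective(0).getReaction())

    compartments = {
        sbml_model.getCompartment(i).getId(): sbml_model.getCompartment(i).getName()
        for i in range(sbml_model.getNumCompartments())
    }
    return MetabolicModel(
        id=sbml_model.getId() or "model",
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        objective_reaction_id=objective,
        compartments=compartments,
    )


def _association_from_gpr(fbc_rxn, gpr: GprExpression):
    gpa = fbc_rxn.createGeneProductAssociation()

    def build(node: GprExpression, parent):
        if node.op == "gene":
            ref = parent.createGeneProductRef()
            ref.setGeneProduct(_encode_id("G_", node.children[0]))
            return
        branch = parent.createAnd() if node.op == "and" else parent.createOr()
        for child in node.children:
            build(child, branch)

    if gpr.op == "gene":
        ref = gpa.createGeneProductRef()
        ref.setGeneProduct(_encode_id("G_", gpr.children[0]))
    else:
        branch = gpa.createAnd() if gpr.op == "and" else gpa.createOr()
        for child in gpr.children:
            build(child, branch)


def write_sbml(model: MetabolicModel, path: str) -> None:
    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    model_fbc = sbml_model.getPlugin("fbc")
    model_fbc.setStrict(True)

    compartments = set(m.compartment or "c" for m in model.metabolites)
    for comp_id in sorted(compartments):
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setName(model.compartments.get(comp_id, comp_id))
        comp.setConstant(True)

    for met in model.metabolites:
        species = sbml_model.createSpecies()
        species.setId(_encode_id("M_", met.id))
        species.setName(met.name)
        species.setCompartment(met.compartment or "c")
        species.setHasOnlySubstanceUnits(False)
        species.setBoundaryCondition(False)
        species.setConstant(False)
        if met.formula:
            species.getPlugin("fbc").setChemicalFormula(met.formula)

    for gene in model.genes:
        product = model_fbc.createGeneProduct()
        product.setId(_encode_id("G_", gene))
        product.setLabel(gene)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            param = sbml_model.createParameter()
            param.setId(pid)
            param.setValue(value)
            param.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        sbml_rxn = sbml_model.createReaction()
        sbml_rxn.setId(_encode_id("R_", rxn.id))
        sbml_rxn.setName(rxn.name)
        sbml_rxn.setFast(False)
        sbml_rxn.setReversible(rxn.lower_bound < 0)
        for met_id, coeff in sorted(rxn.stoichiometry.items()):
            ref = sbml_rxn.createReactant() if coeff < 0 else sbml_rxn.createProduct()
            ref.setSpecies(_encode_id("M_", met_id))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rxn_fbc = sbml_rxn.getPlugin("fbc")
        rxn_fbc.setLowerFluxBound(bound_param(rxn.lower_bound))
        rxn_fbc.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr is not None:
            _association_from_gpr(rxn_fbc, rxn.gpr)

    if model.objective_reaction_id is not None:
        objective = model_fbc.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        flux_obj = objective.createFluxObjective()
        flux_obj.setReaction(_encode_id("R_", model.objective_reaction_id))
        flux_obj.setCoefficient(1.0)
        model_fbc.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")
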