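"""SBML import/export for :class:`~panflux.model.MetabolicModel`.

Reads two dialects:

* SBML Level 3 with the ``fbc`` package — flux bounds as referenced
  parameters, gene associations as ``fbc:geneProductAssociation`` trees,
  objective as ``fbc:listOfObjectives``;
* legacy SBML Level 2 — bounds as ``LOWER_BOUND``/``UPPER_BOUND`` kinetic
  law parameters and gene associations / subsystems embedded in reaction
  notes (``GENE_ASSOCIATION: ...``, ``SUBSYSTEM: ...``), the encoding
  used by constraint-based reconstructions that predate fbc.

Always writes Level 3 + fbc version 2 with an explicit maximize-biomass
objective, so the emitted files load directly into other constraint-based
toolchains.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional

import libsbml

from . import gpr as gpr_mod
from .gpr import And, Gene, Gpr, Or, parse_gpr
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "read_sbml",
    "write_sbml",
    "SBMLFormatError",
    "BiomassNotFoundError",
    "BiomassAmbiguityError",
    "DEFAULT_BIOMASS_PATTERN",
]

DEFAULT_BIOMASS_PATTERN = r"biomass"

_DEFAULT_BOUND = 1000.0


class SBMLFormatError(ValueError):
    """The file is not parseable SBML or lacks required structure."""


class BiomassNotFoundError(ValueError):
    """No reaction matched the biomass pattern and no objective was set."""


class BiomassAmbiguityError(ValueError):
    """More than one reaction matched the biomass id pattern."""


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _notes_field(notes: Optional[str], key: str) -> Optional[str]:
    if not notes:
        return None
    m = re.search(rf"{key}:\s*([^<\n]*)", notes, flags=re.IGNORECASE)
    if m:
        value = m.group(1).strip()
        return value or None
    return None


def read_sbml(
    path: str,
    biomass_pattern: str = DEFAULT_BIOMASS_PATTERN,
) -> MetabolicModel:
    """Load an SBML file into a :class:`MetabolicModel`.

    The biomass reaction is taken from the active fbc objective when one
    is present; otherwise *biomass_pattern* is matched (case-insensitive)
    against reaction ids, then names.  Zero candidates raise
    :class:`BiomassNotFoundError` listing the reaction ids, several raise
    :class:`BiomassAmbiguityError`.
    """
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise SBMLFormatError(f"SBML parse failure in {path}: " + "; ".join(msgs))
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLFormatError(f"no model element in {path}")

    mplug = sbml_model.getPlugin("fbc")

    # gene product id -> label (fbc); labels carry the raw locus tags
    gene_labels = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            label = gp.getLabel() or _strip_prefix(gp.getId(), "G_")
            gene_labels[gp.getId()] = label

    boundary = set()
    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            boundary.add(sp.getId())
            continue
        formula = None
        splug = sp.getPlugin("fbc")
        if splug is not None and splug.isSetChemicalFormula():
            formula = splug.getChemicalFormula()
        if formula is None:
            formula = _notes_field(sp.getNotesString(), "FORMULA")
        metabolites.append(
            Metabolite(
                id=_strip_prefix(sp.getId(), "M_"),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
                formula=formula,
            )
        )

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            if ref.getSpecies() in boundary:
                continue
            met = _strip_prefix(ref.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            if ref.getSpecies() in boundary:
                continue
            met = _strip_prefix(ref.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0.0}
        if not stoich:
            continue  # pure boundary-to-boundary reaction carries no constraint

        lb, ub = _read_bounds(rxn, sbml_model)
        gpr = _read_gpr(rxn, gene_labels)
        notes = rxn.getNotesString()
        subsystem = _notes_field(notes, "SUBSYSTEM") or ""
        reactions.append(
            Reaction(
                id=_strip_prefix(rxn.getId(), "R_"),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                name=rxn.getName() or "",
                subsystem=subsystem,
            )
        )

    biomass_id = _find_biomass(sbml_model, mplug, reactions, biomass_pattern)
    return MetabolicModel(
        id=sbml_model.getId() or sbml_model.getName() or "model",
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=biomass_id,
    )


def _read_bounds(rxn, sbml_model):
    rplug = rxn.getPlugin("fbc")
    lb = ub = None
    if rplug is not None:
        if rplug.isSetLowerFluxBound():
            p = sbml_model.getParameter(rplug.getLowerFluxBound())
            if p is not None:
                lb = p.getValue()
        if rplug.isSetUpperFluxBound():
            p = sbml_model.getParameter(rplug.getUpperFluxBound())
            if p is not None:
                ub = p.getValue()
    if lb is None or ub is None:
        kl = rxn.getKineticLaw()
        if kl is not None:
            for j in range(kl.getNumParameters()):
                p = kl.getParameter(j)
                if p.getId().upper() == "LOWER_BOUND" and lb is None:
                    lb = p.getValue()
                elif p.getId().upper() == "UPPER_BOUND" and ub is None:
                    ub = p.getValue()
    if lb is None:
        lb = -_DEFAULT_BOUND if rxn.getReversible() else 0.0
    if ub is None:
        ub = _DEFAULT_BOUND
    return lb, ub


def _read_gpr(rxn, gene_labels):
    rplug = rxn.getPlugin("fbc")
    if rplug is not None and rplug.isSetGeneProductAssociation():
        assoc = rplug.getGeneProductAssociation().getAssociation()
        if assoc is not None:
            return _association_to_gpr(assoc, gene_labels)
    text = _notes_field(rxn.getNotesString(), r"GENE[_ ]?ASSOCIATION")
    if text and text.lower() not in ("none", "n/a", "-"):
        return parse_gpr(text)
    return None


def _association_to_gpr(assoc, gene_labels):
    if assoc.isGeneProductRef():
        gp_id = assoc.getGeneProduct()
        return Gene(gene_labels.get(gp_id, _strip_prefix(gp_id, "G_")))
    children = [
        _association_to_gpr(assoc.getAssociation(i), gene_labels)
        for i in range(assoc.getNumAssociations())
    ]
    if assoc.isFbcAnd():
        return And(*children)
    if assoc.isFbcOr():
        return Or(*children)
    raise SBMLFormatError(f"unsupported fbc association node: {assoc}")


def _find_biomass(sbml_model, mplug, reactions, pattern):
    # 1) active fbc objective with a single flux objective
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() == 1:
            rid = _strip_prefix(obj.getFluxObjective(0).getReaction(), "R_")
            if any(r.id == rid for r in reactions):
                return rid
    # 2) configurable id/name pattern
    rx = re.compile(pattern, flags=re.IGNORECASE)
    by_id = [r.id for r in reactions if rx.search(r.id)]
    if len(by_id) == 1:
        return by_id[0]
    if len(by_id) > 1:
        raise BiomassAmbiguityError(
            f"pattern {pattern!r} matches several reaction ids: {sorted(by_id)}"
        )
    by_name = [r.id for r in reactions if rx.search(r.name)]
    if len(by_name) == 1:
        return by_name[0]
    if len(by_name) > 1:
        raise BiomassAmbiguityError(
            f"pattern {pattern!r} matches several reaction names: {sorted(by_name)}"
        )
    raise BiomassNotFoundError(
        f"no reaction matches biomass pattern {pattern!r}; reaction ids: "
        + ", ".join(sorted(r.id for r in reactions))
    )


# ---------------------------------------------------------------------------
# writing

_SID_RE = re.compile(r"[^A-Za-z0-9_]")


def _sid(raw: str, prefix: str) -> str:
    safe = _SID_RE.sub("_", raw)
    if not safe or not (safe[0].isalpha() or safe[0] == "_"):
        safe = "_" + safe
    return prefix + safe


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write *model* as SBML Level 3 Version 1 with fbc version 2.

    Ids are emitted with the conventional ``M_``/``R_``/``G_`` prefixes;
    gene products carry the raw gene id in their ``fbc:label`` so the GPR
    round-trips exactly.  Reactions without a gene association get no
    ``geneProductAssociation`` element.  Subsystems are stored in
    reaction notes.
    """
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_SID_RE.sub("_", model.id))
    sm.setName(model.id)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in sorted({m.compartment for m in model.metabolites.values()}):
        comp = sm.createCompartment()
        comp.setId(_SID_RE.sub("_", comp_id))
        comp.setConstant(True)

    for met in sorted(model.metabolites.values(), key=lambda m: m.id):
        sp = sm.createSpecies()
        sp.setId(_sid(met.id, "M_"))
        if met.name:
            sp.setName(met.name)
        sp.setCompartment(_SID_RE.sub("_", met.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        if met.formula:
            sp.getPlugin("fbc").setChemicalFormula(met.formula)

    # one constant parameter per distinct bound value (fbc-strict style)
    bound_params = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    gene_ids = {}
    for g in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gid = _sid(g, "G_")
        gp.setId(gid)
        gp.setLabel(g)
        gene_ids[g] = gid

    for rxn in sorted(model.reactions.values(), key=lambda r: r.id):
        sr = sm.createReaction()
        sr.setId(_sid(rxn.id, "R_"))
        if rxn.name:
            sr.setName(rxn.name)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for met_id, coef in sorted(rxn.stoichiometry.items()):
            if coef < 0:
                ref = sr.createReactant()
                ref.setStoichiometry(-coef)
            else:
                ref = sr.createProduct()
                ref.setStoichiometry(coef)
            ref.setSpecies(_sid(met_id, "M_"))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr is not None:
            gpa = rplug.createGeneProductAssociation()
            _build_association(gpa, rxn.gpr, gene_ids)
        if rxn.subsystem:
            sr.setNotes(
                "<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>SUBSYSTEM: {rxn.subsystem}</p></body>"
            )

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(_sid(model.biomass_reaction_id, "R_"))
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise OSError(f"could not write SBML to {path}")


def _build_association(parent, gpr: Gpr, gene_ids) -> None:
    if isinstance(gpr, Gene):
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(gene_ids[gpr.id])
        return
    node = parent.createAnd() if isinstance(gpr, And) else parent.createOr()
    for child in gpr.children:
        _build_association(node, child, gene_ids)


def sbml_string(model: MetabolicModel) -> str:
    """Serialize to an SBML string (same content as :func:`write_sbml`)."""
    import os
    import tempfile

    with tempfile.NamedTemporaryFile("r", suffix=".xml", delete=False) as fh:
        tmp = fh.name
    try:
        write_sbml(model, tmp)
        with open(tmp) as fh2:
            return fh2.read()
    finally:
        os.unlink(tmp)
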