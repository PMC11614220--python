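"""SBML Level 3 Version 1 read/write for :class:`MetabolicNetwork`.

Conventions: boundary metabolites carry ``boundaryCondition="true"`` (a
species placed in a compartment named/id'd ``external`` is also treated as
boundary on read); flux bounds are stored as the classic ``LOWER_BOUND`` /
``UPPER_BOUND`` local parameters of a trivial kinetic law, and fbc-package
bounds are honoured on read when present.  Metabolite and reaction order
follows the document listing order, so loading is deterministic.
"""

from __future__ import annotations

import math
from typing import Dict

import libsbml

from .model import (
    DEFAULT_BOUND,
    MetabolicNetwork,
    Metabolite,
    NetworkValidationError,
    Reaction,
)

__all__ = ["read_sbml", "write_sbml", "SBMLParseError"]

_COMPARTMENT_IDS = {"external": "e", "cytosol": "c", "mitochondrion": "m"}
_COMPARTMENT_NAMES = {
    "e": "external",
    "ext": "external",
    "external": "external",
    "extracellular": "external",
    "c": "cytosol",
    "cyt": "cytosol",
    "cytosol": "cytosol",
    "cytoplasm": "cytosol",
    "m": "mitochondrion",
    "mit": "mitochondrion",
    "mito": "mitochondrion",
    "mitochondrion": "mitochondrion",
    "mitochondria": "mitochondrion",
}


class SBMLParseError(ValueError):
    pass


def _resolve_compartment(comp_id: str, doc_names: Dict[str, str]) -> str:
    for key in (comp_id, doc_names.get(comp_id, "")):
        name = _COMPARTMENT_NAMES.get(key.strip().lower())
        if name:
            return name
    raise NetworkValidationError(f"unknown compartment {comp_id!r}")


def read_sbml(path: str) -> MetabolicNetwork:
    """Load an SBML file into a :class:`MetabolicNetwork`."""
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLParseError(
            f"{path}: line {err.getLine()}: {err.getMessage().strip()}"
        )
    model = doc.getModel()
    if model is None:
        raise SBMLParseError(f"{path}: document contains no <model> element")

    comp_names = {
        c.getId(): (c.getName() or c.getId()) for c in model.getListOfCompartments()
    }
    metabolites = []
    for sp in model.getListOfSpecies():
        compartment = _resolve_compartment(sp.getCompartment(), comp_names)
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or sp.getId(),
                compartment=compartment,
                is_boundary=bool(sp.getBoundaryCondition()) or compartment == "external",
            )
        )

    reactions = []
    for rxn in model.getListOfReactions():
        stoich: Dict[str, float] = {}
        for ref in rxn.getListOfReactants():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for ref in rxn.getListOfProducts():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        lb, ub = _read_bounds(model, rxn)
        reactions.append(
            Reaction(
                id=rxn.getId(),
                stoichiometry=stoich,
                reversible=bool(rxn.getReversible()),
                lower_bound=lb,
                upper_bound=ub,
                name=rxn.getName() or rxn.getId(),
            )
        )
    return MetabolicNetwork(
        metabolites=metabolites, reactions=reactions, name=model.getId() or ""
    )


def _read_bounds(model, rxn):
    lb = ub = None
    kl = rxn.getKineticLaw()
    if kl is not None:
        for i in range(kl.getNumLocalParameters()):
            p = kl.getLocalParameter(i)
            if p.getId() == "LOWER_BOUND":
                lb = p.getValue()
            elif p.getId() == "UPPER_BOUND":
                ub = p.getValue()
    fbc = rxn.getPlugin("fbc")
    if fbc is not None:
        for attr, ref in (("lb", fbc.getLowerFluxBound()), ("ub", fbc.getUpperFluxBound())):
            if ref:
                param = model.getParameter(ref)
                if param is not None:
                    if attr == "lb":
                        lb = param.getValue()
                    else:
                        ub = param.getValue()
    if lb is not None and math.isinf(lb):
        lb = -DEFAULT_BOUND
    if ub is not None and math.isinf(ub):
        ub = DEFAULT_BOUND
    return lb, ub


def write_sbml(network: MetabolicNetwork, path: str) -> None:
    """Write ``network`` as SBML L3V1 (round-trips through :func:`read_sbml`)."""
    network.validate()
    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId(network.name or "model")

    used = {m.compartment for m in network.metabolites}
    for comp in sorted(used):
        c = model.createCompartment()
        c.setId(_COMPARTMENT_IDS[comp])
        c.setName(comp)
        c.setConstant(True)

    for m in network.metabolites:
        sp = model.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name or m.id)
        sp.setCompartment(_COMPARTMENT_IDS[m.compartment])
        sp.setBoundaryCondition(bool(m.is_boundary))
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)

    for r in network.reactions:
        rxn = model.createReaction()
        rxn.setId(r.id)
        rxn.setName(r.name or r.id)
        rxn.setReversible(bool(r.reversible))
        rxn.setFast(False)
        for met, coef in sorted(r.stoichiometry.items()):
            ref = rxn.createReactant() if coef < 0 else rxn.createProduct()
            ref.setSpecies(met)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        kl = rxn.createKineticLaw()
        kl.setMath(libsbml.parseL3Formula("FLUX_VALUE"))
        for pid, value in (("FLUX_VALUE", 0.0), ("LOWER_BOUND", r.lower_bound), ("UPPER_BOUND", r.upper_bound)):
            p = kl.createLocalParameter()
            p.setId(pid)
            p.setValue(float(value))

    ok = libsbml.writeSBMLToFile(doc, str(path))
    if not ok:
        raise IOError(f"could not write SBML to {path}")
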