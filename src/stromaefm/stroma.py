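"""Stroma formation: collagen, inflammation and angiogenesis reactions.

The tumoral stroma is modelled through three protein products — collagen
(extracellular matrix), IL1-beta / TNF-alpha (inflammation) and VEGF-A
(neoangiogenesis) — produced by redirecting amino-acid metabolism:

* collagen polypeptides are assembled as 100-residue bricks (``CBS``) with
  the canonical residue distribution 33% Gly, 2x 8.5% Pro/Hyp and 50%
  "X-Y" residues drawn equiprobably from eight amino-acid pools
  (``XYAAS``), then polymerised (``COLLAG``);
* each marker protein has a synthesis reaction whose reactant coefficients
  are the residue proportions of its consensus sequence and whose product
  coefficient is the inverse of the protein length;
* stroma release requires one inflammation marker *and* the growth factor
  simultaneously (``INF1``/``INF2``/``FACT``/``STROMA``).

``build_stroma_extension`` grafts these reactions (plus the proline,
histidine, alanine and asparagine transport/metabolism the base model
lacks) onto a core-metabolism network.
"""

from __future__ import annotations

from typing import Dict, Mapping

from .model import MetabolicNetwork, Metabolite, NetworkValidationError, Reaction

__all__ = [
    "protein_synthesis_reaction",
    "build_stroma_extension",
    "PROTEIN_COMPOSITIONS",
    "PRINTED_PROTEIN_REACTIONS",
    "STROMA_REACTION_IDS",
]

#: amino-acid pool metabolites protein synthesis may draw on
AMINO_ACID_POOLS = (
    "MET", "ALAc", "GLUTc", "TIV", "PROc", "YFLKW", "SERc",
    "GLYc", "ASNc", "ASPc", "GLNc", "CYSc", "ARGc", "HISc",
)

#: residue counts of the consensus sequences (UniProt IL1B/TNFA/VEGFA_HUMAN),
#: conflated onto the model's pooled amino acids; lengths 269 / 233 / 232
PROTEIN_COMPOSITIONS: Dict[str, Dict[str, int]] = {
    "IL1B": {
        "MET": 12, "ALAc": 13, "GLUTc": 21, "TIV": 35, "PROc": 15,
        "YFLKW": 74, "SERc": 21, "GLYc": 13, "ASNc": 12, "ASPc": 20,
        "GLNc": 18, "CYSc": 5, "ARGc": 6, "HISc": 4,
    },
    "TNFA": {
        "MET": 2, "SERc": 20, "TIV": 38, "GLUTc": 16, "ARGc": 14,
        "ASPc": 7, "YFLKW": 57, "ALAc": 19, "PROc": 15, "GLYc": 17,
        "GLNc": 13, "CYSc": 4, "HISc": 4, "ASNc": 7,
    },
    "VEGFA": {
        "MET": 8, "ASNc": 7, "YFLKW": 55, "SERc": 15, "TIV": 25,
        "HISc": 11, "ALAc": 8, "GLNc": 13, "PROc": 15, "GLUTc": 16,
        "GLYc": 14, "ASPc": 8, "ARGc": 19, "CYSc": 18,
    },
}

#: the marker-protein reactions with coefficients exactly as published for
#: the model (residue proportions rounded to 3 decimals, product coefficient
#: = inverse length truncated to 5 decimals)
PRINTED_PROTEIN_REACTIONS: Dict[str, Dict[str, float]] = {
    "IL1B": {
        "MET": -0.045, "ALAc": -0.048, "GLUTc": -0.078, "TIV": -0.13,
        "PROc": -0.056, "YFLKW": -0.275, "SERc": -0.078, "GLYc": -0.048,
        "ASNc": -0.045, "ASPc": -0.074, "GLNc": -0.067, "CYSc": -0.019,
        "ARGc": -0.022, "HISc": -0.015, "IL1B": 0.00371,
    },
    "TNFA": {
        "MET": -0.009, "SERc": -0.086, "TIV": -0.163, "GLUTc": -0.069,
        "ARGc": -0.06, "ASPc": -0.03, "YFLKW": -0.245, "ALAc": -0.082,
        "PROc": -0.064, "GLYc": -0.073, "GLNc": -0.056, "CYSc": -0.017,
        "HISc": -0.017, "ASNc": -0.03, "TNFA": 0.00429,
    },
    "VEGFA": {
        "MET": -0.034, "ASNc": -0.03, "YFLKW": -0.237, "SERc": -0.065,
        "TIV": -0.108, "HISc": -0.047, "ALAc": -0.034, "GLNc": -0.056,
        "PROc": -0.065, "GLUTc": -0.069, "GLYc": -0.06, "ASPc": -0.034,
        "ARGc": -0.082, "CYSc": -0.078, "VEGFA": 0.00431,
    },
}

STROMA_REACTION_IDS = (
    "CBS", "COLLAG", "XYAAS", "IL1B", "TNFA", "VEGFA",
    "FACT", "INF1", "INF2", "STROMA", "EX_COLLAGEN", "EX_STROMA",
)


def protein_synthesis_reaction(
    name: str, composition: Mapping[str, int], length: int
) -> Reaction:
    """Protein synthesis with residue-proportion stoichiometry.

    Reactant coefficients are ``count / length`` (they sum to exactly 1)
    and the single product carries coefficient ``1 / length`` — one flux
    unit consumes one residue's worth of amino-acid pool.
    """
    if length <= 0:
        raise NetworkValidationError("protein length must be positive")
    unknown = set(composition) - set(AMINO_ACID_POOLS)
    if unknown:
        raise NetworkValidationError(
            f"unknown amino-acid pools in composition: {sorted(unknown)}"
        )
    total = sum(composition.values())
    if total != length:
        raise NetworkValidationError(
            f"residue counts sum to {total}, expected length {length}"
        )
    stoich: Dict[str, float] = {
        pool: -count / length for pool, count in composition.items() if count
    }
    stoich[name] = 1.0 / length
    return Reaction(id=name, stoichiometry=stoich, reversible=False, name=name)


def _extension_reactions() -> Dict[str, Reaction]:
    R = Reaction
    rxns = [
        # collagen assembly, published stoichiometry
        R("CBS", {"GLYc": -0.33, "XYAA": -0.50, "PROc": -0.085,
                  "HYPc": -0.085, "CBrick": 1.0}),
        R("COLLAG", {"CBrick": -100.0, "Collagen": 1.0}),
        R("XYAAS", {"ALAc": -1.0, "ARGc": -1.0, "SERc": -1.0, "TIV": -1.0,
                    "YFLKW": -1.0, "GLNc": -1.0, "ASPc": -1.0, "GLUTc": -1.0,
                    "XYAA": 14.0}),
        # marker proteins, coefficients as published
        R("IL1B", PRINTED_PROTEIN_REACTIONS["IL1B"]),
        R("TNFA", PRINTED_PROTEIN_REACTIONS["TNFA"]),
        R("VEGFA", PRINTED_PROTEIN_REACTIONS["VEGFA"]),
        # stroma response needs inflammation AND growth factor
        R("FACT", {"VEGFA": -1.0, "GrowthFactor": 1.0}),
        R("INF1", {"IL1B": -1.0, "Inflam": 1.0}),
        R("INF2", {"TNFA": -1.0, "Inflam": 1.0}),
        R("STROMA", {"Inflam": -1.0, "GrowthFactor": -1.0, "Stroma": 1.0}),
        R("EX_COLLAGEN", {"Collagen": -1.0, "COLLAGENx": 1.0}),
        R("EX_STROMA", {"Stroma": -1.0, "STROMAx": 1.0}),
        # transport and metabolism of the amino acids the core model lacks
        R("EX_PRO", {"PROx": -1.0, "PROc": 1.0}, reversible=True),
        R("PROS", {"GLUTc": -1.0, "ATP": -1.0, "NADHc": -2.0,
                   "PROc": 1.0, "ADP": 1.0, "NADc": 2.0}),
        R("HPRO", {"PROc": -1.0, "O2c": -0.5, "HYPc": 1.0}),
        R("EX_HIS", {"HISx": -1.0, "HISc": 1.0}, reversible=True),
        R("HISDG", {"HISc": -1.0, "THF": -1.0, "GLUTc": 1.0, "METHF": 1.0}),
        R("EX_ALA", {"ALAc": -1.0, "ALAx": 1.0}, reversible=True),
        R("ALAT", {"PYRc": -1.0, "GLUTc": -1.0, "ALAc": 1.0, "AKGc": 1.0},
          reversible=True),
        R("ASNS", {"ASPc": -1.0, "GLNc": -1.0, "ATP": -1.0,
                   "ASNc": 1.0, "GLUTc": 1.0, "ADP": 1.0}),
        R("ASNASE", {"ASNc": -1.0, "ASPc": 1.0}),
    ]
    return {r.id: r for r in rxns}


_NEW_INTERNAL = {
    "XYAA": "cytosol", "CBrick": "cytosol", "Collagen": "cytosol",
    "HYPc": "cytosol", "IL1B": "cytosol", "TNFA": "cytosol",
    "VEGFA": "cytosol", "Inflam": "cytosol", "GrowthFactor": "cytosol",
    "Stroma": "cytosol",
}
_NEW_BOUNDARY = {"COLLAGENx", "STROMAx", "PROx", "HISx", "ALAx"}


def build_stroma_extension(base: MetabolicNetwork) -> MetabolicNetwork:
    """Return a new network: ``base`` plus the stroma-formation reactions.

    The base network must already contain the pooled amino-acid metabolites
    and the cofactors the auxiliary reactions draw on; anything missing is
    reported in the error.
    """
    rxns = _extension_reactions()
    new_mets = set(_NEW_INTERNAL) | _NEW_BOUNDARY
    required = set()
    for r in rxns.values():
        required.update(set(r.stoichiometry) - new_mets)
    missing = sorted(required - set(base.metabolite_ids))
    if missing:
        raise NetworkValidationError(
            f"base network lacks metabolites required by the stroma "
            f"extension: {missing}"
        )
    dup = set(rxns) & set(base.reaction_ids)
    if dup:
        raise NetworkValidationError(
            f"base network already defines extension reactions: {sorted(dup)}"
        )
    metabolites = list(base.metabolites)
    metabolites += [
        Metabolite(mid, mid, comp) for mid, comp in _NEW_INTERNAL.items()
    ]
    metabolites += [
        Metabolite(mid, mid, "external", is_boundary=True)
        for mid in sorted(_NEW_BOUNDARY)
    ]
    return MetabolicNetwork(
        metabolites=metabolites,
        reactions=list(base.reactions) + list(rxns.values()),
        name=(base.name or "base") + "_stroma",
    )
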