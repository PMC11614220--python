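"""Synthetic inputs: stand-in core network, cell-line tables, toy fixtures.

Everything the pipeline consumes can be generated here without downloads:

* :func:`synthetic_core_network` / :func:`synthetic_stroma_network` — a
  SYNTHETIC stand-in for the published central-carbon model (which is
  distributed separately and is not packaged here).  It is a curated
  three-compartment network with glycolysis, lactate fermentation,
  glutaminolysis, a lumped TCA cycle and oxidative phosphorylation,
  serine/glycine/folate metabolism, amino-acid uptake and degradation, a
  biomass reaction, and — after the stroma extension — the published
  collagen/inflammation/angiogenesis reactions.  It reproduces the
  *structure* of the study (compartments, pooled amino acids TIV/YFLKW,
  exchange set matching the measured metabolites), not the original
  model's reaction inventory, so absolute counts and scores differ from
  the published ones.
* :func:`generate_cell_lines` — per-cell-line exchange fluxes drawn from
  the mean/SD/sign structure of the measured panel.
* :func:`generate_planted_efm_data` — scaled copies of one mode's exchange
  vector plus Gaussian noise, for parameter-recovery tests.
* :func:`generate_toy_network` — chain/diamond/cycle/random fixtures small
  enough for the brute-force EFM oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .efm import FluxMode
from .model import MetabolicNetwork, Metabolite, Reaction
from .scoring import ExometabolomicsTable
from .stroma import build_stroma_extension

__all__ = [
    "SyntheticSpec",
    "synthetic_core_network",
    "synthetic_stroma_network",
    "DEFAULT_EXCHANGE_ALIASES",
    "CANCER_TYPES",
    "generate_cell_lines",
    "generate_planted_efm_data",
    "generate_toy_network",
]

#: Table-level metabolite names -> exchange reaction ids of the stand-in model
DEFAULT_EXCHANGE_ALIASES: Dict[str, str] = {
    "glucose": "EX_GLUC",
    "lactate": "EX_LAC",
    "glutamine": "EX_GLN",
    "glutamate": "EX_GLUT",
    "serine": "EX_SER",
    "glycine": "EX_GLY",
    "alanine": "EX_ALA",
    "proline": "EX_PRO",
    "asp_asn": "EX_ASP",
    "arginine": "EX_ARG",
    "tiv": "EX_TIV",
    "yflkw": "EX_YFLKW",
    "xtp": "EX_XTP",
    "pyruvate": "EX_PYR",
    "formate": "EX_FOR",
    "histidine": "EX_HIS",
    "cysteine": "EX_CYS",
    "methionine": "EX_MET",
    "collagen": "EX_COLLAGEN",
    "stroma": "EX_STROMA",
    "biomass": "EX_BIOMASS",
}

#: nine tumour-type labels used to tag synthetic cell lines
CANCER_TYPES = (
    "Breast", "CNS", "Colon", "Leukemia", "Melanoma",
    "NSCLC", "Ovarian", "Prostate", "Renal",
)


def synthetic_core_network() -> MetabolicNetwork:
    """SYNTHETIC stand-in core-carbon network (pre stroma extension).

    Cytosolic glycolysis feeding lactate fermentation or mitochondrial
    respiration, glutaminolysis with nucleotide synthesis, the folate
    cycle coupling serine, glycine, formate and methionine, degradation
    routes for the pooled essential amino acids, reductive citrate export
    for lipogenesis, and a protein/nucleotide/lipid biomass reaction.
    """
    M = Metabolite
    ext = [
        "GLUCx", "LACx", "GLNx", "GLUTx", "SERx", "GLYx", "ASPx", "ARGx",
        "TIVx", "YFLKWx", "XTPx", "PYRx", "FORx", "CYSx", "METx", "O2x",
        "BIOMASSx",
    ]
    cyt = [
        "GLUCc", "LACc", "GLNc", "GLUTc", "SERc", "GLYc", "ALAc", "PROc",
        "ASPc", "ASNc", "ARGc", "TIV", "YFLKW", "MET", "HISc", "CYSc",
        "PYRc", "FORc", "XTPc", "G3P", "THF", "METHF", "ATP", "ADP",
        "NADc", "NADHc", "AcCoAc", "OAAc", "AKGc", "CITc", "LIPID", "O2c",
        "BIOMASSc",
    ]
    mit = ["PYRm", "AcCoAm", "OAAm", "CITm", "AKGm", "GLUTm", "NADm",
           "NADHm", "O2m"]
    metabolites = (
        [M(i, i, "external", is_boundary=True) for i in ext]
        + [M(i, i, "cytosol") for i in cyt]
        + [M(i, i, "mitochondrion") for i in mit]
    )

    R = Reaction
    rxns = [
        # exchanges: forward = observed direction (uptake for consumed and
        # unconstrained metabolites, secretion for secreted ones)
        R("EX_GLUC", {"GLUCx": -1, "GLUCc": 1}),
        R("EX_LAC", {"LACc": -1, "LACx": 1}, reversible=True),
        R("EX_GLN", {"GLNx": -1, "GLNc": 1}, reversible=True),
        R("EX_GLUT", {"GLUTc": -1, "GLUTx": 1}, reversible=True),
        R("EX_SER", {"SERx": -1, "SERc": 1}, reversible=True),
        R("EX_GLY", {"GLYx": -1, "GLYc": 1}, reversible=True),
        R("EX_ASP", {"ASPx": -1, "ASPc": 1}, reversible=True),
        R("EX_ARG", {"ARGx": -1, "ARGc": 1}, reversible=True),
        R("EX_TIV", {"TIVx": -1, "TIV": 1}, reversible=True),
        R("EX_YFLKW", {"YFLKWx": -1, "YFLKW": 1}, reversible=True),
        R("EX_XTP", {"XTPx": -1, "XTPc": 1}, reversible=True),
        R("EX_PYR", {"PYRc": -1, "PYRx": 1}, reversible=True),
        R("EX_FOR", {"FORx": -1, "FORc": 1}, reversible=True),
        R("EX_CYS", {"CYSx": -1, "CYSc": 1}, reversible=True),
        R("EX_MET", {"METx": -1, "MET": 1}, reversible=True),
        R("EX_O2", {"O2x": -1, "O2c": 1}),
        R("EX_BIOMASS", {"BIOMASSc": -1, "BIOMASSx": 1}),
        # glycolysis and fermentation
        R("GLYC1", {"GLUCc": -1, "ATP": -2, "G3P": 2, "ADP": 2}),
        R("GLYC2", {"G3P": -1, "ADP": -2, "NADc": -1,
                    "PYRc": 1, "ATP": 2, "NADHc": 1}),
        R("LDH", {"PYRc": -1, "NADHc": -1, "LACc": 1, "NADc": 1},
          reversible=True),
        # serine / glycine / folate
        R("SERSYNT", {"G3P": -1, "GLUTc": -1, "NADc": -1,
                      "SERc": 1, "AKGc": 1, "NADHc": 1}),
        R("SHMT1", {"SERc": -1, "THF": -1, "GLYc": 1, "METHF": 1},
          reversible=True),
        R("MTHFD1", {"METHF": -1, "NADc": -1, "FORc": 1, "THF": 1,
                     "NADHc": 1}, reversible=True),
        R("GCS", {"GLYc": -1, "THF": -1, "NADc": -1, "METHF": 1, "NADHc": 1}),
        # glutaminolysis and nucleotide synthesis
        R("GLS", {"GLNc": -1, "GLUTc": 1}),
        R("NUC", {"GLNc": -2, "G3P": -1, "METHF": -1, "ATP": -4,
                  "XTPc": 1, "GLUTc": 2, "THF": 1, "ADP": 4}),
        R("GOT1", {"AKGc": -1, "ASPc": -1, "GLUTc": 1, "OAAc": 1},
          reversible=True),
        # amino-acid degradation
        R("ARGDG", {"ARGc": -1, "AKGc": -1, "NADc": -1,
                    "GLUTc": 2, "NADHc": 1}),
        R("CYSDG", {"CYSc": -1, "NADc": -1, "PYRc": 1, "NADHc": 1}),
        R("METDG", {"MET": -1, "SERc": -1, "CYSc": 1, "PYRc": 1}),
        R("TIVDG", {"TIV": -1, "AKGc": -1, "NADc": -1,
                    "GLUTc": 1, "AcCoAc": 1, "NADHc": 1}),
        R("YFLKWDG", {"YFLKW": -1, "AKGc": -1, "NADc": -1,
                      "GLUTc": 1, "AcCoAc": 1, "NADHc": 1}),
        # lipogenesis and anaplerotic plumbing
        R("LIPS", {"AcCoAc": -8, "ATP": -7, "NADHc": -14,
                   "LIPID": 1, "ADP": 7, "NADc": 14}),
        R("CITt", {"CITm": -1, "CITc": 1}),
        R("ACL", {"CITc": -1, "ATP": -1, "AcCoAc": 1, "OAAc": 1, "ADP": 1}),
        R("OAADC", {"OAAc": -1, "PYRc": 1}),
        R("ATPASE", {"ATP": -1, "ADP": 1}),
        # mitochondria: pyruvate oxidation, TCA, glutamate entry, OxPhos
        R("PYRtm", {"PYRc": -1, "PYRm": 1}),
        R("PDH", {"PYRm": -1, "NADm": -1, "AcCoAm": 1, "NADHm": 1}),
        R("CS", {"AcCoAm": -1, "OAAm": -1, "CITm": 1}),
        R("IDH", {"CITm": -1, "NADm": -1, "AKGm": 1, "NADHm": 1},
          reversible=True),
        R("AKGDH", {"AKGm": -1, "NADm": -2, "ADP": -1,
                    "OAAm": 1, "NADHm": 2, "ATP": 1}),
        R("GLUTtm", {"GLUTc": -1, "GLUTm": 1}, reversible=True),
        R("GDH", {"GLUTm": -1, "NADm": -1, "AKGm": 1, "NADHm": 1},
          reversible=True),
        R("AKGtm", {"AKGc": -1, "AKGm": 1}, reversible=True),
        R("SHUTTLE", {"NADHc": -1, "NADm": -1, "NADc": 1, "NADHm": 1}),
        R("O2tm", {"O2c": -1, "O2m": 1}),
        R("OXPHOS", {"NADHm": -1, "O2m": -0.5, "ADP": -2.5,
                     "NADm": 1, "ATP": 2.5}),
        # growth
        R("BIOMASS", {
            "ALAc": -0.35, "ASPc": -0.10, "ASNc": -0.05, "GLUTc": -0.12,
            "GLNc": -0.10, "GLYc": -0.20, "SERc": -0.15, "PROc": -0.10,
            "ARGc": -0.08, "CYSc": -0.04, "MET": -0.03, "HISc": -0.03,
            "TIV": -0.20, "YFLKW": -0.25, "XTPc": -0.30, "LIPID": -0.20,
            "ATP": -20.0, "BIOMASSc": 1.0, "ADP": 20.0,
        }),
    ]
    return MetabolicNetwork(metabolites=metabolites, reactions=rxns,
                            name="synthetic_core")


def synthetic_stroma_network() -> MetabolicNetwork:
    """Stand-in core network plus the published stroma extension."""
    return build_stroma_extension(synthetic_core_network())


# ---------------------------------------------------------------------------
# cell-line tables
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpec:
    """Study conditions for synthetic cell-line tables (60-line panel)."""

    n_lines: int = 60
    seed: int = 0
    enforce_signs: bool = True
    max_redraws: int = 100

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")


def generate_cell_lines(
    table: ExometabolomicsTable, spec: SyntheticSpec
) -> pd.DataFrame:
    """Per-line exchange fluxes ~ Normal(mean, sd) per metabolite.

    With ``enforce_signs``, draws violating the metabolite's sign category
    are redrawn (up to ``max_redraws``, then clipped to 0), keeping the
    distribution shape close to a truncated normal.  A round-robin
    ``cancer_type`` label column is appended.
    """
    rng = np.random.default_rng(spec.seed)
    mets = table.numeric_metabolites()
    data = {}
    for met in mets:
        entry = table.entries[met]
        draws = rng.normal(entry.mean, entry.sd, size=spec.n_lines)
        if spec.enforce_signs and entry.sign in ("-", "+"):
            bad = draws > 0 if entry.sign == "-" else draws < 0
            for _ in range(spec.max_redraws):
                if not bad.any():
                    break
                draws[bad] = rng.normal(entry.mean, entry.sd, size=int(bad.sum()))
                bad = draws > 0 if entry.sign == "-" else draws < 0
            draws[bad] = 0.0
        data[met] = draws
    df = pd.DataFrame(data, index=[f"line_{i:02d}" for i in range(spec.n_lines)])
    df["cancer_type"] = [
        CANCER_TYPES[i % len(CANCER_TYPES)] for i in range(spec.n_lines)
    ]
    return df


def generate_planted_efm_data(
    mode: FluxMode,
    network: MetabolicNetwork,
    metabolites: Sequence[str],
    scale_range: tuple = (0.5, 2.0),
    noise_sd: float = 0.0,
    n_lines: int = 60,
    seed: int = 0,
    aliases: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Cell lines planted on one mode: ``c_i * exchange_vector + noise``."""
    from .scoring import mode_exchange_vector

    base = mode_exchange_vector(mode, network, metabolites, aliases=aliases)
    nonnull = [m for m in metabolites if base[m] != 0.0]
    if len(nonnull) < 3:
        raise ValueError("planted mode needs >= 3 non-null exchange fluxes")
    rng = np.random.default_rng(seed)
    scales = rng.uniform(scale_range[0], scale_range[1], size=n_lines)
    rowsource = np.array([base[m] for m in metabolites])
    rows = scales[:, None] * rowsource[None, :]
    rows += rng.normal(0.0, noise_sd, size=rows.shape)
    return pd.DataFrame(
        rows, columns=list(metabolites),
        index=[f"line_{i:02d}" for i in range(n_lines)],
    )


# ---------------------------------------------------------------------------
# toy networks for the enumeration oracles
# ---------------------------------------------------------------------------


def generate_toy_network(
    kind: str, size: int = 6, seed: int = 0
) -> MetabolicNetwork:
    """Small fixtures with brute-force-enumerable EFM sets.

    chain:   Sx -> A1 -> ... -> Ak -> Px           (exactly one EFM)
    diamond: one input, two parallel routes, one output (two EFMs)
    cycle:   input/output plus an internal loop through shared currency
    random:  a chain-connected backbone plus random extra reactions; always
             has at least one EFM
    """
    M, R = Metabolite, Reaction
    if kind == "chain":
        k = max(1, size - 2)
        mets = [M("Sx", "Sx", "external", is_boundary=True),
                M("Px", "Px", "external", is_boundary=True)]
        mets += [M(f"A{i}", f"A{i}", "cytosol") for i in range(1, k + 1)]
        rxns = [R("IN", {"Sx": -1, "A1": 1})]
        rxns += [
            R(f"C{i}", {f"A{i}": -1, f"A{i+1}": 1}) for i in range(1, k)
        ]
        rxns.append(R("OUT", {f"A{k}": -1, "Px": 1}))
        return MetabolicNetwork(mets, rxns, name="chain")
    if kind == "diamond":
        mets = [M("Sx", "Sx", "external", is_boundary=True),
                M("Px", "Px", "external", is_boundary=True),
                M("A", "A", "cytosol"), M("B", "B", "cytosol")]
        rxns = [
            R("IN", {"Sx": -1, "A": 1}),
            R("TOP", {"A": -1, "B": 1}),
            R("BOT", {"A": -1, "B": 1}),
            R("OUT", {"B": -1, "Px": 1}),
        ]
        return MetabolicNetwork(mets, rxns, name="diamond")
    if kind == "cycle":
        mets = [M("Sx", "Sx", "external", is_boundary=True),
                M("Px", "Px", "external", is_boundary=True)]
        mets += [M(x, x, "cytosol") for x in ("A", "B", "C")]
        rxns = [
            R("IN", {"Sx": -1, "A": 1}),
            R("AB", {"A": -1, "B": 1}),
            R("BC", {"B": -1, "C": 1}, reversible=True),
            R("CA", {"C": -1, "A": 1}),
            R("OUT", {"B": -1, "Px": 1}),
        ]
        return MetabolicNetwork(mets, rxns, name="cycle")
    if kind == "random":
        rng = np.random.default_rng(seed)
        k = max(3, min(size, 14))
        n_int = max(2, k // 2)
        mets = [M("Sx", "Sx", "external", is_boundary=True),
                M("Px", "Px", "external", is_boundary=True)]
        mets += [M(f"A{i}", f"A{i}", "cytosol") for i in range(n_int)]
        rxns = [R("IN", {"Sx": -1, "A0": 1}),
                R("OUT", {f"A{n_int-1}": -1, "Px": 1})]
        for i in range(n_int - 1):
            rxns.append(R(f"B{i}", {f"A{i}": -1, f"A{i+1}": 1}))
        extra = k - len(rxns)
        tries = 0
        while extra > 0 and tries < 50 * k:
            tries += 1
            i, j = rng.integers(0, n_int, size=2)
            if i == j:
                continue
            rid = f"X{len(rxns)}"
            rev = bool(rng.random() < 0.3)
            rxns.append(R(rid, {f"A{i}": -1, f"A{j}": 1}, reversible=rev))
            extra -= 1
        return MetabolicNetwork(mets, rxns, name=f"random_{seed}")
    raise ValueError(f"unknown toy kind {kind!r}")
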