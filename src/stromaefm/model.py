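"""Stoichiometric network representation.

A :class:`MetabolicNetwork` is an ordered collection of metabolites and
reactions over three compartments (external, cytosol, mitochondrion).
Boundary metabolites (flagged ``is_boundary``) are excluded from the
steady-state balance, so the internal stoichiometric matrix ``N`` satisfies
``N @ v = 0`` for every steady-state flux vector ``v``.

Flux vectors are plain mappings ``reaction-id -> flux``.  Exchange fluxes
are reported in the exometabolomics sign convention (uptake negative,
secretion positive) regardless of how the exchange reaction is written.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "FluxVector",
    "NetworkValidationError",
    "exchange_flux",
    "write_stoichiometric_matrix",
    "support",
    "split_reversible_reactions",
]

COMPARTMENTS = ("external", "cytosol", "mitochondrion")

#: Default box bound used when a reaction carries no explicit flux bound.
DEFAULT_BOUND = 1000.0

FluxVector = Mapping[str, float]


class NetworkValidationError(ValueError):
    """Raised when a network or one of its components is inconsistent."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    is_boundary: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise NetworkValidationError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}"
            )


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]
    reversible: bool = False
    lower_bound: Optional[float] = None
    upper_bound: Optional[float] = None
    name: str = ""

    def __post_init__(self) -> None:
        stoich = {m: float(c) for m, c in self.stoichiometry.items() if c != 0.0}
        if not stoich:
            raise NetworkValidationError(
                f"reaction {self.id!r} has no nonzero coefficient"
            )
        object.__setattr__(self, "stoichiometry", stoich)
        lb = self.lower_bound
        ub = self.upper_bound
        if lb is None:
            lb = -DEFAULT_BOUND if self.reversible else 0.0
        if ub is None:
            ub = DEFAULT_BOUND
        if not self.reversible and lb < 0:
            raise NetworkValidationError(
                f"irreversible reaction {self.id!r} has negative lower bound {lb}"
            )
        if lb > ub:
            raise NetworkValidationError(
                f"reaction {self.id!r}: lower bound {lb} exceeds upper bound {ub}"
            )
        object.__setattr__(self, "lower_bound", float(lb))
        object.__setattr__(self, "upper_bound", float(ub))

    @property
    def reactants(self) -> Dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> Dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


@dataclass
class MetabolicNetwork:
    """Ordered metabolites + reactions with the internal balance matrix."""

    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- bookkeeping -------------------------------------------------------

    def validate(self) -> None:
        seen = set()
        for m in self.metabolites:
            if m.id in seen:
                raise NetworkValidationError(f"duplicate metabolite id {m.id!r}")
            seen.add(m.id)
        met_ids = seen
        seen = set()
        for r in self.reactions:
            if r.id in seen:
                raise NetworkValidationError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
            missing = set(r.stoichiometry) - met_ids
            if missing:
                raise NetworkValidationError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(missing)}"
                )

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def internal_metabolites(self) -> List[Metabolite]:
        return [m for m in self.metabolites if not m.is_boundary]

    @property
    def internal_metabolite_ids(self) -> List[str]:
        return [m.id for m in self.internal_metabolites]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(f"no metabolite {met_id!r}")

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"no reaction {rxn_id!r}")

    # -- stoichiometric matrix --------------------------------------------

    def stoichiometric_matrix(self) -> np.ndarray:
        """Internal stoichiometric matrix N (internal metabolites x reactions)."""
        rows = {m.id: i for i, m in enumerate(self.internal_metabolites)}
        N = np.zeros((len(rows), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                i = rows.get(met)
                if i is not None:
                    N[i, j] = coef
        return N

    def flux_array(self, v: FluxVector) -> np.ndarray:
        unknown = set(v) - set(self.reaction_ids)
        if unknown:
            raise KeyError(f"flux vector references unknown reactions {sorted(unknown)}")
        return np.array([float(v.get(r.id, 0.0)) for r in self.reactions])

    # -- exchange reactions ------------------------------------------------

    def is_exchange(self, rxn_id: str) -> bool:
        r = self.reaction(rxn_id)
        boundary = {m.id for m in self.metabolites if m.is_boundary}
        internal = [m for m in r.stoichiometry if m not in boundary]
        if len(r.stoichiometry) == 1:
            return True
        return len(internal) == 1 and len(r.stoichiometry) > len(internal)

    @property
    def exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if self.is_exchange(r.id)]

    def exchange_reaction_for(
        self, metabolite_id: str, aliases: Optional[Mapping[str, str]] = None
    ) -> Reaction:
        """Exchange reaction moving ``metabolite_id`` across the boundary.

        ``aliases`` maps user-level metabolite names to either a reaction id
        or a model metabolite id, accommodating files with unknown naming
        schemes.
        """
        target = metabolite_id
        if aliases and metabolite_id in aliases:
            target = aliases[metabolite_id]
            for r in self.exchange_reactions:
                if r.id == target:
                    return r
        variants = {target} | {target + s for s in ("c", "x", "m")}
        candidates = []
        for r in self.exchange_reactions:
            participants = set(r.stoichiometry)
            # match the id itself or compartment-suffixed forms (GLUC / GLUCc / GLUCx)
            if participants & variants:
                candidates.append(r)
        if not candidates:
            raise KeyError(f"no exchange reaction for metabolite {metabolite_id!r}")
        return candidates[0]

    # -- derived networks --------------------------------------------------

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            name=self.name,
        )

    def subnetwork(self, reaction_ids: Sequence[str]) -> "MetabolicNetwork":
        keep = set(reaction_ids)
        rxns = [r for r in self.reactions if r.id in keep]
        used = set()
        for r in rxns:
            used.update(r.stoichiometry)
        mets = [m for m in self.metabolites if m.id in used]
        return MetabolicNetwork(metabolites=mets, reactions=rxns, name=self.name)


def write_stoichiometric_matrix(network: MetabolicNetwork, path: str) -> None:
    """Export the internal stoichiometric matrix as CSV.

    Rows are internal metabolites (first column holds their ids), columns
    are reactions, with a header row of reaction ids.
    """
    import pandas as pd

    N = network.stoichiometric_matrix()
    pd.DataFrame(
        N, index=network.internal_metabolite_ids, columns=network.reaction_ids
    ).to_csv(path)


def support(v: FluxVector, tol: float = 1e-9) -> frozenset:
    """Reactions carrying flux above ``tol`` relative to the largest flux."""
    vmax = max((abs(x) for x in v.values()), default=0.0)
    cutoff = tol * max(1.0, vmax)
    return frozenset(r for r, x in v.items() if abs(x) > cutoff)


def exchange_flux(
    v: FluxVector,
    metabolite: str,
    network: MetabolicNetwork,
    aliases: Optional[Mapping[str, str]] = None,
) -> float:
    """Signed exchange rate for ``metabolite``: uptake < 0, secretion > 0.

    The sign is normalised from the reaction's stoichiometry, not from any
    assumed writing convention: if the forward direction of the exchange
    reaction brings the metabolite *into* the internal compartments, forward
    flux counts as uptake (negative).
    """
    r = network.exchange_reaction_for(metabolite, aliases=aliases)
    flux = float(v.get(r.id, 0.0))
    boundary = {m.id for m in network.metabolites if m.is_boundary}
    internal_coefs = [c for m, c in r.stoichiometry.items() if m not in boundary]
    if internal_coefs:
        coef = internal_coefs[0]
        # forward produces the internal species -> forward is uptake
        return -flux if coef > 0 else flux
    # pure boundary reaction: forward produces the external species -> secretion
    coef = next(iter(r.stoichiometry.values()))
    return flux if coef > 0 else -flux


def split_reversible_reactions(
    network: MetabolicNetwork,
) -> Tuple[MetabolicNetwork, List[Tuple[str, str]]]:
    """Split every reversible reaction into irreversible forward/backward halves.

    Returns the split network together with the list of (forward-id,
    backward-id) pairs.  Backward halves carry the negated stoichiometry and
    the suffix ``__rev``.
    """
    reactions: List[Reaction] = []
    pairs: List[Tuple[str, str]] = []
    for r in network.reactions:
        if not r.reversible:
            reactions.append(r)
            continue
        fwd = replace(
            r,
            reversible=False,
            lower_bound=0.0,
            upper_bound=max(r.upper_bound, 0.0) or DEFAULT_BOUND,
        )
        bwd = Reaction(
            id=r.id + "__rev",
            stoichiometry={m: -c for m, c in r.stoichiometry.items()},
            reversible=False,
            lower_bound=0.0,
            upper_bound=-min(r.lower_bound, 0.0) or DEFAULT_BOUND,
            name=r.name,
        )
        reactions.extend([fwd, bwd])
        pairs.append((fwd.id, bwd.id))
    return (
        MetabolicNetwork(
            metabolites=list(network.metabolites), reactions=reactions, name=network.name
        ),
        pairs,
    )


def merge_split_fluxes(
    v: FluxVector, pairs: Iterable[Tuple[str, str]]
) -> Dict[str, float]:
    """Collapse a flux vector on a split network back to net fluxes."""
    out = dict(v)
    for fwd, bwd in pairs:
        back = out.pop(bwd, 0.0)
        out[fwd] = out.get(fwd, 0.0) - back
    return out
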