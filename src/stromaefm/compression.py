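"""Loss-free network reduction: blocked reactions and enzyme subsets.

Reactions whose fluxes stand in a fixed ratio in *every* steady state — an
"enzyme subset" — are detected from the null space of the internal
stoichiometric matrix (two reactions are coupled iff their kernel rows are
proportional) and merged into a single compressed reaction carrying the
ratio-scaled summed stoichiometry.  Reactions that can carry no steady-state
flux at all (blocked, decided by LP with the irreversibilities and a large
flux box) are removed first.  The :class:`CompressionMap` inverts the whole
transformation, so flux modes of the compressed network decompress exactly
onto modes of the original.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import numpy as np
from scipy.linalg import null_space

from ._lp import solve_lp
from .model import MetabolicNetwork, Reaction

__all__ = [
    "CompressionMap",
    "find_blocked_reactions",
    "compress",
    "decompress",
]

#: LP box used for blocked-reaction detection (boundedness only).
BLOCKED_BOX = 1000.0
BLOCKED_TOL = 1e-6
#: kernel rows count as proportional above this cosine similarity
PROPORTIONALITY_COS = 1.0 - 1e-9


@dataclass
class CompressionMap:
    """Invertible record of one compression pass."""

    subsets: List[Tuple[str, List[Tuple[str, float]]]] = field(default_factory=list)
    blocked: List[str] = field(default_factory=list)
    split_pairs: List[Tuple[str, str]] = field(default_factory=list)

    def subset_of(self, reaction_id: str) -> Tuple[str, float]:
        for sid, members in self.subsets:
            for rid, ratio in members:
                if rid == reaction_id:
                    return sid, ratio
        raise KeyError(f"reaction {reaction_id!r} not in any subset")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "subsets": [
                        {"id": sid, "members": [[r, c] for r, c in members]}
                        for sid, members in self.subsets
                    ],
                    "blocked": self.blocked,
                    "split_pairs": [list(p) for p in self.split_pairs],
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str) -> "CompressionMap":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            subsets=[
                (s["id"], [(r, float(c)) for r, c in s["members"]])
                for s in raw["subsets"]
            ],
            blocked=list(raw["blocked"]),
            split_pairs=[tuple(p) for p in raw["split_pairs"]],
        )


def find_blocked_reactions(network: MetabolicNetwork) -> Set[str]:
    """Reactions with max |v_r| = 0 over the bounded steady-state cone."""
    N = network.stoichiometric_matrix()
    n = len(network.reactions)
    bounds = []
    for r in network.reactions:
        lb = max(r.lower_bound, -BLOCKED_BOX)
        ub = min(r.upper_bound, BLOCKED_BOX)
        bounds.append((lb, ub))
    blocked: Set[str] = set()
    b_eq = np.zeros(N.shape[0])
    for j, r in enumerate(network.reactions):
        c = np.zeros(n)
        c[j] = -1.0  # maximise v_j
        hi = solve_lp(c, A_eq=N, b_eq=b_eq, bounds=bounds)
        vmax = -hi.objective if hi.status == "optimal" else 0.0
        c[j] = 1.0
        lo = solve_lp(c, A_eq=N, b_eq=b_eq, bounds=bounds)
        vmin = lo.objective if lo.status == "optimal" else 0.0
        if max(abs(vmax), abs(vmin)) <= BLOCKED_TOL:
            blocked.add(r.id)
    return blocked


def _proportional(a: np.ndarray, b: np.ndarray) -> bool:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return False
    return abs(float(a @ b)) / (na * nb) > PROPORTIONALITY_COS


def compress(
    network: MetabolicNetwork,
) -> Tuple[MetabolicNetwork, CompressionMap]:
    """Remove blocked reactions and merge enzyme subsets.

    Returns the compressed network and the map needed by
    :func:`decompress`.  Compressing twice is a no-op: after one pass no
    two kernel rows remain proportional.
    """
    blocked = sorted(find_blocked_reactions(network))
    kept = [r for r in network.reactions if r.id not in blocked]
    work = MetabolicNetwork(
        metabolites=list(network.metabolites), reactions=kept, name=network.name
    )
    N = work.stoichiometric_matrix()
    K = null_space(N) if N.size else np.zeros((len(kept), 0))
    if K.size == 0:
        K = np.zeros((len(kept), 0))

    # group reactions whose kernel rows are proportional
    n = len(kept)
    assigned = [-1] * n
    groups: List[List[int]] = []
    for i in range(n):
        if assigned[i] >= 0:
            continue
        gi = len(groups)
        assigned[i] = gi
        groups.append([i])
        if K.shape[1] == 0 or np.linalg.norm(K[i]) == 0:
            continue  # kernel-blocked; keep as singleton (LP said feasible)
        for j in range(i + 1, n):
            if assigned[j] < 0 and _proportional(K[i], K[j]):
                assigned[j] = gi
                groups[gi].append(j)

    subsets: List[Tuple[str, List[Tuple[str, float]]]] = []
    new_reactions: List[Reaction] = []
    for members in groups:
        ref = members[0]
        ratios: Dict[int, float] = {ref: 1.0}
        for j in members[1:]:
            ratios[j] = float(K[j] @ K[ref]) / float(K[ref] @ K[ref])
        # orient so irreversible members keep nonnegative ratios
        irrev_signs = {np.sign(ratios[j]) for j in members if not kept[j].reversible}
        if irrev_signs == {-1.0}:
            ratios = {j: -x for j, x in ratios.items()}
        stoich: Dict[str, float] = {}
        for j in members:
            for met, coef in kept[j].stoichiometry.items():
                stoich[met] = stoich.get(met, 0.0) + ratios[j] * coef
        stoich = {m: c for m, c in stoich.items() if abs(c) > 1e-12}
        reversible = all(kept[j].reversible for j in members)
        lbs, ubs = [], []
        for j in members:
            rj, rxn = ratios[j], kept[j]
            if rj > 0:
                lbs.append(rxn.lower_bound / rj)
                ubs.append(rxn.upper_bound / rj)
            else:
                lbs.append(rxn.upper_bound / rj)
                ubs.append(rxn.lower_bound / rj)
        sid = kept[members[0]].id if len(members) == 1 else "__".join(
            kept[j].id for j in members
        )
        subsets.append((sid, [(kept[j].id, ratios[j]) for j in members]))
        if not stoich:
            # members cancel exactly (an internal cycle subset); keep a
            # boundary-free placeholder only if something remains — skip
            continue
        new_reactions.append(
            Reaction(
                id=sid,
                stoichiometry=stoich,
                reversible=reversible,
                lower_bound=max(lbs) if not reversible else max(lbs),
                upper_bound=min(ubs),
                name=sid,
            )
        )

    used = set()
    for r in new_reactions:
        used.update(r.stoichiometry)
    mets = [m for m in network.metabolites if m.id in used]
    compressed = MetabolicNetwork(
        metabolites=mets, reactions=new_reactions, name=network.name + "_compressed"
    )
    cmap = CompressionMap(subsets=subsets, blocked=blocked, split_pairs=[])
    return compressed, cmap


def decompress(
    mode: Dict[str, float], cmap: CompressionMap, tol: float = 0.0
) -> Dict[str, float]:
    """Expand a compressed-network flux vector onto the original reactions."""
    lookup = {sid: members for sid, members in cmap.subsets}
    out: Dict[str, float] = {rid: 0.0 for rid in cmap.blocked}
    for sid, flux in mode.items():
        if sid not in lookup:
            raise KeyError(f"unknown subset id {sid!r}")
        for rid, ratio in lookup[sid]:
            out[rid] = flux * ratio
    return out
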