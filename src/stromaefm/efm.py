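"""Elementary Flux Modes: definition, verification, exhaustive enumeration.

An Elementary Flux Mode (EFM) is a steady-state flux vector with minimal
support: no other steady-state flux respecting the irreversibilities has a
strictly smaller set of active reactions.  EFMs are the extreme rays of the
flux cone ``{v : N v = 0, v_irrev >= 0}`` and are unique up to positive
scaling.  Elementarity is decided by the stoichiometric rank test:

    v elementary  <=>  rank(N restricted to supp(v)) = |supp(v)| - 1

Two exhaustive engines are provided for small networks: a Double
Description tableau (the classic pairwise-combination algorithm) and an
independent brute-force oracle that scans support subsets.  Both are meant
for fixtures of a few dozen reactions at most; the constrained MILP sampler
in :mod:`stromaefm.constraints` is the scalable path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    FluxVector,
    MetabolicNetwork,
    merge_split_fluxes,
    split_reversible_reactions,
    support,
)

__all__ = [
    "FluxMode",
    "is_steady_state",
    "is_elementary",
    "enumerate_efms_exhaustive",
    "brute_force_efms",
    "NetworkTooLargeError",
    "read_efm_matrix",
    "write_efm_matrix",
]

SUPPORT_TOL = 1e-9
RANK_TOL = 1e-9


class NetworkTooLargeError(ValueError):
    """Exhaustive enumeration refused; use the constrained sampler instead."""


@dataclass
class FluxMode:
    """A flux vector with its support; candidate or verified EFM."""

    vector: Dict[str, float]
    support: frozenset = field(default_factory=frozenset)
    verified_elementary: bool = False

    def __post_init__(self) -> None:
        if not self.support:
            self.support = support(self.vector, SUPPORT_TOL)

    def normalized(self) -> "FluxMode":
        """Scale so the largest absolute flux equals 1 (modes are conical)."""
        vmax = max((abs(x) for x in self.vector.values()), default=0.0)
        if vmax == 0:
            return FluxMode(dict(self.vector), self.support, self.verified_elementary)
        vec = {r: x / vmax for r, x in self.vector.items() if abs(x) > 0}
        return FluxMode(vec, self.support, self.verified_elementary)

    def signature(self) -> Tuple[Tuple[str, int], ...]:
        """Support plus direction pattern; the dedup key for mode sets."""
        return tuple(
            sorted((r, 1 if self.vector[r] > 0 else -1) for r in self.support)
        )


def is_steady_state(
    v: FluxVector, network: MetabolicNetwork, tol: float = 1e-8
) -> bool:
    """True iff the internal metabolite balance holds to relative tolerance."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    arr = network.flux_array(v)
    imbalance = network.stoichiometric_matrix() @ arr
    scale = max(1.0, float(np.max(np.abs(arr))) if arr.size else 1.0)
    return bool(np.max(np.abs(imbalance), initial=0.0) <= tol * scale)


def _rank(M: np.ndarray) -> int:
    if M.size == 0:
        return 0
    s = np.linalg.svd(M, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.sum(s > RANK_TOL * s[0]))


def is_elementary(v: FluxVector, network: MetabolicNetwork) -> bool:
    """Stoichiometric rank test for elementarity (zero vector is not an EFM)."""
    supp = sorted(support(v, SUPPORT_TOL))
    if not supp:
        return False
    N = network.stoichiometric_matrix()
    cols = [network.reaction_ids.index(r) for r in supp]
    return _rank(N[:, cols]) == len(supp) - 1


# ---------------------------------------------------------------------------
# Double Description on the split (all-irreversible) network
# ---------------------------------------------------------------------------


def _double_description_rays(N: np.ndarray) -> List[np.ndarray]:
    """Extreme rays of {v >= 0, N v = 0} by pairwise combination.

    Processes one balance row at a time, keeping rays in the hyperplane and
    combining positive/negative pairs that pass the combinatorial adjacency
    test (no third ray's zero set contains their common zero set).
    """
    n = N.shape[1]
    rays: List[np.ndarray] = [np.eye(n)[i] for i in range(n)]
    for row in N:
        vals = [float(row @ r) for r in rays]
        tol = 1e-10 * max(1.0, max(abs(x) for x in vals) if vals else 1.0)
        zero = [r for r, x in zip(rays, vals) if abs(x) <= tol]
        pos = [(r, x) for r, x in zip(rays, vals) if x > tol]
        neg = [(r, x) for r, x in zip(rays, vals) if x < -tol]
        new: List[np.ndarray] = list(zero)
        zero_sets = [frozenset(np.flatnonzero(r <= 1e-12 * max(1, r.max())))
                     for r in rays]
        all_rays = list(zip(rays, zero_sets))
        for (rp, xp), (rn, xn) in itertools.product(pos, neg):
            combo = xp * rn - xn * rp  # positive combination, lies in hyperplane
            combo = combo / np.max(np.abs(combo))
            z_combo = frozenset(np.flatnonzero(combo <= 1e-12))
            zp = frozenset(np.flatnonzero(rp <= 1e-12 * max(1, rp.max())))
            zn = frozenset(np.flatnonzero(rn <= 1e-12 * max(1, rn.max())))
            common = zp & zn
            adjacent = True
            for other, zo in all_rays:
                if other is rp or other is rn:
                    continue
                if common <= zo:
                    adjacent = False
                    break
            if adjacent:
                new.append(combo)
        # dedupe by support pattern
        uniq: Dict[frozenset, np.ndarray] = {}
        for r in new:
            key = frozenset(np.flatnonzero(r > 1e-12))
            uniq.setdefault(key, r)
        rays = list(uniq.values())
    return rays


def enumerate_efms_exhaustive(
    network: MetabolicNetwork, max_columns: int = 32
) -> List[FluxMode]:
    """All EFMs of a small network via Double Description.

    Reversible reactions are split first; spurious two-cycles (both halves
    of one reversible reaction) are removed and the remaining rays mapped
    back to signed net fluxes, deduplicated by support + direction pattern.
    """
    split, pairs = split_reversible_reactions(network)
    if len(split.reactions) > max_columns:
        raise NetworkTooLargeError(
            f"{len(split.reactions)} columns after splitting exceeds the "
            f"exhaustive-enumeration guard ({max_columns}); use "
            "sample_constrained_efms instead"
        )
    N = split.stoichiometric_matrix()
    rids = split.reaction_ids
    pair_sets = {frozenset(p) for p in pairs}
    modes: Dict[Tuple, FluxMode] = {}
    for ray in _double_description_rays(N):
        vec = {rids[i]: float(x) for i, x in enumerate(ray) if x > 1e-12}
        if frozenset(vec) in pair_sets:
            continue  # internal two-cycle artefact of splitting
        net = {r: x for r, x in merge_split_fluxes(vec, pairs).items() if x != 0.0}
        if not net:
            continue
        mode = _canonical_mode(net, network)
        if mode is not None:
            modes.setdefault(mode.signature(), mode)
    out = list(modes.values())
    for m in out:
        m.verified_elementary = is_elementary(m.vector, network)
    return sorted(out, key=lambda m: m.signature())


def _canonical_mode(
    net: Dict[str, float], network: MetabolicNetwork
) -> Optional[FluxMode]:
    """Normalise scale and sign of a net flux vector.

    A mode whose support is entirely reversible is valid in both directions;
    such modes are canonicalised to a positive flux on the lexicographically
    first support reaction, so that both engines count them once.
    """
    supp = sorted(net)
    irrev = [r for r in supp if not network.reaction(r).reversible]
    if irrev:
        if any(net[r] < 0 for r in irrev):
            if all(net[r] <= 0 for r in irrev):
                net = {r: -x for r, x in net.items()}
            else:
                return None  # violates an irreversibility in both orientations
    elif net[supp[0]] < 0:
        net = {r: -x for r, x in net.items()}
    return FluxMode(net).normalized()


def brute_force_efms(
    network: MetabolicNetwork, max_reactions: int = 18
) -> List[FluxMode]:
    """Independent oracle: scan all support subsets with the rank test.

    A subset S is an EFM support iff the kernel of N restricted to S is
    one-dimensional with a full-support kernel vector that can be oriented
    to respect every irreversible reaction in S.  Uniqueness of the kernel
    vector makes elementarity automatic (any smaller-support mode would lie
    in the same kernel).
    """
    nr = len(network.reactions)
    if nr > max_reactions:
        raise NetworkTooLargeError(
            f"{nr} reactions exceeds the brute-force guard ({max_reactions})"
        )
    N = network.stoichiometric_matrix()
    rids = network.reaction_ids
    reversible = np.array([r.reversible for r in network.reactions])
    modes: Dict[Tuple, FluxMode] = {}
    for size in range(1, nr + 1):
        for subset in itertools.combinations(range(nr), size):
            sub = N[:, subset]
            if _rank(sub) != size - 1:
                continue
            # one-dimensional kernel: extract it
            _, s, vt = np.linalg.svd(sub)
            kern = vt[-1]
            scale = np.max(np.abs(kern))
            if scale == 0:
                continue
            kern = kern / scale
            if np.any(np.abs(kern) <= 1e-9):
                continue  # kernel vector not full support on S
            net = {rids[j]: float(kern[i]) for i, j in enumerate(subset)}
            mode = _canonical_mode(net, network)
            if mode is not None:
                mode.verified_elementary = True
                modes.setdefault(mode.signature(), mode)
    return sorted(modes.values(), key=lambda m: m.signature())


# ---------------------------------------------------------------------------
# EFM matrix CSV (rows = modes, columns = reaction ids)
# ---------------------------------------------------------------------------


def write_efm_matrix(
    modes: Sequence[FluxMode], network: MetabolicNetwork, path: str
) -> None:
    rids = network.reaction_ids
    data = [[m.vector.get(r, 0.0) for r in rids] for m in modes]
    pd.DataFrame(data, columns=rids).to_csv(path, index=False)


def read_efm_matrix(
    path: str,
    aliases: Optional[Dict[str, str]] = None,
    renormalize: bool = True,
) -> List[FluxMode]:
    """Load an EFM matrix CSV; column names may be remapped via ``aliases``."""
    df = pd.read_csv(path)
    if aliases:
        df = df.rename(columns=dict(aliases))
    modes = []
    for _, row in df.iterrows():
        vec = {r: float(x) for r, x in row.items() if x != 0.0}
        mode = FluxMode(vec)
        modes.append(mode.normalized() if renormalize else mode)
    return modes
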