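"""Optimisation and sampling baselines for comparison with EFM analysis.

* Parsimonious FBA: maximise the summed production of biomass, collagen
  and stroma, then minimise total (split, nonnegative) flux at the fixed
  optimum.  Strict constraints are relaxed to a small margin inside LPs.
* Essentiality: a reaction is essential when forcing it to zero makes the
  constrained feasibility LP infeasible.
* Flux sampling: artificial-centering hit-and-run over the bounded
  steady-state polytope carrying the same (relaxed) constraint set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import null_space

from ._lp import solve_lp
from .constraints import ConstraintSet, EPS_STRICT
from .model import (
    MetabolicNetwork,
    merge_split_fluxes,
    split_reversible_reactions,
)

__all__ = ["LPSolution", "pfba", "is_essential", "flux_sample"]

log = logging.getLogger(__name__)

#: margin used for 'must be active' fluxes inside LPs
EPS_HARD = 1e-6


@dataclass
class LPSolution:
    fluxes: Dict[str, float]
    objective_value: float
    status: str  # 'optimal', 'infeasible' or 'unbounded'


class _SplitLP:
    """Shared scaffolding: split network, equalities, bounds, cs rows."""

    def __init__(
        self,
        network: MetabolicNetwork,
        cs: Optional[ConstraintSet],
        flux_bound: float,
        eps_hard: float = EPS_HARD,
    ):
        self.network = network
        self.split, self.pairs = split_reversible_reactions(network)
        self.rids = self.split.reaction_ids
        self.col = {r: j for j, r in enumerate(self.rids)}
        self.back_of = {f: b for f, b in self.pairs}
        self.nc = len(self.rids)
        self.N = self.split.stoichiometric_matrix()
        self.lb = np.zeros(self.nc)
        self.ub = np.full(self.nc, flux_bound)
        self.A_ub: List[np.ndarray] = []
        self.b_ub: List[float] = []
        if cs is None:
            return
        for rid, sign in cs.hard_active:
            j = self._directed_col(rid, sign)
            if j is None:
                raise ValueError(f"hard constraint on missing direction ({rid},{sign})")
            self.lb[j] = max(self.lb[j], eps_hard)
        for rid, sign in cs.forbidden_direction:
            j = self._directed_col(rid, sign)
            if j is not None:
                self.ub[j] = 0.0
        for rule in cs.linear:
            row = np.zeros(self.nc)
            for rid, coef in ((rule.left, -rule.left_coef), (rule.right, rule.right_coef)):
                row[self.col[rid]] += coef
                if rid in self.back_of:
                    row[self.col[self.back_of[rid]]] -= coef
            self.A_ub.append(row)
            self.b_ub.append(-EPS_STRICT)  # right - left <= -eps

    def _directed_col(self, rid: str, sign: int) -> Optional[int]:
        if sign > 0:
            return self.col.get(rid)
        return self.col.get(self.back_of.get(rid, "")) if rid in self.back_of else None

    def net_fluxes(self, x: np.ndarray) -> Dict[str, float]:
        vec = {self.rids[j]: float(x[j]) for j in range(self.nc)}
        return merge_split_fluxes(vec, self.pairs)

    def solve(self, c: np.ndarray, extra_eq=None, backend: str = "highs"):
        A_eq = self.N
        b_eq = np.zeros(self.N.shape[0])
        if extra_eq is not None:
            A_eq = np.vstack([A_eq, extra_eq[0]])
            b_eq = np.concatenate([b_eq, [extra_eq[1]]])
        A_ub = np.array(self.A_ub) if self.A_ub else None
        b_ub = np.array(self.b_ub) if self.b_ub else None
        return solve_lp(
            c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
            bounds=list(zip(self.lb, self.ub)), backend=backend,
        )


def pfba(
    network: MetabolicNetwork,
    cs: ConstraintSet,
    flux_bound: float = 15.0,
    objective_reactions: Sequence[str] = ("EX_BIOMASS", "EX_COLLAGEN", "EX_STROMA"),
    backend: str = "highs",
) -> LPSolution:
    """Two-stage parsimonious FBA under the (relaxed, uncapped) constraints.

    Stage 1 maximises the summed flux of the production reactions with
    every split flux in [0, flux_bound]; stage 2 fixes that optimum and
    minimises total split flux.  The support-size cap is not applied.
    """
    if flux_bound <= 0:
        raise ValueError("flux_bound must be positive")
    cs_nolimit = ConstraintSet(
        hard_active=set(cs.hard_active),
        forbidden_direction=set(cs.forbidden_direction),
        linear=list(cs.linear),
        max_support=None,
    )
    lp = _SplitLP(network, cs_nolimit, flux_bound)
    obj = np.zeros(lp.nc)
    for rid in objective_reactions:
        if rid not in lp.col:
            raise KeyError(f"objective reaction {rid!r} not in network")
        obj[lp.col[rid]] = -1.0  # maximise
    stage1 = lp.solve(obj, backend=backend)
    if stage1.status != "optimal":
        return LPSolution({}, float("nan"), stage1.status)
    opt = -stage1.objective
    stage2 = lp.solve(
        np.ones(lp.nc), extra_eq=(-obj, opt), backend=backend
    )
    if stage2.status != "optimal":
        # tolerate solver strictness on the fixed optimum
        log.warning("pFBA stage 2 returned %s; falling back to stage 1", stage2.status)
        return LPSolution(lp.net_fluxes(stage1.x), opt, "optimal")
    return LPSolution(lp.net_fluxes(stage2.x), opt, "optimal")


def is_essential(
    network: MetabolicNetwork,
    cs: ConstraintSet,
    reaction: str,
    flux_bound: float = 15.0,
) -> bool:
    """True iff forcing the reaction to zero kills constrained feasibility."""
    lp = _SplitLP(network, cs, flux_bound)
    for col_id in (reaction, lp.back_of.get(reaction)):
        if col_id is not None and col_id in lp.col:
            j = lp.col[col_id]
            lp.lb[j] = 0.0
            lp.ub[j] = 0.0
    res = lp.solve(np.zeros(lp.nc))
    return res.status != "optimal"


def flux_sample(
    network: MetabolicNetwork,
    cs: Optional[ConstraintSet],
    n: int,
    seed: int = 0,
    flux_bound: float = 15.0,
    warmup: int = 1000,
    thinning: int = 20,
) -> Tuple[List[Dict[str, float]], np.ndarray, List[str]]:
    """Artificial-centering hit-and-run over the constrained flux polytope.

    Returns ``(samples, matrix, reaction_ids)`` where ``matrix`` holds the
    net fluxes row-per-sample (cheap to score in bulk) and ``samples`` the
    same rows as flux dicts.  The chain is seeded, warmed up and thinned;
    directions are drawn through the running sample centre.
    """
    lp = _SplitLP(network, cs, flux_bound)
    nc = lp.nc
    n_ineq = len(lp.A_ub)
    A_ub = np.array(lp.A_ub) if n_ineq else None
    b_ub = np.array(lp.b_ub) if n_ineq else None
    b_eq = np.zeros(lp.N.shape[0])

    # flux-variability pass: columns whose range collapses (forbidden
    # directions, reactions blocked under the constraints) are pinned so
    # the walk happens on the polytope's affine hull
    lo = lp.lb.copy()
    hi = lp.ub.copy()
    for j in range(nc):
        if hi[j] - lo[j] < 1e-9:
            continue
        c = np.zeros(nc)
        c[j] = 1.0
        r_min = solve_lp(c, A_eq=lp.N, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                         bounds=list(zip(lo, hi)))
        c[j] = -1.0
        r_max = solve_lp(c, A_eq=lp.N, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                         bounds=list(zip(lo, hi)))
        if r_min.status != "optimal" or r_max.status != "optimal":
            offenders = [r.label for r in (cs.linear if cs else [])]
            raise ValueError(
                "constrained flux polytope is empty; check hard/linear "
                f"constraints {offenders}"
            )
        vmin, vmax = r_min.objective, -r_max.objective
        if vmax - vmin < 1e-9:
            lo[j] = hi[j] = 0.5 * (vmin + vmax)
        else:
            lo[j], hi[j] = vmin, vmax

    free = np.flatnonzero(hi - lo >= 1e-9)
    fixed = np.flatnonzero(hi - lo < 1e-9)
    if free.size == 0:
        raise ValueError("constrained flux polytope is a single point")
    v_fix = 0.5 * (lo[fixed] + hi[fixed])
    N_free = lp.N[:, free]
    b_free = -lp.N[:, fixed] @ v_fix if fixed.size else b_eq

    # interior start on the free coordinates: maximise the smallest slack
    nf = free.size
    rows, rhs = [], []
    for k in range(nf):
        row = np.zeros(nf + 1)
        row[k], row[-1] = -1.0, 1.0
        rows.append(row)
        rhs.append(-lo[free[k]])
        row = np.zeros(nf + 1)
        row[k], row[-1] = 1.0, 1.0
        rows.append(row)
        rhs.append(hi[free[k]])
    if n_ineq:
        for i in range(n_ineq):
            row = np.zeros(nf + 1)
            row[:nf] = A_ub[i, free]
            row[-1] = 1.0
            rows.append(row)
            rhs.append(b_ub[i] - (A_ub[i, fixed] @ v_fix if fixed.size else 0.0))
    c = np.zeros(nf + 1)
    c[-1] = -1.0
    start = solve_lp(
        c,
        A_eq=np.hstack([N_free, np.zeros((N_free.shape[0], 1))]),
        b_eq=b_free,
        A_ub=np.array(rows),
        b_ub=np.array(rhs),
        bounds=[(None, None)] * nf + [(0.0, None)],
    )
    if start.status != "optimal" or start.x is None or start.x[-1] <= 1e-12:
        raise ValueError(
            "constrained flux polytope has no interior on its affine hull"
        )
    x0 = start.x[:nf]

    B = null_space(N_free) if N_free.size else np.eye(nf)
    if B.size == 0:
        raise ValueError("steady-state space is trivial; nothing to sample")
    # inequality system G v_free <= h covering bounds and linear rules
    G = np.vstack(
        [-np.eye(nf), np.eye(nf)]
        + ([A_ub[:, free]] if n_ineq else [])
    )
    h = np.concatenate(
        [-lo[free], hi[free]]
        + ([b_ub - (A_ub[:, fixed] @ v_fix if fixed.size else 0.0)] if n_ineq else [])
    )

    rng = np.random.default_rng(seed)
    x = x0.copy()
    center = x0.copy()
    seen = 1
    out = np.empty((n, nf))
    kept = 0
    step = 0
    max_steps = warmup + thinning * n
    slack = h - G @ x
    while kept < n and step < 10 * max_steps:
        step += 1
        # artificial centering: walk through the running centre most of the
        # time; B is orthonormal so B.T projects onto the nullspace chart
        if seen > 2 and rng.random() < 0.9:
            direction_v = (center - x) if rng.random() < 0.5 else (x - center)
            t_dir = B.T @ direction_v
        else:
            t_dir = rng.standard_normal(B.shape[1])
        d = B @ t_dir
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            t_dir = rng.standard_normal(B.shape[1])
            d = B @ t_dir
            norm = np.linalg.norm(d)
        d /= norm
        gd = G @ d
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = slack / gd
        upper = np.min(ratios[gd > 1e-12], initial=np.inf)
        lower = np.max(ratios[gd < -1e-12], initial=-np.inf)
        if not np.isfinite(upper) or not np.isfinite(lower) or upper <= lower:
            continue
        alpha = rng.uniform(lower, upper)
        x = x + alpha * d
        slack = slack - alpha * gd
        if np.min(slack) < -1e-9:  # numerical drift: re-anchor
            slack = h - G @ x
        seen += 1
        center += (x - center) / seen
        if step > warmup and (step - warmup) % thinning == 0:
            out[kept] = x
            kept += 1
    if kept < n:
        out = out[:kept]
        log.warning("hit-and-run produced %d/%d samples", kept, n)

    # reassemble full split vectors, then map to net fluxes
    full = np.zeros((out.shape[0], nc))
    full[:, free] = out
    if fixed.size:
        full[:, fixed] = v_fix
    rids = network.reaction_ids
    net = np.zeros((full.shape[0], len(rids)))
    idx = {r: i for i, r in enumerate(rids)}
    for j, rid in enumerate(lp.rids):
        if rid.endswith("__rev"):
            net[:, idx[rid[:-5]]] -= full[:, j]
        else:
            net[:, idx[rid]] += full[:, j]
    samples = [
        {rids[i]: float(row[i]) for i in range(len(rids)) if row[i] != 0.0}
        for row in net
    ]
    return samples, net, rids
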