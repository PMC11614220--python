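"""Biological constraints on flux modes, and a constrained EFM sampler.

Four constraint classes are supported, mirroring how exometabolomic
observations are imposed on the mode computation:

* *hard activity*: a directed reaction must carry strictly positive flux
  (glucose uptake, lactate secretion, glutamine uptake — the Warburg /
  glutaminolysis signature);
* *forbidden direction*: the direction opposite to an observed uptake or
  secretion must carry zero flux ("desired observations" — they allow a
  metabolite to stay unused but never to move the wrong way);
* *strict linear inequalities* between fluxes (collagen and stroma output
  above biomass output);
* *support-size cap*: strictly fewer active reactions than a given bound.

The sampler emulates a constrained-enumeration engine with an iterated
mixed-integer program: Boolean activity indicators are linked to fluxes by
big-M and epsilon-activation, the support count is minimised (with a small
seeded perturbation for diversity), each solution is rank-tested for
elementarity, and a no-good support cut excludes rediscovery before the
next solve.
"""

from __future__ import annotations

import contextlib
import json
import logging
import os
import sys
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple, Union

import numpy as np
from scipy.optimize import LinearConstraint, milp

from .efm import FluxMode, is_elementary, is_steady_state
from .model import (
    FluxVector,
    MetabolicNetwork,
    merge_split_fluxes,
    split_reversible_reactions,
    support,
)

__all__ = [
    "ConstraintSet",
    "LinearRule",
    "default_constraint_set",
    "satisfies",
    "sample_constrained_efms",
    "SampleResult",
]

log = logging.getLogger(__name__)

Directed = Tuple[str, int]  # (reaction id, +1 forward / -1 backward)

#: epsilon linking indicators to fluxes in the MILP; kept within 1e6 of the
#: big-M so the solver's feasibility tolerances stay meaningful
EPS_ACTIVATION = 1e-3
#: margin standing in for strictness of '>' constraints
EPS_STRICT = 1e-6
BIG_M = 1000.0


@dataclass(frozen=True)
class LinearRule:
    """Strict inequality ``left_coef * v_left > right_coef * v_right``."""

    left: str
    right: str
    left_coef: float = 1.0
    right_coef: float = 1.0

    @property
    def label(self) -> str:
        return f"linear:{self.left}>{self.right}"


def _as_directed(item: Union[str, Directed]) -> Directed:
    if isinstance(item, str):
        return (item, +1)
    rid, sign = item
    if sign not in (+1, -1):
        raise ValueError(f"direction must be +1 or -1, got {sign!r}")
    return (rid, sign)


@dataclass
class ConstraintSet:
    hard_active: Set[Directed] = field(default_factory=set)
    forbidden_direction: Set[Directed] = field(default_factory=set)
    linear: List[LinearRule] = field(default_factory=list)
    max_support: Optional[int] = None

    def __post_init__(self) -> None:
        self.hard_active = {_as_directed(d) for d in self.hard_active}
        self.forbidden_direction = {_as_directed(d) for d in self.forbidden_direction}
        clash = self.hard_active & self.forbidden_direction
        if clash:
            raise ValueError(
                f"directions both required and forbidden: {sorted(clash)}"
            )

    # -- (de)serialisation -------------------------------------------------

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "hard_active": sorted(list(d) for d in self.hard_active),
                    "forbidden_direction": sorted(
                        list(d) for d in self.forbidden_direction
                    ),
                    "linear": [
                        [r.left, r.right, r.left_coef, r.right_coef]
                        for r in self.linear
                    ],
                    "max_support": self.max_support,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str) -> "ConstraintSet":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            hard_active={(r, int(s)) for r, s in raw["hard_active"]},
            forbidden_direction={(r, int(s)) for r, s in raw["forbidden_direction"]},
            linear=[LinearRule(a, b, float(c), float(d)) for a, b, c, d in raw["linear"]],
            max_support=raw["max_support"],
        )


def _uptake_sign(network: MetabolicNetwork, rxn_id: str) -> int:
    """+1 if forward flux of the exchange reaction is uptake, else -1."""
    r = network.reaction(rxn_id)
    boundary = {m.id for m in network.metabolites if m.is_boundary}
    internal = [c for m, c in r.stoichiometry.items() if m not in boundary]
    if internal:
        return +1 if internal[0] > 0 else -1
    return -1 if next(iter(r.stoichiometry.values())) > 0 else +1


def default_constraint_set(
    table,
    network: MetabolicNetwork,
    aliases: Optional[Dict[str, str]] = None,
    max_support: int = 60,
) -> ConstraintSet:
    """Constraints derived from an exometabolomics table.

    Hard activity for the 'hard' entries in their observed direction;
    forbidden opposite direction for every signed 'desired' entry;
    '+/-' entries unconstrained; collagen and stroma exchange each above
    biomass exchange; support strictly below ``max_support``.
    """
    hard: Set[Directed] = set()
    forbidden: Set[Directed] = set()
    for met, entry in table.entries.items():
        rxn = network.exchange_reaction_for(met, aliases=aliases)  # may raise
        up = _uptake_sign(network, rxn.id)
        if entry.sign == "+/-":
            continue
        observed = up if entry.sign == "-" else -up
        if entry.kind == "hard":
            hard.add((rxn.id, observed))
        else:
            forbidden.add((rxn.id, -observed))
    def _find(name: str) -> str:
        for key in (name, name.capitalize(), name.upper()):
            try:
                return network.exchange_reaction_for(key, aliases=aliases).id
            except KeyError:
                continue
        raise KeyError(f"no exchange reaction found for {name!r}")

    collagen = _find("collagen")
    stroma = _find("stroma")
    biomass = _find("biomass")
    linear = [LinearRule(collagen, biomass), LinearRule(stroma, biomass)]
    return ConstraintSet(
        hard_active=hard,
        forbidden_direction=forbidden,
        linear=linear,
        max_support=max_support,
    )


def satisfies(
    mode: Union[FluxMode, FluxVector],
    cs: ConstraintSet,
    eps: float = 1e-6,
) -> Tuple[bool, List[str]]:
    """Check all constraint classes; returns (ok, violated labels)."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    vec = mode.vector if isinstance(mode, FluxMode) else dict(mode)
    violations: List[str] = []
    for rid, sign in sorted(cs.hard_active):
        if sign * vec.get(rid, 0.0) <= eps:
            violations.append(f"hard:{rid}")
    for rid, sign in sorted(cs.forbidden_direction):
        if sign * vec.get(rid, 0.0) > eps:
            violations.append(f"forbidden:{rid}")
    for rule in cs.linear:
        lhs = rule.left_coef * vec.get(rule.left, 0.0)
        rhs = rule.right_coef * vec.get(rule.right, 0.0)
        if lhs - rhs <= eps:
            violations.append(rule.label)
    if cs.max_support is not None and len(support(vec)) >= cs.max_support:
        violations.append("size")
    return (not violations, violations)


def translate_constraints(cs: ConstraintSet, cmap) -> ConstraintSet:
    """Re-express a constraint set on a compressed network.

    A constraint on reaction r with subset ratio rho becomes a constraint
    on the subset flux, with the direction flipped when rho < 0 and linear
    rules rescaled by the ratios.
    """

    def move(d: Directed) -> Directed:
        sid, ratio = cmap.subset_of(d[0])
        return (sid, d[1] if ratio > 0 else -d[1])

    linear = []
    for rule in cs.linear:
        ls, lr = cmap.subset_of(rule.left)
        rs, rr = cmap.subset_of(rule.right)
        linear.append(
            LinearRule(ls, rs, rule.left_coef * lr, rule.right_coef * rr)
        )
    return ConstraintSet(
        hard_active={move(d) for d in cs.hard_active},
        forbidden_direction={move(d) for d in cs.forbidden_direction},
        linear=linear,
        max_support=cs.max_support,
    )


class SampleResult(list):
    """List of FluxModes with sampling metadata."""

    complete: bool = True
    status: str = "ok"


def sample_constrained_efms(
    network: MetabolicNetwork,
    cs: ConstraintSet,
    n: int,
    seed: int = 0,
    time_limit: Optional[float] = None,
    eps: float = EPS_STRICT,
    perturbation: float = 0.1,
    mip_rel_gap: float = 0.25,
    solve_time_limit: float = 30.0,
) -> SampleResult:
    """Sample up to ``n`` distinct EFMs satisfying ``cs``.

    Iterates a support-minimising MILP with seeded objective perturbation;
    every incumbent is rank-tested, accepted solutions are excluded from
    rediscovery (together with all their support supersets — safe, because
    EFM supports are pairwise incomparable) and the solve repeats.  With an
    ample time limit on a small network this recovers exactly the
    constraint-satisfying subset of the full EFM set.

    Proving support optimality is unnecessary for correctness (any
    rank-test-verified solution is an EFM), so each solve stops at relative
    gap ``mip_rel_gap`` or after ``solve_time_limit`` seconds and the
    incumbent is used; supersets of a non-elementary incumbent's support
    never contain an EFM support, so cutting them is always safe.
    """
    rng = np.random.default_rng(seed)
    t0 = time.monotonic()
    split, pairs = split_reversible_reactions(network)
    rids = split.reaction_ids
    col = {r: j for j, r in enumerate(rids)}
    nc = len(rids)
    N = split.stoichiometric_matrix()
    back_of = {f: b for f, b in pairs}
    rev_cols = {b for _, b in pairs}

    def directed_col(d: Directed) -> Optional[int]:
        rid, sign = d
        if sign > 0:
            return col.get(rid)
        if rid in back_of:
            return col.get(back_of[rid])
        return None  # backward of an irreversible reaction

    ub = np.array(
        [min(r.upper_bound, BIG_M) if r.upper_bound > 0 else BIG_M for r in split.reactions]
    )

    # variables: [v_0..v_nc-1, z_0..z_nc-1]
    nv = 2 * nc
    rows: List[np.ndarray] = []
    lo: List[float] = []
    hi: List[float] = []

    def add_row(row, lb_val, ub_val):
        rows.append(row)
        lo.append(lb_val)
        hi.append(ub_val)

    for i in range(N.shape[0]):
        row = np.zeros(nv)
        row[:nc] = N[i]
        add_row(row, 0.0, 0.0)
    for j in range(nc):
        row = np.zeros(nv)
        row[j] = 1.0
        row[nc + j] = -ub[j]
        add_row(row, -np.inf, 0.0)  # v <= ub z
        row = np.zeros(nv)
        row[j] = 1.0
        row[nc + j] = -EPS_ACTIVATION
        add_row(row, 0.0, np.inf)  # v >= eps z
    for f, b in pairs:
        row = np.zeros(nv)
        row[nc + col[f]] = 1.0
        row[nc + col[b]] = 1.0
        add_row(row, -np.inf, 1.0)  # no spurious two-cycles

    z_fix_one: List[int] = []
    z_fix_zero: List[int] = []
    for d in cs.hard_active:
        j = directed_col(d)
        if j is None:
            log.warning("hard constraint %s targets a missing direction", d)
            return _empty_result("infeasible: missing hard direction")
        z_fix_one.append(j)
    for d in cs.forbidden_direction:
        j = directed_col(d)
        if j is not None:
            z_fix_zero.append(j)

    for rule in cs.linear:
        row = np.zeros(nv)
        for rid, coefsign in ((rule.left, rule.left_coef), (rule.right, -rule.right_coef)):
            jf = col.get(rid)
            if jf is None:
                raise KeyError(f"linear rule references unknown reaction {rid!r}")
            row[jf] += coefsign
            if rid in back_of:
                row[col[back_of[rid]]] -= coefsign
        add_row(row, eps, np.inf)

    if cs.max_support is not None:
        row = np.zeros(nv)
        row[nc:] = 1.0
        add_row(row, -np.inf, float(cs.max_support - 1))

    var_lb = np.zeros(nv)
    var_ub = np.concatenate([ub, np.ones(nc)])
    for j in z_fix_one:
        var_lb[nc + j] = 1.0
    for j in z_fix_zero:
        var_ub[nc + j] = 0.0
        var_ub[j] = 0.0
    integrality = np.concatenate([np.zeros(nc), np.ones(nc)])

    result = SampleResult()
    seen: Set[Tuple] = set()
    cut_rows: List[np.ndarray] = []
    cut_ub: List[float] = []
    while len(result) < n:
        if time_limit is not None and time.monotonic() - t0 > time_limit:
            result.complete = False
            result.status = "timeout"
            break
        c = np.concatenate(
            [np.zeros(nc), 1.0 + perturbation * rng.random(nc)]
        )
        A = np.array(rows + cut_rows)
        lc = LinearConstraint(
            A,
            np.array(lo + [-np.inf] * len(cut_rows)),
            np.array(hi + cut_ub),
        )
        options = _milp_options(time_limit, t0, mip_rel_gap, solve_time_limit)
        with _quiet_solver():
            res = milp(
                c=c,
                constraints=lc,
                integrality=integrality,
                bounds=_bounds(var_lb, var_ub),
                options=options,
            )
            if res.status == 4:  # solver error: retry without presolve
                res = milp(
                    c=c,
                    constraints=lc,
                    integrality=integrality,
                    bounds=_bounds(var_lb, var_ub),
                    options={**options, "presolve": False},
                )
        if res.x is None:
            if res.status == 1:  # hit a limit before any incumbent
                result.complete = False
                result.status = "timeout"
            elif res.status == 2:
                if not result:
                    result.status = "infeasible"
                    log.info("constrained MILP infeasible: %s", res.message)
            else:
                result.complete = False
                result.status = "solver_error"
                log.warning("MILP solver error: %s", res.message)
            break
        # re-solve the flux under the *rounded* integer assignment: MILP
        # incumbents may leak tiny flux through z=0 columns within the
        # solver's integrality tolerance (big-M x tolerance), so the raw
        # v is not trustworthy
        z_int = res.x[nc:] > 0.5
        v = _clean_flux(
            z_int, np.array(rows + cut_rows), np.array(lo + [-np.inf] * len(cut_rows)),
            np.array(hi + cut_ub), ub, nc,
        )
        if v is None:
            # assignment infeasible once the leak is closed: forbid exactly
            # this z-pattern and retry (cannot exclude any EFM)
            cut = np.zeros(nv)
            cut[nc:][z_int] = 1.0
            cut[nc:][~z_int] = -1.0
            cut_rows.append(cut)
            cut_ub.append(float(np.count_nonzero(z_int) - 1))
            continue
        v = np.where(v > EPS_ACTIVATION / 2, v, 0.0)
        if not np.any(v > 0):
            result.status = "degenerate"
            break
        # decompose: peel conformal kernel components off the solution until
        # an elementary mode remains (identity when already elementary)
        v = _extract_elementary_split(v, N)
        supp_split = np.flatnonzero(v > 0)
        # no-good cut: exclude this support and all its supersets.  The cut
        # support is (contained in) an EFM support, and EFM supports are
        # pairwise incomparable, so no other EFM is ever lost.
        cut = np.zeros(nv)
        cut[nc + supp_split] = 1.0
        cut_rows.append(cut)
        cut_ub.append(float(len(supp_split) - 1))

        vec = {rids[j]: float(v[j]) for j in supp_split}
        net = {r: x for r, x in merge_split_fluxes(vec, pairs).items() if x != 0.0}
        mode = FluxMode(net).normalized()
        ok_ss = is_steady_state(mode.vector, network, tol=1e-6)
        elem = is_elementary(mode.vector, network)
        ok_cs, _ = satisfies(mode, cs, eps=eps)
        if ok_ss and elem and ok_cs and mode.signature() not in seen:
            mode.verified_elementary = True
            seen.add(mode.signature())
            result.append(mode)
    return result


def _clean_flux(
    z_int: np.ndarray,
    A: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    ub: np.ndarray,
    nc: int,
) -> Optional[np.ndarray]:
    """Minimal-total flux consistent with a fixed integer assignment.

    Substitutes the rounded z into every constraint row and solves the
    remaining LP over the fluxes with parsimony as a deterministic
    tie-break; returns None when the assignment admits no flux.
    """
    from ._lp import solve_lp

    a_v = A[:, :nc]
    a_z = A[:, nc:]
    z = z_int.astype(float)
    lo_v = lo - a_z @ z
    hi_v = hi - a_z @ z
    eq = lo_v == hi_v
    A_eq = a_v[eq]
    b_eq = hi_v[eq]
    rows_ub, rhs_ub = [], []
    for i in np.flatnonzero(~eq):
        if np.isfinite(hi_v[i]):
            rows_ub.append(a_v[i])
            rhs_ub.append(hi_v[i])
        if np.isfinite(lo_v[i]):
            rows_ub.append(-a_v[i])
            rhs_ub.append(-lo_v[i])
    bounds = [
        (EPS_ACTIVATION, ub[j]) if z_int[j] else (0.0, 0.0) for j in range(nc)
    ]
    res = solve_lp(
        np.ones(nc),
        A_eq=A_eq if len(A_eq) else None,
        b_eq=b_eq if len(A_eq) else None,
        A_ub=np.array(rows_ub) if rows_ub else None,
        b_ub=np.array(rhs_ub) if rows_ub else None,
        bounds=bounds,
    )
    if res.status != "optimal" or res.x is None:
        return None
    return res.x


def _extract_elementary_split(v: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Reduce a nonnegative steady flux to an elementary one within its support.

    While the rank test fails, a kernel vector of N restricted to the
    support (not proportional to the flux itself) is subtracted with the
    largest step that keeps all fluxes nonnegative; at least one support
    element vanishes per step, so this terminates with an elementary mode
    whose support is contained in the original one.
    """
    v = v.copy()
    for _ in range(v.size):
        supp = np.flatnonzero(v > 0)
        if supp.size == 0:
            return v
        sub = N[:, supp]
        u, s, vt = np.linalg.svd(sub) if sub.size else (None, np.array([]), None)
        smax = s[0] if s.size else 0.0
        rank = int(np.sum(s > 1e-9 * smax)) if smax > 0 else 0
        if rank >= supp.size - 1:
            return v
        kernel = vt[rank:]
        vs = v[supp]
        w = None
        for cand in kernel:
            cos = abs(cand @ vs) / (np.linalg.norm(cand) * np.linalg.norm(vs))
            if cos < 1.0 - 1e-9:
                # make it non-proportional *and* orthogonal-ish to v
                w = cand - (cand @ vs) / (vs @ vs) * vs
                break
        if w is None:  # numerically proportional kernel: give up gracefully
            return v
        if not np.any(w > 1e-12):
            w = -w
        pos = w > 1e-12
        t = np.min(vs[pos] / w[pos])
        vs = vs - t * w
        vs[vs < 1e-9 * max(1.0, vs.max(initial=0.0))] = 0.0
        v[supp] = vs
    return v


def _bounds(lb: np.ndarray, ub: np.ndarray):
    from scipy.optimize import Bounds

    return Bounds(lb=lb, ub=ub)


def _milp_options(time_limit, t0, mip_rel_gap, solve_time_limit):
    opts = {"presolve": True, "mip_rel_gap": mip_rel_gap, "disp": False}
    per_solve = solve_time_limit
    if time_limit is not None:
        per_solve = min(per_solve, max(1.0, time_limit - (time.monotonic() - t0)))
    opts["time_limit"] = per_solve
    return opts


@contextlib.contextmanager
def _quiet_solver():
    """Mute C-level solver chatter that bypasses Python logging."""
    try:
        sys.stdout.flush()
        sys.stderr.flush()
        saved = [os.dup(fd) for fd in (1, 2)]
        devnull = os.open(os.devnull, os.O_WRONLY)
        os.dup2(devnull, 1)
        os.dup2(devnull, 2)
        os.close(devnull)
    except OSError:  # exotic stdio (no fd): run unmuted
        yield
        return
    try:
        yield
    finally:
        sys.stdout.flush()
        sys.stderr.flush()
        for fd, s in zip((1, 2), saved):
            os.dup2(s, fd)
            os.close(s)


def _empty_result(status: str) -> SampleResult:
    out = SampleResult()
    out.status = status
    return out
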