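"""Regression scoring of flux modes against exometabolomic exchange data.

Measured exchange fluxes (fmol/cell/h, uptake negative) for NCI-60 cancer
cell lines are summarised as per-metabolite mean +/- SD with a sign
category; a flux mode is scored by ordinary least squares of the measured
means (y, fmol/cell/h) on the mode's non-null exchange values
(x, dimensionless), so R^2 is scale-invariant in the mode and RMSE carries
data units.  Modes are ranked by R^2 (ties: lower RMSE, then index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression

from .efm import FluxMode
from .model import MetabolicNetwork, exchange_flux

__all__ = [
    "ExoEntry",
    "ExometabolomicsTable",
    "RegressionScore",
    "UndefinedScoreError",
    "table1_constants",
    "regress_mode",
    "rank_modes",
    "per_line_first_places",
    "summarize_exchanges",
]


class UndefinedScoreError(ValueError):
    """Fewer than two usable points: the regression is undefined."""


@dataclass(frozen=True)
class ExoEntry:
    mean: Optional[float]
    sd: Optional[float]
    sign: str  # '-', '+' or '+/-'
    kind: str  # 'hard', 'desired' or 'unconstrained'
    status: str = "numeric"  # 'numeric', 'uncalibrated' or 'missing'


@dataclass
class ExometabolomicsTable:
    entries: Dict[str, ExoEntry] = field(default_factory=dict)
    per_line: Optional[pd.DataFrame] = None  # cell lines x metabolites

    def numeric_metabolites(self) -> List[str]:
        return [m for m, e in self.entries.items() if e.status == "numeric"]


@dataclass(frozen=True)
class RegressionScore:
    r2: float
    rmse: float
    slope: float
    intercept: float
    n_points: int


def table1_constants() -> ExometabolomicsTable:
    """Mean +/- SD exchange fluxes of the NCI-60 panel, with sign categories.

    Units fmol/cell/h; uptake negative.  Pyruvate's measurement is
    uncalibrated and formate/histidine are missing, so those three carry a
    sign category but no usable numeric mean.
    """
    e = ExoEntry
    entries = {
        "glucose": e(-326.87, 196.12, "-", "hard"),
        "lactate": e(442.20, 289.40, "+", "hard"),
        "glutamine": e(-82.48, 56.20, "-", "hard"),
        "glutamate": e(13.54, 16.99, "+", "desired"),
        "serine": e(-11.57, 7.05, "-", "desired"),
        "glycine": e(0.96, 2.97, "+/-", "unconstrained"),
        "alanine": e(15.89, 13.34, "+", "desired"),
        "proline": e(1.21, 1.49, "+/-", "unconstrained"),
        "asp_asn": e(-3.33, 3.39, "-", "desired"),
        "arginine": e(-4.90, 4.44, "-", "desired"),
        "tiv": e(-14.90, 7.99, "-", "desired"),
        "yflkw": e(-19.80, 10.57, "-", "desired"),
        "xtp": e(0.10, 0.22, "+/-", "unconstrained"),
        "pyruvate": e(None, None, "+", "desired", "uncalibrated"),
        "formate": e(None, None, "+/-", "unconstrained", "missing"),
        "histidine": e(None, None, "-", "desired", "missing"),
        "cysteine": e(0.05, 0.08, "+/-", "unconstrained"),
        "methionine": e(-2.11, 1.23, "+/-", "unconstrained"),
    }
    return ExometabolomicsTable(entries=entries)


def mode_exchange_vector(
    mode: FluxMode,
    network: MetabolicNetwork,
    metabolites: Sequence[str],
    aliases: Optional[Mapping[str, str]] = None,
) -> Dict[str, float]:
    """Signed exchange value of the mode for each listed metabolite."""
    return {
        m: exchange_flux(mode.vector, m, network, aliases=aliases)
        for m in metabolites
    }


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionScore:
    reg = LinearRegression().fit(x.reshape(-1, 1), y)
    pred = reg.predict(x.reshape(-1, 1))
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    return RegressionScore(
        r2=r2,
        rmse=rmse,
        slope=float(reg.coef_[0]),
        intercept=float(reg.intercept_),
        n_points=len(x),
    )


def regress_mode(
    mode: FluxMode,
    table: ExometabolomicsTable,
    network: MetabolicNetwork,
    aliases: Optional[Mapping[str, str]] = None,
    means: Optional[Mapping[str, float]] = None,
) -> RegressionScore:
    """OLS of measured means on the mode's non-null exchange values.

    Only metabolites with a numeric mean *and* non-zero mode exchange enter
    the fit.  ``means`` overrides the table means (used for per-cell-line
    scoring).  Fewer than two points raises :class:`UndefinedScoreError`.
    """
    usable = table.numeric_metabolites() if means is None else [
        m for m in table.entries if m in means and means[m] is not None
    ]
    xs, ys = [], []
    for met in usable:
        x = exchange_flux(mode.vector, met, network, aliases=aliases)
        if x == 0.0:
            continue
        y = table.entries[met].mean if means is None else means[met]
        xs.append(x)
        ys.append(y)
    if len(xs) < 2:
        raise UndefinedScoreError(
            f"only {len(xs)} non-null exchange value(s) with numeric data"
        )
    return _ols(np.array(xs), np.array(ys))


def rank_modes(
    modes: Sequence[FluxMode],
    table: ExometabolomicsTable,
    network: MetabolicNetwork,
    aliases: Optional[Mapping[str, str]] = None,
) -> List[Tuple[int, RegressionScore]]:
    """Modes ordered by descending R^2 (ties: ascending RMSE, then index)."""
    scored = [
        (i, regress_mode(m, table, network, aliases=aliases))
        for i, m in enumerate(modes)
    ]
    return sorted(scored, key=lambda t: (-t[1].r2, t[1].rmse, t[0]))


def per_line_first_places(
    modes: Sequence[FluxMode],
    per_line: pd.DataFrame,
    table: ExometabolomicsTable,
    network: MetabolicNetwork,
    aliases: Optional[Mapping[str, str]] = None,
) -> Tuple[Dict[int, int], Dict[int, float]]:
    """First-place counts and mean R^2 per mode across cell lines.

    ``per_line`` has one row per cell line and one column per metabolite
    (extra columns such as a cancer-type label are ignored).  Lines with
    fewer than two usable metabolites are skipped with a warning.
    """
    firsts: Dict[int, int] = {}
    totals: Dict[int, List[float]] = {i: [] for i in range(len(modes))}
    known = set(table.entries)
    for line, row in per_line.iterrows():
        means = {
            m: float(row[m]) for m in per_line.columns
            if m in known and pd.notna(row[m])
        }
        try:
            scored = [
                (i, regress_mode(m, table, network, aliases=aliases, means=means))
                for i, m in enumerate(modes)
            ]
        except UndefinedScoreError as err:
            warnings.warn(f"cell line {line!r} skipped: {err}")
            continue
        scored.sort(key=lambda t: (-t[1].r2, t[1].rmse, t[0]))
        best = scored[0][0]
        firsts[best] = firsts.get(best, 0) + 1
        for i, sc in scored:
            totals[i].append(sc.r2)
    mean_r2 = {i: float(np.mean(v)) if v else float("nan") for i, v in totals.items()}
    return firsts, mean_r2


def summarize_exchanges(
    modes: Sequence[FluxMode],
    network: MetabolicNetwork,
    metabolites: Sequence[str],
    aliases: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Min/max/mean/median/SD of exchange values per metabolite over modes."""
    if not modes:
        raise ValueError("empty mode list")
    data = {
        met: [exchange_flux(m.vector, met, network, aliases=aliases) for m in modes]
        for met in metabolites
    }
    df = pd.DataFrame(data)
    return pd.DataFrame(
        {
            "min": df.min(),
            "max": df.max(),
            "mean": df.mean(),
            "median": df.median(),
            "sd": df.std(ddof=1).fillna(0.0),
        }
    )


def max_r2_over_samples(
    X: np.ndarray,
    y: np.ndarray,
    min_points: int = 2,
) -> float:
    """Largest R^2 of y-on-x OLS over the rows of X, masking zero entries.

    Closed-form per-row least squares consistent with :func:`regress_mode`
    (verified in the test suite); used to score large flux-sampling runs.
    """
    best = -np.inf
    for row in X:
        mask = row != 0.0
        if mask.sum() < min_points:
            continue
        x, yy = row[mask], y[mask]
        xm, ym = x.mean(), yy.mean()
        sxx = float(np.sum((x - xm) ** 2))
        if sxx == 0:
            continue
        slope = float(np.sum((x - xm) * (yy - ym))) / sxx
        pred = ym + slope * (x - xm)
        ss_res = float(np.sum((yy - pred) ** 2))
        ss_tot = float(np.sum((yy - ym) ** 2))
        if ss_tot == 0:
            continue
        best = max(best, 1.0 - ss_res / ss_tot)
    return best
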