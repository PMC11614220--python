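"""End-to-end orchestration: model -> compression -> EFMs -> scoring -> baselines.

The pipeline reproduces the analysis workflow at configurable size: build
or load the stroma-extended model, compress it, sample constrained EFMs
(or load a pre-computed EFM matrix), rank the modes against exchange-flux
data, and optionally compare with parsimonious FBA and hit-and-run flux
sampling, per cell line and per cancer type.  Every stage writes CSV/JSON
artifacts plus a provenance record, and reruns with the same configuration
and seeds are deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .baselines import flux_sample, pfba
from .compression import compress, decompress
from .constraints import (
    default_constraint_set,
    sample_constrained_efms,
    satisfies,
    translate_constraints,
)
from .efm import FluxMode, read_efm_matrix, write_efm_matrix
from .model import MetabolicNetwork, exchange_flux
from .sbml_io import read_sbml, write_sbml
from .scoring import (
    max_r2_over_samples,
    per_line_first_places,
    rank_modes,
    regress_mode,
    table1_constants,
)
from .synthetic_data import (
    DEFAULT_EXCHANGE_ALIASES,
    SyntheticSpec,
    generate_cell_lines,
    synthetic_stroma_network,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run."""

    model: str = "build"  # 'build' or a path to an SBML file
    efm_source: str = "sample"  # 'sample' or a path to an EFM matrix CSV
    n_modes: int = 100
    seed: int = 0
    time_limit: Optional[float] = 600.0
    data_source: str = "table1"  # 'table1', 'synthetic' or a per-line CSV path
    n_synthetic_lines: int = 60
    run_pfba: bool = True
    pfba_bound: float = 15.0
    flux_sampling_n: Sequence[int] = ()
    aliases: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_EXCHANGE_ALIASES))
    output_dir: str = "stromaefm_out"
    dry_run: bool = False

    def validate(self) -> None:
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if any(n < 1 for n in self.flux_sampling_n):
            raise ValueError("flux sampling sizes must be positive")
        for attr in ("model", "efm_source", "data_source"):
            value = getattr(self, attr)
            if attr == "model" and value == "build":
                continue
            if attr == "efm_source" and value == "sample":
                continue
            if attr == "data_source" and value in ("table1", "synthetic"):
                continue
            if not Path(value).exists():
                raise FileNotFoundError(f"{attr} path does not exist: {value}")


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute the configured analysis; returns the JSON-ready summary."""
    config.validate()
    if config.dry_run:
        return {"dry_run": True, "config": dataclasses.asdict(config)}

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    aliases = config.aliases

    def stage(name):
        t0 = time.monotonic()

        def done(**info):
            report["stages"][name] = {"seconds": round(time.monotonic() - t0, 2), **info}
            log.info("stage %s done in %.1fs", name, time.monotonic() - t0)

        return done

    # -- model -------------------------------------------------------------
    fin = stage("model")
    if config.model == "build":
        network = synthetic_stroma_network()
    else:
        network = read_sbml(config.model)
    write_sbml(network, str(out / "model.xml"))
    fin(
        reactions=len(network.reactions),
        metabolites=len(network.metabolites),
        exchanges=len(network.exchange_reactions),
    )

    # -- compression -------------------------------------------------------
    fin = stage("compression")
    compressed, cmap = compress(network)
    cmap.to_json(str(out / "compression_map.json"))
    write_sbml(compressed, str(out / "model_compressed.xml"))
    n_int = len(compressed.internal_metabolites)
    fin(
        reactions=len(compressed.reactions),
        internal_metabolites=n_int,
        external_metabolites=len(compressed.metabolites) - n_int,
        blocked=len(cmap.blocked),
    )

    # -- constraints & modes ----------------------------------------------
    table = table1_constants()
    cs = default_constraint_set(table, network, aliases=aliases)
    cs.to_json(str(out / "constraints.json"))

    fin = stage("modes")
    if config.efm_source == "sample":
        # sample on the compressed network, decompress back
        ccs = translate_constraints(cs, cmap)
        compressed_modes = sample_constrained_efms(
            compressed, ccs, n=config.n_modes, seed=config.seed,
            time_limit=config.time_limit,
        )
        modes: List[FluxMode] = [
            FluxMode(
                {k: v for k, v in decompress(m.vector, cmap).items() if v != 0.0}
            ).normalized()
            for m in compressed_modes
        ]
    else:
        modes = read_efm_matrix(config.efm_source)
    write_efm_matrix(modes, network, str(out / "modes.csv"))
    violations = [satisfies(m, cs)[1] for m in modes]
    fin(n_modes=len(modes), all_satisfy=all(not v for v in violations))

    # -- regression ranking ------------------------------------------------
    fin = stage("ranking")
    ranked = rank_modes(modes, table, network, aliases=aliases)
    rows = [
        {
            "mode": i,
            "r2": sc.r2,
            "rmse": sc.rmse,
            "slope": sc.slope,
            "intercept": sc.intercept,
            "n_points": sc.n_points,
        }
        for i, sc in ranked
    ]
    pd.DataFrame(rows).to_csv(out / "scores.csv", index=False)
    best_i, best = ranked[0]
    summary = {
        "n_modes": len(modes),
        "best_mode": best_i,
        "best_r2": best.r2,
        "best_rmse": best.rmse,
        "r2_range": [ranked[-1][1].r2, best.r2],
        "rmse_range": [
            min(sc.rmse for _, sc in ranked),
            max(sc.rmse for _, sc in ranked),
        ],
        "best_mode_exchanges": {
            met: exchange_flux(modes[best_i].vector, met, network, aliases=aliases)
            for met in table.entries
        },
    }
    fin(best_r2=round(best.r2, 4))

    # -- per-line analysis -------------------------------------------------
    if config.data_source != "table1":
        fin = stage("per_line")
        if config.data_source == "synthetic":
            per_line = generate_cell_lines(
                table, SyntheticSpec(n_lines=config.n_synthetic_lines, seed=config.seed)
            )
        else:
            per_line = pd.read_csv(config.data_source, index_col=0)
        per_line.to_csv(out / "cell_lines.csv")
        firsts, mean_r2 = per_line_first_places(
            modes, per_line, table, network, aliases=aliases
        )
        summary["per_line_first_places"] = firsts
        summary["per_line_mean_r2_best"] = max(mean_r2.values())
        if "cancer_type" in per_line.columns:
            by_type = {}
            for ctype, group in per_line.groupby("cancer_type"):
                means = group.drop(columns="cancer_type").mean()
                scored = [
                    (i, regress_mode(m, table, network, aliases=aliases,
                                     means=means.to_dict()))
                    for i, m in enumerate(modes)
                ]
                scored.sort(key=lambda t: (-t[1].r2, t[1].rmse, t[0]))
                by_type[ctype] = {"best_mode": scored[0][0],
                                  "best_r2": scored[0][1].r2}
            summary["per_cancer_type"] = by_type
        fin(n_lines=len(per_line))

    # -- baselines ---------------------------------------------------------
    if config.run_pfba:
        fin = stage("pfba")
        sol = pfba(network, cs, flux_bound=config.pfba_bound)
        summary["pfba_status"] = sol.status
        if sol.status == "optimal":
            pd.Series(sol.fluxes).to_csv(out / "pfba_fluxes.csv", header=False)
            mode = FluxMode(
                {k: v for k, v in sol.fluxes.items() if v != 0.0}
            ).normalized()
            sc = regress_mode(mode, table, network, aliases=aliases)
            gluc = exchange_flux(sol.fluxes, "glucose", network, aliases=aliases)
            lac = exchange_flux(sol.fluxes, "lactate", network, aliases=aliases)
            summary["pfba_r2"] = sc.r2
            summary["pfba_lactate_glucose_ratio"] = (
                lac / gluc if gluc != 0 else float("nan")
            )
        fin(status=sol.status)

    if config.flux_sampling_n:
        mets = table.numeric_metabolites()
        y = np.array([table.entries[m].mean for m in mets])
        summary["flux_sampling_max_r2"] = {}
        for n_samp in config.flux_sampling_n:
            fin = stage(f"flux_sampling_{n_samp}")
            _, mat, rids = flux_sample(
                network, cs, n=n_samp, seed=config.seed,
            )
            X = _exchange_matrix(mat, rids, mets, network, aliases)
            summary["flux_sampling_max_r2"][str(n_samp)] = max_r2_over_samples(X, y)
            fin(n=int(mat.shape[0]))

    report["summary"] = summary
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    with open(out / "provenance.json", "w") as fh:
        json.dump(
            {
                "config": dataclasses.asdict(config),
                "config_hash": report["config_hash"],
                "version": __version__,
            },
            fh,
            indent=1,
            default=str,
        )
    return report


def _exchange_matrix(
    mat: np.ndarray,
    rids: Sequence[str],
    metabolites: Sequence[str],
    network: MetabolicNetwork,
    aliases: Dict[str, str],
) -> np.ndarray:
    """Signed exchange values (uptake negative) for each sample row."""
    boundary = {m.id for m in network.metabolites if m.is_boundary}
    cols = []
    signs = []
    for met in metabolites:
        r = network.exchange_reaction_for(met, aliases=aliases)
        cols.append(list(rids).index(r.id))
        internal = [c for k, c in r.stoichiometry.items() if k not in boundary]
        signs.append(-1.0 if internal and internal[0] > 0 else 1.0)
    return mat[:, cols] * np.array(signs)
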