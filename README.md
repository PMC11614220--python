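# stromaefm

Constraint-based metabolic analysis linking the **Warburg effect** (aerobic
glycolysis — glucose fermented to lactate even with oxygen available) to the
production of the **tumoral stroma**: collagen, the inflammation markers
IL1β/TNFα, and the angiogenesis growth factor VEGF-A.

The package is for systems biologists who want to decompose a medium-scale
metabolic model into **Elementary Flux Modes (EFMs)** under biological
constraints, rank the modes against exometabolomic measurements, and compare
the result with the standard optimisation and sampling baselines.

## The method

A metabolic network with internal stoichiometric matrix *N* is assumed at
steady state, *N·ν = 0*, with irreversible reactions constrained to ν ≥ 0.
An **EFM** is a steady-state flux vector of minimal support — no feasible
flux uses a strict subset of its active reactions — and is unique up to
positive scaling (an extreme ray of the flux cone). Elementarity is decided
by the rank test: ν is elementary iff rank(N restricted to supp(ν)) =
|supp(ν)| − 1.

Because exhaustive enumeration is hopeless at this scale, EFMs are *sampled
under constraints* derived from NCI-60 cancer-cell exchange-flux data
(fmol/cell/h, uptake negative):

* **hard activities** — glucose uptake, lactate secretion and glutamine
  uptake must carry flux (ν_fwd > 0);
* **forbidden directions** — metabolites observed only consumed (or only
  secreted) must not move the other way (ν_bwd = 0), while staying unused
  is allowed;
* **linear rules** — collagen output > biomass output and stroma output >
  biomass output (stroma formation above proliferation);
* **size cap** — strictly fewer than 60 active reactions.

The sampler iterates a support-minimising mixed-integer program (Boolean
activity indicators linked to fluxes by big-M and epsilon-activation),
rank-tests every incumbent, decomposes non-elementary ones, and excludes
found supports by no-good cuts, on the enzyme-subset-**compressed** network.
Each mode ν is then scored against the measured means *y* by ordinary least
squares *y = a·x + b* over its non-null exchange values *x*, and modes are
ranked by R² (ties by RMSE). Parsimonious FBA and artificial-centering
hit-and-run flux sampling provide the baselines.

The stoichiometric model shipped with the package is a **synthetic stand-in**
core-carbon network (glycolysis, glutaminolysis, TCA + OxPhos,
serine/glycine/folate metabolism, pooled essential amino acids TIV and
YFLKW) carrying the published stroma-extension reactions — collagen bricks
(`CBS`, `COLLAG`, `XYAAS`), the marker proteins (`IL1B`, `TNFA`, `VEGFA`)
and the stroma logic (`FACT`/`INF1`/`INF2`/`STROMA`). Any SBML L3 model with
the required metabolite pools can be used instead (`read_sbml` + an alias
table).

## Worked example

```python
from stromaefm import (
    synthetic_stroma_network, table1_constants, default_constraint_set,
    compress, translate_constraints, sample_constrained_efms, decompress,
    FluxMode, rank_modes, exchange_flux,
)
from stromaefm.synthetic_data import DEFAULT_EXCHANGE_ALIASES as AL

net = synthetic_stroma_network()
table = table1_constants()
cs = default_constraint_set(table, net, aliases=AL)
comp, cmap = compress(net)
modes = [
    FluxMode({k: v for k, v in decompress(m.vector, cmap).items() if v}).normalized()
    for m in sample_constrained_efms(comp, translate_constraints(cs, cmap),
                                     n=40, seed=11, time_limit=120)
]
ranked = rank_modes(modes, table, net, aliases=AL)
best_i, best = ranked[0]
print(f"{len(modes)} modes, R2 {ranked[-1][1].r2:.3f}..{best.r2:.3f}")
print("best mode glutamine exchange:",
      round(exchange_flux(modes[best_i].vector, "glutamine", net, AL), 3))
```

prints (seed 11):

```
40 modes, R2 0.032..0.710
best mode glutamine exchange: -0.424
```

Every sampled mode carries the constrained phenotype — glucose in, lactate
out, glutamine in, collagen and stroma produced — and the R² spread shows
how differently the modes' exchange stoichiometries match the measured
panel; the best mode consumes glutamine (negative = uptake, in the mode's
dimensionless scale), feeding glutamate, proline and serine/glycine
synthesis for collagen. The same run is available from the shell:

```sh
stromaefm report --seed 11 --out results/
```

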