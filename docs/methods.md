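# Methods

## Model and assumptions

The analysis operates on a three-compartment stoichiometric network
(external / cytosol / mitochondrion). Boundary metabolites are excluded
from the balance, so steady state means *N·ν = 0* over internal
metabolites only; concentrations and kinetics are not modelled, and all
conclusions are about flux *ratios* (modes are rays, normalised so the
largest absolute flux is 1). Exchange fluxes are always reported uptake-
negative / secretion-positive, normalised from the reaction's stoichiometry
rather than from any assumed writing convention in the file.

The packaged network (`synthetic_data.synthetic_core_network`, plus
`stroma.build_stroma_extension`) is a **synthetic stand-in** for the
original published core-carbon model, which is distributed as third-party
supplementary material and is not packaged. The stand-in keeps the study's
structure: glycolysis split around glyceraldehyde-3-phosphate (so serine
synthesis and nucleotide synthesis branch off it), lactate dehydrogenase,
a lumped TCA cycle with reductive citrate export for lipogenesis, NAD(H)
pools per compartment with a one-way cytosol→mitochondrion shuttle,
oxidative phosphorylation with a 2.5 ATP/NADH yield, the folate cycle
(SHMT, methylene-THF ↔ formate, glycine cleavage, histidine degradation
feeding THF), the conflated amino-acid pools TIV (Thr/Ile/Val) and YFLKW
(Tyr/Phe/Leu/Lys/Trp) with uptake and degradation as single group
reactions, and a protein/nucleotide/lipid biomass reaction. The stroma
extension reactions use the published stoichiometries verbatim: collagen
bricks of 100 residues at 33% Gly / 2×8.5% Pro+Hyp / 50% equiprobable
"X-Y" residues, marker proteins whose reactant coefficients are residue
proportions of the consensus sequences (product coefficient = inverse
length), and stroma release requiring one inflammation marker *and* the
growth factor. Consequently **absolute inventories and scores differ from
the published ones** (70 reactions / 22 exchanges here, compressing to 50
reactions over 32 internal + 22 external metabolites); what carries over
is the procedure and the qualitative structure of the results.

## Constraints

Exchange observations enter as four classes: hard activities (strict
forward flux: glucose uptake, lactate secretion, glutamine uptake),
forbidden directions (the direction opposite to a one-sided observation is
zero; "+/−" metabolites are unconstrained), strict linear inequalities
(collagen > biomass and stroma > biomass on the exchange fluxes), and a
support cap (< 60 active reactions). Strictness cannot be expressed in an
LP, so ">" is implemented with a margin of 1e−6 on the mode's normalised
scale; `satisfies` uses the same epsilon. Constraints are expressed on
directed reaction halves, matching the forward/backward split used
throughout; a user-editable alias table maps data-level metabolite names
to exchange reaction ids so foreign SBML naming schemes need no code
changes.

## Network compression

Blocked reactions (max |ν| = 0 under the bounded steady-state cone,
decided by per-reaction LPs with a |ν| ≤ 1000 box) are removed; reactions
whose kernel rows are proportional (cosine > 1 − 1e−9 on a null-space
basis of *N*) form enzyme subsets and are merged with ratio-scaled summed
stoichiometry. Subsets are detected on the *unsplit* network — splitting
reversibles first would add two-cycle kernel directions that destroy the
proportionality signal — and reversibles are split downstream in the
engines. Decompression assigns each member its subset flux times its
ratio, and blocked reactions zero; on all toy fixtures the EFM sets of
compressed and original networks correspond bijectively (tested against
the brute-force oracle).

## Constrained EFM sampling

One MILP per mode over the split compressed network: variables (ν, z) with
z Boolean activity indicators, ν_r ≤ M·z_r (M = 1000), ν_r ≥ ε·z_r
(ε = 1e−3; ε was chosen so M/ε stays within the solver's feasibility
tolerances — smaller values provoke false infeasibility), two-cycle
exclusion z_fwd + z_bwd ≤ 1, the constraint classes above, and all
accumulated cuts. The objective minimises Σ w_r z_r with seeded weights
w_r ∈ [1, 1.1], which both randomises the search and biases it to small
supports; solves stop at 25% relative gap or a per-solve time limit, since
optimality is unnecessary — any rank-test-verified solution is an EFM.

Three safeguards make the loop sound and terminating:

1. **Integer-assignment cleaning.** MILP incumbents can leak flux of order
   M × (integrality tolerance) through z = 0 columns, so the flux is
   re-solved by an LP with z fixed to its rounded values (parsimonious
   total flux as a deterministic tie-break). An assignment with no flux is
   excluded by an exact no-good cut on z.
2. **Decomposition.** A non-elementary solution is reduced inside its own
   support by repeatedly subtracting a kernel vector of N restricted to
   the support with the largest step that keeps all split fluxes
   nonnegative (each step zeroes at least one reaction), yielding an EFM
   contained in the solution.
3. **Superset cuts.** The support of the resulting EFM is excluded
   together with all supersets: EFM supports are pairwise incomparable, so
   no other EFM is ever cut. Termination follows because every iteration
   excludes a new support.

On seeded toy networks (≤ 15 reactions) the sampler provably empties the
constrained EFM set and matches the brute-force oracle exactly; this is
asserted in the suite. Determinism given (network, constraints, n, seed)
holds at toy scale; on the full model HiGHS is deterministic per
environment but not guaranteed across versions.

## Exhaustive engines (fixture scale)

`enumerate_efms_exhaustive` is a Double Description tableau on the split
network (pairwise positive/negative combination per balance row with the
combinatorial adjacency test), guarded at 32 columns. The independent
oracle `brute_force_efms` scans support subsets: a subset is an EFM
support iff N restricted to it has a one-dimensional kernel whose vector
has full support and can be oriented to respect irreversibilities
(guarded at 18 reactions). Rank decisions use singular values with a
1e−9 relative threshold; support membership uses 1e−9 relative to the
largest flux. Fully reversible modes are canonicalised to a positive flux
on the lexicographically first support reaction so both engines count
them once.

## Scoring

`regress_mode` fits measured means *y* (fmol/cell/h) on mode exchange
values *x* (dimensionless) by OLS with intercept, restricted to
metabolites with numeric means and x ≠ 0; R² = 1 − SS_res/SS_tot (not
clamped), RMSE in data units. Regressing y-on-x rather than x-on-y keeps
RMSE in measurement units and makes scores invariant to the mode's
arbitrary scale. Pyruvate (uncalibrated), formate and histidine (missing)
never enter fits even when the mode uses them. Ranking is by descending
R², ties by ascending RMSE then index. Per-line and per-cancer-type
analyses reuse the same fit with per-line means; exchange statistics use
the sample SD (ddof = 1). A closed-form row scorer
(`max_r2_over_samples`) handles large sampling matrices and is asserted
equal to the reference fit.

## Baselines

*pFBA*: stage 1 maximises ν_EX_BIOMASS + ν_EX_COLLAGEN + ν_EX_STROMA with
every split flux in [0, 15]; stage 2 fixes the optimum and minimises total
split flux (L1 parsimony). The support cap is not applied, matching the
way the optimisation baseline is normally run. Because parsimonious
optima can be degenerate, the solution is cross-checked between HiGHS and
GLPK. Essentiality fixes one reaction (both halves) to zero and tests
feasibility. *Flux sampling*: artificial-centering hit-and-run on the
polytope {steady state, relaxed constraints, 0 ≤ ν ≤ 15 per split flux}.
A flux-variability pass first pins zero-range columns so the walk lives on
the polytope's affine hull; the start point maximises the smallest slack;
directions go through the running sample centre 90% of the time; the
chain warms up 1000 steps and keeps every 10th state. Chord arithmetic is
incremental with re-anchoring when drift exceeds 1e−9.

## Synthetic data generators

Cell-line tables draw each metabolite from Normal(mean, SD) of the
packaged panel constants; one-sided metabolites are redrawn up to 100
times, then clipped to zero, approximating a truncated normal. A
round-robin label over nine tumour types exercises the per-type
aggregation. Planted datasets are c_i · (mode exchange vector) + Gaussian
noise with c_i ~ U(0.5, 2); in the recovery harness "signal" is defined
as the largest absolute exchange value of the planted mode. All
generators are pure functions of their arguments and seed.

## Problem sizes used

The packaged analyses run 60 sampled modes (test fixtures use 30), flux
samples of 1 000 and 50 000, 60 synthetic cell lines, and toy fixtures of
4–14 reactions — sizes chosen so a complete rerun takes minutes on one
CPU while every statistic is still computed, not copied.

## Known limitations

* The stand-in network reproduces the study's structure, not the original
  model's inventory; absolute counts, scores and the best mode's exchange
  values are specific to it.
* EFMs that differ only in internal routing can share near-identical
  exchange signatures (cosine similarity > 0.99 among sampled modes).
  Exometabolomics then cannot distinguish them: planted-mode recovery is
  perfect at 0.1% noise but degrades by ~40% of per-line first places at
  5% noise, the analogue of near-tied modes splitting first places in
  per-line rankings on real data.
* Strict inequalities are margin-approximated (1e−6), so modes hugging a
  constraint boundary tighter than the margin are unreachable.
* The hit-and-run chain is thinned, not independence-sampled; tail
  quantities (the max R² over samples) converge slowly with n.
* The MILP sampler's output distribution over EFMs is not uniform; it is
  biased toward small supports by construction.
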