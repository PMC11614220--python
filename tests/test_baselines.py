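"""Parsimonious FBA, essentiality, and hit-and-run sampling."""

import numpy as np
import pytest

from stromaefm import (
    ConstraintSet,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    brute_force_efms,
    flux_sample,
    is_essential,
    is_steady_state,
    pfba,
)


def _parallel_routes_net():
    M, R = Metabolite, Reaction
    return MetabolicNetwork(
        metabolites=[
            M("Sx", "Sx", "external", is_boundary=True),
            M("Px", "Px", "external", is_boundary=True),
            M("A", "A", "cytosol"), M("B", "B", "cytosol"),
        ],
        reactions=[
            R("IN", {"Sx": -1, "A": 1}),
            R("TOP", {"A": -1, "B": 1}),
            R("BOT", {"A": -1, "B": 1}),
            R("OUT", {"B": -1, "Px": 1}),
        ],
    )


class TestPFBA:
    def test_single_route_toy_recovers_the_unique_efm(self, chain):
        sol = pfba(chain, ConstraintSet(), flux_bound=10.0,
                   objective_reactions=("OUT",))
        assert sol.status == "optimal"
        efm = brute_force_efms(chain)[0]
        scale = sol.fluxes["OUT"] / efm.vector["OUT"]
        for rid, v in efm.vector.items():
            assert sol.fluxes[rid] == pytest.approx(scale * v, rel=1e-6)

    def test_stage2_preserves_the_stage1_objective(
        self, stroma_net, constraint_set
    ):
        sol = pfba(stroma_net, constraint_set, flux_bound=15.0)
        assert sol.status == "optimal"
        total = sum(
            sol.fluxes.get(r, 0.0)
            for r in ("EX_BIOMASS", "EX_COLLAGEN", "EX_STROMA")
        )
        assert total == pytest.approx(sol.objective_value, rel=1e-8)

    def test_two_backends_agree(self, stroma_net, constraint_set):
        a = pfba(stroma_net, constraint_set, flux_bound=15.0, backend="highs")
        b = pfba(stroma_net, constraint_set, flux_bound=15.0, backend="glpk")
        assert a.status == b.status == "optimal"
        assert a.objective_value == pytest.approx(b.objective_value, rel=1e-6)
        assert a.fluxes["CBS"] == pytest.approx(b.fluxes["CBS"], rel=0.05)

    def test_solution_is_steady_and_respects_bounds(
        self, stroma_net, constraint_set
    ):
        sol = pfba(stroma_net, constraint_set, flux_bound=15.0)
        assert is_steady_state(sol.fluxes, stroma_net, tol=1e-6)
        assert max(abs(v) for v in sol.fluxes.values()) <= 15.0 + 1e-6

    def test_infeasible_constraints_reported(self, chain):
        cs = ConstraintSet(hard_active={("IN", 1)},
                           forbidden_direction={("OUT", 1)})
        sol = pfba(chain, cs, flux_bound=10.0, objective_reactions=("OUT",))
        assert sol.status == "infeasible"

    def test_matches_cobra_fba_on_toy(self, chain):
        """Independent cross-check of stage 1 against COBRApy's FBA."""
        cobra = pytest.importorskip("cobra")
        model = cobra.Model("chain")
        mets = {
            m.id: cobra.Metabolite(m.id) for m in chain.internal_metabolites
        }
        for r in chain.reactions:
            rxn = cobra.Reaction(r.id)
            rxn.lower_bound, rxn.upper_bound = 0.0, 10.0
            model.add_reactions([rxn])
            rxn.add_metabolites(
                {mets[k]: v for k, v in r.stoichiometry.items() if k in mets}
            )
        model.objective = "OUT"
        ours = pfba(chain, ConstraintSet(), flux_bound=10.0,
                    objective_reactions=("OUT",))
        assert model.optimize().objective_value == pytest.approx(
            ours.objective_value, rel=1e-6
        )


class TestEssentiality:
    def test_only_input_is_essential(self, chain):
        cs = ConstraintSet(hard_active={("OUT", 1)})
        assert is_essential(chain, cs, "IN")

    def test_redundant_branch_is_not(self):
        net = _parallel_routes_net()
        cs = ConstraintSet(hard_active={("OUT", 1)})
        assert not is_essential(net, cs, "TOP")
        assert not is_essential(net, cs, "BOT")
        assert is_essential(net, cs, "IN")

    def test_pooled_amino_acid_uptakes_on_the_full_model(
        self, stroma_net, constraint_set
    ):
        # TIV and YFLKW have no synthesis route, only uptake: essential for
        # the collagen/stroma phenotype
        assert is_essential(stroma_net, constraint_set, "EX_TIV")
        assert is_essential(stroma_net, constraint_set, "EX_YFLKW")
        # glycine can be made via serine, so its uptake is dispensable
        assert not is_essential(stroma_net, constraint_set, "EX_GLY")


class TestFluxSampling:
    def test_samples_are_steady_and_boxed(self, stroma_net, constraint_set):
        _, mat, rids = flux_sample(
            stroma_net, constraint_set, n=300, seed=2, warmup=200, thinning=5
        )
        assert mat.shape[0] == 300
        N = stroma_net.stoichiometric_matrix()
        assert np.max(np.abs(N @ mat.T)) < 1e-6 * max(1.0, np.max(np.abs(mat)))
        assert mat.max() <= 15.0 + 1e-9

    def test_reproducible_from_seed(self, stroma_net, constraint_set):
        _, a, _ = flux_sample(stroma_net, constraint_set, n=50, seed=9,
                              warmup=100, thinning=3)
        _, b, _ = flux_sample(stroma_net, constraint_set, n=50, seed=9,
                              warmup=100, thinning=3)
        assert np.array_equal(a, b)

    def test_uniformity_on_a_known_polytope(self):
        """On the parallel-routes toy the free coordinates are uniform on a
        triangle; sample means must approach its centroid."""
        net = _parallel_routes_net()
        n = 4000
        _, mat, rids = flux_sample(net, None, n=n, seed=4, flux_bound=1.0,
                                   warmup=500, thinning=5)
        # polytope: TOP,BOT >= 0, TOP+BOT = IN <= 1 -> triangle with
        # centroid (1/3, 1/3)
        top = mat[:, rids.index("TOP")]
        bot = mat[:, rids.index("BOT")]
        se = np.sqrt(top.var() / n)
        # correlated chain: allow a generous multiple of the iid SE
        assert abs(top.mean() - 1 / 3) < 12 * se
        assert abs(bot.mean() - 1 / 3) < 12 * se
        assert np.all(top + bot <= 1.0 + 1e-9)

    def test_empty_polytope_raises(self, chain):
        cs = ConstraintSet(hard_active={("IN", 1)},
                           forbidden_direction={("OUT", 1)})
        with pytest.raises(ValueError, match="polytope"):
            flux_sample(chain, cs, n=10, seed=0)
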