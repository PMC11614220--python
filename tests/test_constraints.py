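"""Constraint encoding and the constrained EFM sampler."""

import pytest

from stromaefm import (
    ConstraintSet,
    LinearRule,
    brute_force_efms,
    default_constraint_set,
    generate_toy_network,
    is_elementary,
    is_steady_state,
    sample_constrained_efms,
    satisfies,
)


class TestDefaultConstraintSet:
    def test_hard_activities_are_the_warburg_signature(self, constraint_set):
        assert constraint_set.hard_active == {
            ("EX_GLUC", 1), ("EX_LAC", 1), ("EX_GLN", 1)
        }

    def test_consumed_metabolite_forbids_secretion(self, constraint_set):
        # aspartate is consumed-only: its secretion direction is forbidden
        assert ("EX_ASP", -1) in constraint_set.forbidden_direction

    def test_secreted_metabolite_forbids_uptake(self, constraint_set):
        # alanine is secreted-only: its uptake direction is forbidden
        assert ("EX_ALA", -1) in constraint_set.forbidden_direction

    def test_bidirectional_metabolite_unconstrained(self, constraint_set):
        rids = {rid for rid, _ in constraint_set.forbidden_direction}
        assert "EX_GLY" not in rids
        assert "EX_PRO" not in rids

    def test_linear_rules_and_size_cap(self, constraint_set):
        pairs = {(r.left, r.right) for r in constraint_set.linear}
        assert pairs == {
            ("EX_COLLAGEN", "EX_BIOMASS"), ("EX_STROMA", "EX_BIOMASS")
        }
        assert constraint_set.max_support == 60

    def test_unknown_metabolite_rejected(self, table, diamond):
        with pytest.raises(KeyError):
            default_constraint_set(table, diamond)


class TestSatisfies:
    def test_zero_hard_flux_reported(self, constraint_set):
        ok, violated = satisfies({"EX_GLUC": 1.0, "EX_GLN": 1.0}, constraint_set)
        assert not ok
        assert "hard:EX_LAC" in violated

    def test_linear_tie_violates_strictness(self):
        cs = ConstraintSet(linear=[LinearRule("C", "B")])
        ok, violated = satisfies({"C": 0.5, "B": 0.5}, cs)
        assert not ok
        assert violated == ["linear:C>B"]

    def test_size_cap_is_strict(self):
        cs = ConstraintSet(max_support=60)
        vec = {f"R{i}": 1.0 for i in range(60)}
        ok, violated = satisfies(vec, cs)
        assert not ok and violated == ["size"]
        vec.popitem()
        ok, _ = satisfies(vec, cs)
        assert ok

    def test_forbidden_direction_allows_zero(self):
        cs = ConstraintSet(forbidden_direction={("E", -1)})
        assert satisfies({"E": 0.0}, cs)[0]
        assert satisfies({"E": 0.5}, cs)[0]
        assert not satisfies({"E": -0.5}, cs)[0]

    def test_conflicting_directions_rejected(self):
        with pytest.raises(ValueError, match="required and forbidden"):
            ConstraintSet(hard_active={("R", 1)}, forbidden_direction={("R", 1)})


class TestSampler:
    def test_matches_oracle_filter_on_diamond(self, diamond):
        cs = ConstraintSet(hard_active={("IN", 1)}, forbidden_direction={("TOP", 1)})
        oracle = [
            m for m in brute_force_efms(diamond) if satisfies(m, cs)[0]
        ]
        got = sample_constrained_efms(diamond, cs, n=10, seed=0)
        assert {m.signature() for m in got} == {m.signature() for m in oracle}

    @pytest.mark.parametrize("seed", range(4))
    def test_completeness_on_random_toys(self, seed):
        """With no cap and ample time the sampler recovers exactly the
        constraint-satisfying subset of the brute-force EFM set."""
        net = generate_toy_network("random", size=12, seed=seed)
        cs = ConstraintSet(hard_active={("IN", 1)}, max_support=8)
        oracle = {
            m.signature() for m in brute_force_efms(net) if satisfies(m, cs)[0]
        }
        got = sample_constrained_efms(net, cs, n=100, seed=seed)
        assert {m.signature() for m in got} == oracle

    def test_deterministic_given_seed(self, diamond):
        cs = ConstraintSet(hard_active={("IN", 1)})
        a = sample_constrained_efms(diamond, cs, n=10, seed=5)
        b = sample_constrained_efms(diamond, cs, n=10, seed=5)
        assert [m.signature() for m in a] == [m.signature() for m in b]

    def test_unsatisfiable_demand_gives_empty(self, diamond):
        # demand flux through both parallel branches: no EFM does that
        cs = ConstraintSet(hard_active={("TOP", 1), ("BOT", 1)})
        got = sample_constrained_efms(diamond, cs, n=5, seed=0)
        assert got == []

    def test_impossible_secretion_gives_empty(self):
        net = generate_toy_network("chain")
        cs = ConstraintSet(hard_active={("IN", -1)})  # reverse an irreversible
        got = sample_constrained_efms(net, cs, n=5, seed=0)
        assert got == []
        assert "infeasible" in got.status

    def test_soundness_on_the_full_model(
        self, stroma_net, constraint_set, sampled_modes
    ):
        """Every sampled mode is a steady-state, rank-test-elementary flux
        satisfying the full constraint set."""
        for m in sampled_modes:
            assert is_steady_state(m.vector, stroma_net, tol=1e-6)
            assert is_elementary(m.vector, stroma_net)
            ok, violated = satisfies(m, constraint_set, eps=1e-6)
            assert ok, violated

    def test_full_model_modes_show_warburg_and_stroma(
        self, stroma_net, sampled_modes, aliases
    ):
        from stromaefm import exchange_flux

        for m in sampled_modes:
            assert exchange_flux(m.vector, "glucose", stroma_net, aliases) < 0
            assert exchange_flux(m.vector, "lactate", stroma_net, aliases) > 0
            assert exchange_flux(m.vector, "glutamine", stroma_net, aliases) < 0
            assert exchange_flux(m.vector, "collagen", stroma_net, aliases) > 0
            assert exchange_flux(m.vector, "stroma", stroma_net, aliases) > 0

    def test_distinct_supports(self, sampled_modes):
        sigs = [m.signature() for m in sampled_modes]
        assert len(sigs) == len(set(sigs))


def test_constraint_set_json_round_trip(tmp_path, constraint_set):
    path = tmp_path / "cs.json"
    constraint_set.to_json(str(path))
    back = ConstraintSet.from_json(str(path))
    assert back.hard_active == constraint_set.hard_active
    assert back.forbidden_direction == constraint_set.forbidden_direction
    assert back.linear == constraint_set.linear
    assert back.max_support == constraint_set.max_support
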