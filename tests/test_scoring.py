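"""Regression scoring, ranking, per-line analysis, exchange statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stromaefm import (
    FluxMode,
    per_line_first_places,
    rank_modes,
    regress_mode,
    summarize_exchanges,
    table1_constants,
)
from stromaefm.scoring import UndefinedScoreError, max_r2_over_samples


class TestTable1Constants:
    def test_fifteen_numeric_means(self, table):
        assert len(table.numeric_metabolites()) == 15

    def test_hard_constraint_values(self, table):
        assert table.entries["glucose"].mean == -326.87
        assert table.entries["glucose"].sd == 196.12
        assert table.entries["lactate"].mean == 442.20
        assert table.entries["glutamine"].mean == -82.48
        assert {m for m, e in table.entries.items() if e.kind == "hard"} == {
            "glucose", "lactate", "glutamine"
        }

    def test_missing_and_uncalibrated_entries(self, table):
        assert table.entries["histidine"].status == "missing"
        assert table.entries["histidine"].mean is None
        assert table.entries["formate"].status == "missing"
        assert table.entries["pyruvate"].status == "uncalibrated"

    def test_signs_follow_the_measured_directions(self, table):
        assert table.entries["glycine"].sign == "+/-"
        assert table.entries["serine"].sign == "-"
        assert table.entries["alanine"].sign == "+"


def _mode_with_exchanges(values):
    """FluxMode carrying given *signed* exchange values on the stand-in model.

    The model writes uptake exchanges forward (boundary -> cytosol), so a
    negative (uptake) exchange value means positive forward flux there.
    """
    uptake_forward = {
        "EX_GLUC", "EX_GLN", "EX_SER", "EX_GLY", "EX_ASP", "EX_ARG",
        "EX_TIV", "EX_YFLKW", "EX_XTP", "EX_FOR", "EX_HIS", "EX_CYS",
        "EX_MET", "EX_PRO",
    }
    vec = {}
    for rid, signed in values.items():
        vec[rid] = -signed if rid in uptake_forward else signed
    return FluxMode(vec)


class TestRegression:
    def test_perfect_linear_fit(self, stroma_net, table, aliases):
        # exchange values exactly proportional to the measured means
        vec = {
            aliases[m]: table.entries[m].mean / 500.0
            for m in table.numeric_metabolites()
        }
        mode = _mode_with_exchanges(vec)
        sc = regress_mode(mode, table, stroma_net, aliases=aliases)
        assert sc.r2 == pytest.approx(1.0, abs=1e-9)
        assert sc.rmse == pytest.approx(0.0, abs=1e-6)
        assert sc.slope == pytest.approx(500.0)
        assert sc.n_points == 15

    @given(st.floats(min_value=0.01, max_value=1e4))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, c):
        net = _SCORING_NET
        table = _SCORING_TABLE
        mode = _SCORING_MODE
        scaled = FluxMode({r: c * v for r, v in mode.vector.items()})
        a = regress_mode(mode, table, net, aliases=_SCORING_ALIASES)
        b = regress_mode(scaled, table, net, aliases=_SCORING_ALIASES)
        assert b.r2 == pytest.approx(a.r2, rel=1e-9)
        assert b.rmse == pytest.approx(a.rmse, rel=1e-6, abs=1e-9)

    def test_zero_exchanges_are_dropped(self, stroma_net, table, aliases):
        vec = {aliases["glucose"]: -10.0, aliases["lactate"]: 12.0,
               aliases["glutamine"]: -3.0}
        mode = _mode_with_exchanges(vec)
        sc = regress_mode(mode, table, stroma_net, aliases=aliases)
        assert sc.n_points == 3

    def test_undefined_below_two_points(self, stroma_net, table, aliases):
        mode = _mode_with_exchanges({aliases["glucose"]: -10.0})
        with pytest.raises(UndefinedScoreError):
            regress_mode(mode, table, stroma_net, aliases=aliases)

    def test_metabolites_without_means_never_enter(self, stroma_net, table, aliases):
        vec = {aliases["glucose"]: -10.0, aliases["lactate"]: 12.0,
               aliases["formate"]: 5.0, aliases["histidine"]: -2.0,
               aliases["pyruvate"]: 1.0}
        mode = _mode_with_exchanges(vec)
        sc = regress_mode(mode, table, stroma_net, aliases=aliases)
        assert sc.n_points == 2


class TestRanking:
    def test_order_is_a_monotone_permutation(
        self, sampled_modes, table, stroma_net, aliases
    ):
        ranked = rank_modes(sampled_modes, table, stroma_net, aliases=aliases)
        assert sorted(i for i, _ in ranked) == list(range(len(sampled_modes)))
        r2s = [sc.r2 for _, sc in ranked]
        assert r2s == sorted(r2s, reverse=True)

    def test_single_mode_ranks_first(self, sampled_modes, table, stroma_net, aliases):
        ranked = rank_modes(sampled_modes[:1], table, stroma_net, aliases=aliases)
        assert ranked[0][0] == 0


class TestPerLine:
    def test_single_mode_takes_every_line(
        self, sampled_modes, table, stroma_net, aliases
    ):
        import pandas as pd

        rng = np.random.default_rng(3)
        mets = table.numeric_metabolites()
        data = {
            m: rng.normal(table.entries[m].mean, table.entries[m].sd, size=5)
            for m in mets
        }
        per_line = pd.DataFrame(data)
        firsts, mean_r2 = per_line_first_places(
            sampled_modes[:1], per_line, table, stroma_net, aliases=aliases
        )
        assert firsts == {0: 5}
        assert 0 in mean_r2


class TestSummaries:
    def test_single_mode_has_zero_sd(self, sampled_modes, stroma_net, aliases):
        stats = summarize_exchanges(
            sampled_modes[:1], stroma_net, ["glucose", "lactate"], aliases=aliases
        )
        assert (stats["sd"] == 0.0).all()
        assert (stats["min"] == stats["max"]).all()

    def test_statistics_over_modes(self, sampled_modes, stroma_net, aliases):
        stats = summarize_exchanges(
            sampled_modes, stroma_net,
            ["glucose", "lactate", "glutamine", "glycine"], aliases=aliases,
        )
        assert (stats.loc["glucose", "max"] < 0)  # always consumed
        assert (stats.loc["lactate", "min"] > 0)  # always produced
        assert stats.loc["glycine", "sd"] >= 0

    def test_empty_mode_list_rejected(self, stroma_net, aliases):
        with pytest.raises(ValueError):
            summarize_exchanges([], stroma_net, ["glucose"], aliases=aliases)


def test_bulk_scorer_agrees_with_regress_mode(stroma_net, table, aliases):
    """The closed-form row scorer matches the sklearn-backed reference."""
    rng = np.random.default_rng(7)
    mets = table.numeric_metabolites()
    y = np.array([table.entries[m].mean for m in mets])
    rows = rng.normal(size=(6, len(mets)))
    rows[rng.random(rows.shape) < 0.2] = 0.0
    best_ref = -np.inf
    for row in rows:
        vec = {aliases[m]: x for m, x in zip(mets, row) if x != 0.0}
        if len(vec) < 2:
            continue
        mode = _mode_with_exchanges(vec)
        best_ref = max(
            best_ref, regress_mode(mode, table, stroma_net, aliases=aliases).r2
        )
    assert max_r2_over_samples(rows, y) == pytest.approx(best_ref, rel=1e-9)


# module-level cache for the hypothesis test (fixtures cannot be @given args)
from stromaefm import synthetic_stroma_network  # noqa: E402
from stromaefm.synthetic_data import DEFAULT_EXCHANGE_ALIASES as _SCORING_ALIASES  # noqa: E402

_SCORING_NET = synthetic_stroma_network()
_SCORING_TABLE = table1_constants()
_SCORING_MODE = _mode_with_exchanges(
    {
        _SCORING_ALIASES["glucose"]: -300.0,
        _SCORING_ALIASES["lactate"]: 400.0,
        _SCORING_ALIASES["glutamine"]: -80.0,
        _SCORING_ALIASES["serine"]: -9.0,
        _SCORING_ALIASES["alanine"]: 12.0,
    }
)
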