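"""Network representation, SBML round trips, stroma extension stoichiometry."""

import math

import pytest

from stromaefm import (
    ConstraintSet,
    MetabolicNetwork,
    Metabolite,
    NetworkValidationError,
    Reaction,
    build_stroma_extension,
    exchange_flux,
    is_essential,
    protein_synthesis_reaction,
    read_sbml,
    write_sbml,
)
from stromaefm.sbml_io import SBMLParseError
from stromaefm.stroma import PRINTED_PROTEIN_REACTIONS, PROTEIN_COMPOSITIONS


def _truncate(x: float, places: int) -> float:
    return math.floor(x * 10**places) / 10**places


class TestProteinSynthesis:
    @pytest.mark.parametrize("name,length", [("IL1B", 269), ("TNFA", 233), ("VEGFA", 232)])
    def test_matches_published_coefficients(self, name, length):
        """Residue proportions reproduce the published reaction coefficients.

        Reactants agree after rounding to 3 decimals; the product
        coefficient is the inverse protein length (published truncated to
        5 decimals)."""
        rxn = protein_synthesis_reaction(name, PROTEIN_COMPOSITIONS[name], length)
        printed = PRINTED_PROTEIN_REACTIONS[name]
        assert _truncate(rxn.stoichiometry[name], 5) == printed[name]
        for pool, coef in printed.items():
            if pool == name:
                continue
            assert round(rxn.stoichiometry[pool], 3) == pytest.approx(coef)

    @pytest.mark.parametrize("name,length", [("IL1B", 269), ("TNFA", 233), ("VEGFA", 232)])
    def test_exact_invariants(self, name, length):
        rxn = protein_synthesis_reaction(name, PROTEIN_COMPOSITIONS[name], length)
        reactant_sum = -sum(c for m, c in rxn.stoichiometry.items() if m != name)
        assert reactant_sum == pytest.approx(1.0, abs=1e-9)
        assert rxn.stoichiometry[name] * length == pytest.approx(1.0, abs=1e-9)
        assert not rxn.reversible

    def test_single_residue_identity(self):
        rxn = protein_synthesis_reaction("P", {"GLYc": 1}, 1)
        assert rxn.stoichiometry == {"GLYc": -1.0, "P": 1.0}

    def test_count_mismatch_rejected(self):
        with pytest.raises(NetworkValidationError, match="sum"):
            protein_synthesis_reaction("P", {"GLYc": 2}, 3)


class TestStromaExtension:
    def test_printed_collagen_stoichiometry(self, stroma_net):
        cbs = stroma_net.reaction("CBS").stoichiometry
        assert cbs == {
            "GLYc": -0.33, "XYAA": -0.50, "PROc": -0.085,
            "HYPc": -0.085, "CBrick": 1.0,
        }
        collag = stroma_net.reaction("COLLAG").stoichiometry
        assert collag == {"CBrick": -100.0, "Collagen": 1.0}

    def test_xyaas_yields_14_from_8_pools(self, stroma_net):
        xyaas = stroma_net.reaction("XYAAS").stoichiometry
        assert xyaas["XYAA"] == 14.0
        pools = {m for m, c in xyaas.items() if c == -1.0}
        assert pools == {"ALAc", "ARGc", "SERc", "TIV", "YFLKW", "GLNc",
                         "ASPc", "GLUTc"}

    def test_stroma_needs_growth_factor_and_inflammation(self, stroma_net):
        """Inflammation alone cannot drive stroma output: the growth-factor
        branch (VEGFA -> FACT) is essential for EX_STROMA flux."""
        cs = ConstraintSet(hard_active={("EX_STROMA", 1)})
        assert is_essential(stroma_net, cs, "VEGFA")
        assert is_essential(stroma_net, cs, "FACT")
        # either inflammation marker suffices, so neither alone is essential
        assert not is_essential(stroma_net, cs, "IL1B")
        assert not is_essential(stroma_net, cs, "TNFA")

    def test_missing_base_metabolite_reported(self):
        base = MetabolicNetwork(
            metabolites=[Metabolite("GLYc", "GLYc", "cytosol")],
            reactions=[Reaction("DUMMY", {"GLYc": 1.0})],
        )
        with pytest.raises(NetworkValidationError, match="PROc"):
            build_stroma_extension(base)

    def test_extension_is_pure(self, core_net):
        before = len(core_net.reactions)
        build_stroma_extension(core_net)
        assert len(core_net.reactions) == before


class TestSBMLRoundTrip:
    def test_toy_round_trip(self, tmp_path, diamond):
        path = tmp_path / "diamond.xml"
        write_sbml(diamond, str(path))
        back = read_sbml(str(path))
        assert back.reaction_ids == diamond.reaction_ids
        for r in diamond.reactions:
            b = back.reaction(r.id)
            assert b.stoichiometry == r.stoichiometry
            assert b.reversible == r.reversible
            assert b.lower_bound == r.lower_bound
            assert b.upper_bound == r.upper_bound

    def test_full_model_round_trip(self, tmp_path, stroma_net):
        path = tmp_path / "model.xml"
        write_sbml(stroma_net, str(path))
        back = read_sbml(str(path))
        assert len(back.reactions) == len(stroma_net.reactions)
        assert len(back.exchange_reactions) == len(stroma_net.exchange_reactions)
        assert [m.id for m in back.internal_metabolites] == [
            m.id for m in stroma_net.internal_metabolites
        ]
        for r in stroma_net.reactions:
            assert back.reaction(r.id).stoichiometry == pytest.approx(
                r.stoichiometry
            )
            assert back.reaction(r.id).reversible == r.reversible

    def test_one_reaction_file(self, tmp_path):
        net = MetabolicNetwork(
            metabolites=[
                Metabolite("Ax", "Ax", "external", is_boundary=True),
                Metabolite("A", "A", "cytosol"),
            ],
            reactions=[Reaction("EX_A", {"Ax": -1.0, "A": 1.0})],
        )
        path = tmp_path / "one.xml"
        write_sbml(net, str(path))
        back = read_sbml(str(path))
        assert len(back.reactions) == 1
        assert len(back.exchange_reactions) == 1

    def test_malformed_file_raises(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<sbml><model><species broken")
        with pytest.raises(SBMLParseError):
            read_sbml(str(bad))


class TestExchangeFlux:
    def test_uptake_written_as_import_is_negative(self, stroma_net, aliases):
        # EX_GLUC is written GLUCx -> GLUCc; forward flux 2 is uptake
        v = {"EX_GLUC": 2.0}
        assert exchange_flux(v, "glucose", stroma_net, aliases) == -2.0

    def test_secretion_written_as_export_is_positive(self, stroma_net, aliases):
        v = {"EX_LAC": 3.0}
        assert exchange_flux(v, "lactate", stroma_net, aliases) == 3.0

    def test_sign_independent_of_writing_convention(self):
        mets = [
            Metabolite("Ax", "Ax", "external", is_boundary=True),
            Metabolite("A", "A", "cytosol"),
            Metabolite("SINK", "SINK", "cytosol"),
        ]
        consume = Reaction("USE", {"A": -1.0, "SINK": 1.0})
        as_import = MetabolicNetwork(
            metabolites=mets,
            reactions=[Reaction("EX_A", {"Ax": -1.0, "A": 1.0}), consume],
        )
        as_export = MetabolicNetwork(
            metabolites=mets,
            reactions=[
                Reaction("EX_A", {"A": -1.0, "Ax": 1.0}, reversible=True),
                consume,
            ],
        )
        assert exchange_flux({"EX_A": 2.0}, "A", as_import) == -2.0
        assert exchange_flux({"EX_A": -2.0}, "A", as_export) == -2.0

    def test_missing_exchange_raises(self, stroma_net):
        with pytest.raises(KeyError):
            exchange_flux({}, "nosuchmetabolite", stroma_net)


def test_network_validation_rejects_duplicates():
    with pytest.raises(NetworkValidationError, match="duplicate"):
        MetabolicNetwork(
            metabolites=[Metabolite("A", "A", "cytosol"),
                         Metabolite("A", "A", "cytosol")],
            reactions=[],
        )


def test_irreversible_negative_bound_rejected():
    with pytest.raises(NetworkValidationError):
        Reaction("R", {"A": 1.0}, reversible=False, lower_bound=-5.0)


def test_stoichiometric_matrix_csv(tmp_path, stroma_net):
    import pandas as pd

    from stromaefm.model import write_stoichiometric_matrix

    path = tmp_path / "N.csv"
    write_stoichiometric_matrix(stroma_net, str(path))
    df = pd.read_csv(path, index_col=0)
    assert list(df.columns) == stroma_net.reaction_ids
    assert list(df.index) == stroma_net.internal_metabolite_ids
    assert df.loc["CBrick", "COLLAG"] == -100.0
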