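"""Greedy matching and reaction-level score aggregation."""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from parity.molecule import parse_smiles
from parity.reaction import (
    BoundLigandSet,
    Reaction,
    bin_score,
    combined_side_score,
    filter_cognates,
    greedy_match,
    score_reaction,
)


def mols(*specs):
    return tuple(parse_smiles(s, cid) for cid, s in specs)


class TestFilterCognates:
    def test_water_removed(self, corpus):
        side = [corpus.compound_table["C00001"], corpus.compound_table["C00026"]]
        assert [m.id for m in filter_cognates(side)] == ["C00026"]

    def test_empty_side(self):
        assert filter_cognates([]) == []

    def test_only_excluded_species(self, corpus):
        # proton/dihydrogen have no structures; emulate by id-labelled waters
        side = [
            corpus.compound_table["C00001"].with_id("C00080"),
            corpus.compound_table["C00001"].with_id("C00282"),
        ]
        assert filter_cognates(side) == []

    def test_exclusion_set_configurable(self, corpus):
        side = [corpus.compound_table["C00026"]]
        assert filter_cognates(side, excluded={"C00026"}) == []


class TestGreedyMatch:
    def test_identical_pair_scores_one(self):
        (a,) = mols(("A", "CCO"))
        pairs = greedy_match(BoundLigandSet("S", (a.with_id("A2"),)), [a])
        assert len(pairs) == 1
        assert pairs[0].result.score == 1.0

    def test_best_bound_wins_surplus_discarded(self, corpus):
        t = corpus.compound_table
        pairs = greedy_match(
            BoundLigandSet("S", (t["OGA"], t["EDO"])), [t["C00026"]]
        )
        assert len(pairs) == 1
        assert pairs[0].bound_id == "OGA"
        assert pairs[0].result.rounded == 0.82

    def test_empty_bound_set_gives_none_pairs(self, corpus):
        t = corpus.compound_table
        pairs = greedy_match(BoundLigandSet("S", ()), [t["C00026"], t["C00042"]])
        assert all(p.is_unmatched for p in pairs)
        assert combined_side_score(pairs) == 0.0
        # unmatched slot: I=0, U=N_C
        assert [p.result.union for p in pairs] == [10, 8]

    def test_zero_score_pairs_not_matched(self):
        b, c = mols(("B", "O"), ("C", "C"))
        pairs = greedy_match(BoundLigandSet("S", (b,)), [c])
        assert pairs[0].is_unmatched

    def test_conservation_of_cognates(self, corpus):
        t = corpus.compound_table
        cognates = [t["C07088"], t["C00026"], t["C00007"]]
        pairs = greedy_match(BoundLigandSet("S", (t["OGA"], t["EDO"])), cognates)
        assert sorted(p.cognate_id for p in pairs) == sorted(m.id for m in cognates)


class TestCombinedScore:
    def test_exact_match_is_one(self):
        (a,) = mols(("A", "OC(=O)CCC(=O)C(O)=O"))
        pairs = greedy_match(BoundLigandSet("S", (a.with_id("A2"),)), [a])
        assert combined_side_score(pairs) == 1.0

    def test_sum_intersection_over_sum_union(self):
        ethane, propane = mols(("ETH", "CC"), ("PRO", "CCC"))
        pairs = greedy_match(BoundLigandSet("S", (ethane.with_id("B1"),)),
                             [ethane, propane])
        # matched ethane: I=2,U=2; unmatched propane: I=0,U=3
        assert combined_side_score(pairs) == pytest.approx(0.4)

    def test_empty_pairs_is_zero(self):
        assert combined_side_score([]) == 0.0

    def test_single_pair_equals_pairwise_parity(self, corpus):
        t = corpus.compound_table
        res = score_reaction(
            BoundLigandSet("S", (t["OGA"],)),
            Reaction("RX", (t["C00026"],), ()),
        )
        assert Fraction(9, 11) == Fraction(res.pairs[0].result.n_sim,
                                           res.pairs[0].result.union)
        assert res.combined_score == pytest.approx(9 / 11)

    def test_one_exact_of_m_cognates_penalty(self, corpus):
        # with M cognates and a single exact match, S = N_C1 / sum N_Cm
        t = corpus.compound_table
        res = score_reaction(
            BoundLigandSet("S", (t["ACT"],)),
            Reaction("RX", (t["C00033"], t["C00033"].with_id("C00033b")), ()),
        )
        assert res.combined_score == pytest.approx(4 / (4 + 4))


class TestScoreReaction:
    def test_reactant_side_exact_match(self, corpus):
        t = corpus.compound_table
        rxn = Reaction("R", (t["C00033"],), (t["C00114"],))
        res = score_reaction(BoundLigandSet("S", (t["ACT"],)), rxn)
        assert res.side == "r"
        assert res.combined_score == 1.0

    def test_product_side_exact_match(self, corpus):
        t = corpus.compound_table
        rxn = Reaction("R", (t["C00114"],), (t["C00033"],))
        res = score_reaction(BoundLigandSet("S", (t["ACT"],)), rxn)
        assert res.side == "p"
        assert res.combined_score == 1.0

    def test_side_tie_reports_reactants(self, corpus):
        t = corpus.compound_table
        rxn = Reaction("R", (t["C00033"],), (t["C00033"].with_id("C00033p"),))
        res = score_reaction(BoundLigandSet("S", (t["ACT"],)), rxn)
        assert res.side == "r"

    def test_empty_bound_set_flagged(self, corpus):
        t = corpus.compound_table
        rxn = Reaction("R", (t["C00026"],), (t["C00042"],))
        res = score_reaction(BoundLigandSet("S", ()), rxn)
        assert res.none_bound
        assert res.combined_score == 0.0

    def test_both_sides_empty_after_filtering(self, corpus):
        t = corpus.compound_table
        water = t["C00001"]
        rxn = Reaction("R", (water,), (water.with_id("C00001b"),))
        res = score_reaction(
            BoundLigandSet("S", (t["ACT"],)), rxn, excluded=frozenset({"C00001", "C00001b"})
        )
        assert res.both_sides_empty
        assert res.combined_score == 0.0

    def test_adding_bound_ligand_never_hurts_fixture_cases(self, corpus):
        t = corpus.compound_table
        rxn = Reaction("R", (t["C00026"], t["C00007"]), ())
        base = score_reaction(BoundLigandSet("S", (t["EDO"],)), rxn)
        more = score_reaction(BoundLigandSet("S", (t["EDO"], t["OGA"])), rxn)
        assert more.combined_score >= base.combined_score

    def test_markush_reaction_scored_via_substitution(self, corpus):
        t = corpus.compound_table
        rxn = Reaction("R", (t["CM0001"],), (t["CM0002"],))
        res = score_reaction(BoundLigandSet("S", (t["TOL"],)), rxn)
        assert res.side == "p"
        assert res.combined_score == pytest.approx(7 / 8)


class TestBinScore:
    @pytest.mark.parametrize(
        "s, expected", [(0.82, 0.80), (0.0, 0.0), (0.875, 0.90), (1.0, 1.0), (0.47, 0.45)]
    )
    def test_examples(self, s, expected):
        assert bin_score(s) == pytest.approx(expected)

    @pytest.mark.parametrize("s", [-0.01, 1.01, float("nan")])
    def test_out_of_range_rejected(self, s):
        with pytest.raises(ValueError):
            bin_score(s)

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_nearest_multiple_of_005(self, s):
        b = bin_score(s)
        assert abs(b * 20 - round(b * 20)) < 1e-9
        assert abs(b - s) <= 0.025 + 1e-9
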