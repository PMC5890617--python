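"""PARITY scoring, permissive/strict MCS, Markush substitution."""

from fractions import Fraction

import pytest

from parity.fixtures import brute_force_parity
from parity.molecule import parse_smiles, write_smiles
from parity.score import (
    parity_score,
    permissive_mcs,
    strict_mcs_score,
    substitute_r_group,
)


def chain(k: int, swap_middle: bool = False) -> str:
    """Linear carbon chain of k atoms, optionally with O in the middle."""
    atoms = ["C"] * k
    if swap_middle:
        atoms[k // 2] = "O"
    return "".join(atoms)


class TestWorkedPair:
    """2-oxoglutarate vs N-oxalylglycine: one central N/C difference."""

    @pytest.fixture(scope="class")
    def pair(self):
        return (
            parse_smiles("OC(=O)CCC(=O)C(O)=O", "C00026"),
            parse_smiles("OC(=O)CNC(=O)C(O)=O", "OGA"),
        )

    def test_permissive_mapping_covers_both_skeletons(self, pair):
        maps = permissive_mcs(*pair)
        assert maps and len(maps[0]) == 10

    def test_parity_is_nine_elevenths(self, pair):
        res = parity_score(*pair)
        assert (res.n_b, res.n_c, res.n_sim) == (10, 10, 9)
        assert Fraction(res.n_sim, res.union) == Fraction(9, 11)
        assert res.rounded == 0.82

    def test_strict_collapses_to_one_third(self, pair):
        res = strict_mcs_score(*pair)
        assert res.n_sim == 5
        assert Fraction(res.n_sim, res.union) == Fraction(5, 15)
        assert res.rounded == 0.33

    def test_symmetry(self, pair):
        b, c = pair
        assert parity_score(b, c).score == parity_score(c, b).score


@pytest.mark.parametrize("smiles", ["CC", "CCO", "c1ccccc1", "OC(=O)CCC(=O)C(O)=O"])
def test_self_similarity_is_one(smiles):
    m = parse_smiles(smiles, "M")
    res = parity_score(m, m)
    assert res.score == 1.0
    assert res.n_sim == m.n_atoms


def test_disjoint_elements_score_zero():
    res = parity_score(parse_smiles("C", "CH4"), parse_smiles("O", "HOH"))
    assert res.score == 0.0
    assert res.n_sim == 0


def test_ethanol_vs_ethane():
    res = parity_score(parse_smiles("CCO", "ETOH"), parse_smiles("CC", "ETHA"))
    assert (res.n_sim, res.n_b, res.n_c) == (2, 3, 2)
    assert res.score == pytest.approx(2 / 3)


def test_ring_vs_smaller_ring_permissive_size():
    benzene = parse_smiles("c1ccccc1", "BNZ")
    cyclopentane = parse_smiles("C1CCCC1", "CPN")
    maps = permissive_mcs(benzene, cyclopentane)
    assert len(maps[0]) == 5  # a 5-path embeds in both rings


def test_ethane_identity_mapping_exists():
    ethane = parse_smiles("CC", "ETHA")
    maps = permissive_mcs(ethane, ethane)
    assert any(len(m) == 2 for m in maps)


def test_empty_or_markush_arguments_rejected(corpus):
    markush = corpus.compound_table["CM0001"]
    concrete = corpus.compound_table["C00033"]
    with pytest.raises(ValueError, match="R-group"):
        parity_score(markush, concrete)
    with pytest.raises(ValueError, match="R-group"):
        permissive_mcs(markush, concrete)


def test_mapping_is_injective_and_within_bounds(random_pairs):
    for b, c in random_pairs[:40]:
        res = parity_score(b, c)
        bs = [i for i, _ in res.mapping.pairs]
        cs = [j for _, j in res.mapping.pairs]
        assert len(set(bs)) == len(bs) and len(set(cs)) == len(cs)
        assert all(0 <= i < b.n_atoms for i in bs)
        assert all(0 <= j < c.n_atoms for j in cs)


def test_truncation_flag_on_tiny_budget():
    b = parse_smiles("OC(=O)CCC(=O)C(O)=O", "B")
    c = parse_smiles("OC(=O)CNC(=O)C(O)=O", "C")
    res = parity_score(b, c, node_budget=10)
    assert res.truncated
    assert 0.0 <= res.score <= 1.0


def test_disconnected_matching_flag():
    # with connectivity off, n_sim is the shared element multiset size
    b = parse_smiles("CO", "B")      # disconnected from c's perspective
    c = parse_smiles("OCCCCCO", "C")
    res = parity_score(b, c, connected=False)
    assert res.n_sim == 2


@pytest.mark.parametrize("k", range(4, 11))
def test_single_internal_change_degrades_gently(k):
    """An element swap in mid-chain gives (k-1)/(k+1), not the MCS crash."""
    a = parse_smiles(chain(k), "A")
    b = parse_smiles(chain(k, swap_middle=True), "B")
    res = parity_score(a, b)
    assert Fraction(res.n_sim, res.union) == Fraction(k - 1, k + 1)
    assert strict_mcs_score(a, b).score < res.score


def test_permissive_dominates_strict(corpus, random_pairs):
    curated = [corpus.compound_table[c] for c in ("C00026", "OGA", "EDO", "C00033", "TOL")]
    pairs = [(a, b) for i, a in enumerate(curated) for b in curated[i + 1:]]
    for b, c in pairs + random_pairs[:30]:
        assert parity_score(b, c).score >= strict_mcs_score(b, c).score


def test_matches_brute_force_oracle_on_sample(random_pairs):
    for b, c in random_pairs[:30]:
        imp = parity_score(b, c)
        orc = brute_force_parity(b, c)
        assert imp.n_sim == orc.n_sim, (b.id, c.id)


class TestMarkushSubstitution:
    def test_ring_r_group_grafts_methyl(self):
        cognate = parse_smiles("*c1ccc(O)cc1", "RPH")
        bound = parse_smiles("Cc1ccccc1", "TOL")
        sub = substitute_r_group(cognate, bound)
        assert sub.n_atoms == 8           # phenol (7) + grafted methyl
        assert not sub.is_markush
        assert write_smiles(sub) == write_smiles(parse_smiles("Cc1ccc(O)cc1", "CRE"))

    def test_lone_r_atom_yields_empty_molecule(self):
        cognate = parse_smiles("*", "RONLY")
        bound = parse_smiles("CC", "ETHA")
        assert substitute_r_group(cognate, bound).is_empty

    def test_no_common_scaffold_deletes_r(self):
        cognate = parse_smiles("*N", "RN")
        bound = parse_smiles("CC", "ETHA")
        sub = substitute_r_group(cognate, bound)
        assert sub.n_atoms == 1
        assert sub.elements == ("N",)

    def test_acetate_markush_becomes_benzoate_like(self, corpus):
        sub = substitute_r_group(
            corpus.compound_table["CM0001"], corpus.compound_table["TOL"]
        )
        assert sub.n_atoms == 9
        tol = corpus.compound_table["TOL"]
        assert parity_score(tol, sub).score == pytest.approx(7 / 9)

    def test_requires_markush_cognate(self, corpus):
        with pytest.raises(ValueError, match="no R-group"):
            substitute_r_group(
                corpus.compound_table["C00033"], corpus.compound_table["TOL"]
            )
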