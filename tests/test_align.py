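import io
import math

import pytest
from Bio import Phylo

from rapidsel.align import (
    build_guide_tree,
    column_conservation,
    consensus_string,
    extract_families,
    gapped_identity,
    logo_matrix,
    pairwise_align,
    progressive_align,
    write_aligned_fasta,
    write_clustal,
)
from tests.conftest import random_peptide

AAS = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_best_score(a, b, match=1.0, mismatch=-1.0, gap_open=1.0, gap_extend=1.0):
    """Enumerate all global alignments of two tiny strings; return the best
    score under the stated affine scoring (gap of length g costs
    open + (g-1)*extend)."""
    best = [-math.inf]

    def rec(i, j, score, state):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + (match if a[i] == b[j] else mismatch), "M")
        if i < len(a):
            rec(i + 1, j, score - (gap_extend if state == "X" else gap_open), "X")
        if j < len(b):
            rec(i, j + 1, score - (gap_extend if state == "Y" else gap_open), "Y")

    rec(0, 0, 0.0, "M")
    return best[0]


class TestPairwiseAlign:
    def test_identical_gapless(self):
        from rapidsel.align import _BLOSUM62

        seq = "FWTLYGPI"
        ga, gb, score = pairwise_align(seq, seq)
        assert ga == gb == seq
        assert score == pytest.approx(sum(_BLOSUM62[c, c] for c in seq))

    def test_toy_example_matches_enumeration(self):
        ga, gb, score = pairwise_align(
            "ACG", "AG", use_blosum=False, match=1, mismatch=-1, gap_open=1, gap_extend=1
        )
        assert score == pytest.approx(1.0)
        assert score == pytest.approx(brute_force_best_score("ACG", "AG"))
        assert gb.count("-") == 1
        assert ga == "ACG"

    def test_optimal_against_enumeration_random(self, rng):
        for _ in range(20):
            a = "".join(AAS[i] for i in rng.integers(0, 20, size=int(rng.integers(2, 6))))
            b = "".join(AAS[i] for i in rng.integers(0, 20, size=int(rng.integers(2, 6))))
            _, _, score = pairwise_align(
                a, b, use_blosum=False, match=1, mismatch=-1, gap_open=2, gap_extend=1
            )
            assert score == pytest.approx(
                brute_force_best_score(a, b, gap_open=2, gap_extend=1)
            )

    def test_score_symmetry(self, rng):
        for _ in range(10):
            a, b = random_peptide(rng, 10), random_peptide(rng, 12)
            assert pairwise_align(a, b)[2] == pytest.approx(pairwise_align(b, a)[2])

    def test_gap_removal(self, rng):
        a, b = random_peptide(rng, 10), random_peptide(rng, 14)
        ga, gb, _ = pairwise_align(a, b)
        assert ga.replace("-", "") == a
        assert gb.replace("-", "") == b
        assert len(ga) == len(gb)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pairwise_align("", "AAA")

    def test_lowercase_initiator_scored_as_tyrosine(self):
        _, _, s1 = pairwise_align("yFWTL", "YFWTL")
        _, _, s2 = pairwise_align("YFWTL", "YFWTL")
        assert s1 == pytest.approx(s2)


class TestGuideTree:
    def test_two_sequences_single_join(self):
        tree = build_guide_tree([("a", "FWTL"), ("b", "FWTI")])
        assert sorted(tree.leaves()) == ["a", "b"]
        assert not tree.is_leaf

    def test_closest_pair_joined_first(self):
        # d(A,B) < d(A,C) = d(B,C): UPGMA by hand joins A,B first
        seqs = [
            ("A", "YFWTLYGPIAKDEQRSC"),
            ("B", "YFWTLYGPIAKDEQRGC"),
            ("C", "YMNHVVKPGWDEITAKC"),
        ]
        tree = build_guide_tree(seqs)
        subtrees = [sorted(c.leaves()) for c in tree.children]
        assert ["A", "B"] in subtrees
        assert ["C"] in subtrees

    def test_upgma_heights_by_hand(self):
        # hand-computed 3x3 UPGMA: d(a,b)=0.2, d(a,c)=0.6, d(b,c)=0.8
        d = {("a", "b"): 0.2, ("a", "c"): 0.6, ("b", "c"): 0.8}
        tree = build_guide_tree([("a", ""), ("b", ""), ("c", "")], distances=d)
        assert tree.height == pytest.approx(0.35)  # (0.6+0.8)/2 / 2
        inner = [c for c in tree.children if not c.is_leaf][0]
        assert inner.height == pytest.approx(0.1)

    def test_ultrametric_distances_reproduced(self):
        # oracle: cophenetic distances of an ultrametric input equal it
        d = {
            ("a", "b"): 0.2, ("a", "c"): 0.6, ("b", "c"): 0.6,
            ("a", "e"): 0.9, ("b", "e"): 0.9, ("c", "e"): 0.9,
        }
        tree = build_guide_tree([("a", ""), ("b", ""), ("c", ""), ("e", "")], distances=d)
        coph = tree.cophenetic()
        for pair, expected in d.items():
            assert coph[pair] == pytest.approx(expected)

    def test_newick_parses(self):
        seqs = [("s1", "FWTLY"), ("s2", "FWTIY"), ("s3", "MNHVV")]
        tree = build_guide_tree(seqs)
        parsed = Phylo.read(io.StringIO(tree.newick()), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == ["s1", "s2", "s3"]

    def test_deterministic_under_ties(self):
        seqs = [("a", "AAAA"), ("b", "CCCC"), ("c", "DDDD")]  # all distances 1.0
        t1 = build_guide_tree(seqs)
        t2 = build_guide_tree(list(reversed(seqs)))
        assert t1.newick() == t2.newick()


class TestProgressiveAlign:
    def test_identical_sequences(self):
        seqs = [(f"s{i}", "YFWTLYGPIC") for i in range(4)]
        profile = progressive_align(seqs)
        assert all(row == "YFWTLYGPIC" for _, row in profile.aligned)
        assert all(c == pytest.approx(1.0) for c in profile.conservation)
        assert profile.consensus == "YFWTLYGPIC"

    def test_single_insertion_gives_one_gap_column(self):
        seqs = [
            ("a", "YFWTLYGPIC"),
            ("b", "YFWTLYGPIC"),
            ("c", "YFWTLLYGPIC"),  # one extra residue
        ]
        profile = progressive_align(seqs)
        assert profile.row("a").count("-") == 1
        assert profile.row("b").count("-") == 1
        assert profile.row("c").count("-") == 0
        assert profile.width == 11

    def test_gap_removal_invariant(self, rng):
        seqs = [(f"s{i}", random_peptide(rng, int(rng.integers(12, 18)))) for i in range(6)]
        profile = progressive_align(seqs)
        widths = {len(row) for _, row in profile.aligned}
        assert len(widths) == 1
        for seq_id, row in profile.aligned:
            assert row.replace("-", "") == dict(seqs)[seq_id]
        assert len(profile.conservation) == profile.width

    def test_pair_reduces_to_pairwise(self, rng):
        a, b = random_peptide(rng, 12), random_peptide(rng, 15)
        ga, gb, _ = pairwise_align(a, b)
        profile = progressive_align([("a", a), ("b", b)])
        assert profile.row("a") == ga
        assert profile.row("b") == gb

    def test_consensus_motif_fixture(self, rng):
        # sequences embedding one shared motif between random flanks
        motif = "FWTLYGPI"
        seqs = []
        for i in range(20):
            left = random_peptide(rng, int(rng.integers(2, 6)))[: 4]
            right = random_peptide(rng, 15 - len(motif) - len(left))
            seqs.append((f"s{i:02d}", "Y" + left + motif + right + "C"))
        profile = progressive_align(seqs)
        assert motif in profile.consensus

    def test_rows_in_input_order(self):
        seqs = [("z", "FWTLY"), ("a", "FWTIY"), ("m", "FWKIY")]
        profile = progressive_align(seqs)
        assert profile.ids == ["z", "a", "m"]


class TestColumnConservation:
    def test_uniform_column_scores_one(self):
        assert column_conservation(["W", "W", "W"]) == [pytest.approx(1.0)]

    def test_uniform_over_20_scores_zero(self):
        rows = [aa for aa in AAS]
        assert column_conservation(rows)[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_residue_split(self):
        rows = ["A", "A", "G", "G"]
        expected = 1 - math.log(2) / math.log(20)
        assert column_conservation(rows)[0] == pytest.approx(expected, abs=1e-6)

    def test_gap_majority_scores_zero(self):
        rows = ["A", "-", "-", "-"]
        assert column_conservation(rows)[0] == 0.0

    def test_half_gaps_still_scored(self):
        rows = ["A", "A", "-", "-"]  # gap fraction exactly 0.5: not a majority
        assert column_conservation(rows)[0] == pytest.approx(1.0)

    def test_bounds(self, rng):
        seqs = [(f"s{i}", random_peptide(rng, int(rng.integers(10, 16)))) for i in range(5)]
        profile = progressive_align(seqs)
        assert all(0.0 <= c <= 1.0 for c in profile.conservation)

    def test_empty_profile_errors(self):
        with pytest.raises(ValueError):
            column_conservation([])


class TestConsensus:
    def test_majority_residue(self):
        assert consensus_string(["AB", "AB", "CB"]) == "AB"

    def test_gap_majority_gives_gap(self):
        assert consensus_string(["A-", "--", "-C"]) == "--"

    def test_tie_breaks_lexicographically(self):
        assert consensus_string(["A", "G"]) == "A"


class TestExtractFamilies:
    def test_all_identical_one_family(self):
        profile = progressive_align([(f"s{i}", "YFWTLYGPIC") for i in range(3)])
        fams = extract_families(profile, 0.6)
        assert len(fams.families) == 1
        assert fams.consensus[1] == "YFWTLYGPIC"

    def test_two_planted_families(self, rng):
        fam1 = "YFWTLYGPIAKDEQRSC"
        fam2 = "YMNHVVKPGWDEITAKC"

        def variant(seed):
            out = list(seed)
            pos = 1 + int(rng.integers(0, 15))
            out[pos] = AAS[int(rng.integers(0, 20))]
            return "".join(out)

        seqs = [(f"a{i}", variant(fam1)) for i in range(5)] + [
            (f"b{i}", variant(fam2)) for i in range(5)
        ]
        profile = progressive_align(seqs)
        fams = extract_families(profile, 0.6)
        assert len(fams.families) == 2
        members = {frozenset(m) for m in fams.families.values()}
        assert frozenset(f"a{i}" for i in range(5)) in members
        assert frozenset(f"b{i}" for i in range(5)) in members

    def test_singleton_far_row_is_own_family(self, rng):
        seqs = [(f"s{i}", "YFWTLYGPIAKDEQRSC") for i in range(4)]
        seqs.append(("lone", "YPPPPPPPPPPPPPPPC"))
        profile = progressive_align(seqs)
        fams = extract_families(profile, 0.6)
        lone_family = fams.families[fams.family_of("lone")]
        assert lone_family == ["lone"]

    def test_families_partition_rows(self, rng):
        seqs = [(f"s{i}", random_peptide(rng)) for i in range(8)]
        profile = progressive_align(seqs)
        fams = extract_families(profile, 0.6)
        all_members = [m for members in fams.families.values() for m in members]
        assert sorted(all_members) == sorted(profile.ids)


class TestGappedIdentity:
    def test_identical_rows(self):
        assert gapped_identity("FW-TL", "FW-TL") == pytest.approx(1.0)

    def test_gap_columns_not_counted_as_matches(self):
        assert gapped_identity("FW-", "FWT") == pytest.approx(1.0)  # 2/min(2,3)... over shorter
        assert gapped_identity("F-W", "FTW") == pytest.approx(1.0)


class TestExports:
    def test_aligned_fasta_and_clustal(self, tmp_path, rng):
        seqs = [(f"s{i}", random_peptide(rng, 12)) for i in range(3)]
        profile = progressive_align(seqs)
        fasta = tmp_path / "msa.fasta"
        aln = tmp_path / "msa.aln"
        write_aligned_fasta(profile, fasta)
        write_clustal(profile, aln)
        assert fasta.read_text().count(">") == 3
        assert aln.read_text().startswith("CLUSTAL")

    def test_logo_matrix_rows_sum_to_one(self, rng):
        seqs = [(f"s{i}", random_peptide(rng, 10)) for i in range(4)]
        profile = progressive_align(seqs)
        logo = logo_matrix(profile)
        assert logo.shape[0] == profile.width
        assert all(abs(s - 1.0) < 1e-9 for s in logo.sum(axis=1))
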