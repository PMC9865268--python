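"""Alignment, duplicate detection, Nei–Gojobori and dating."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from genefam import duplication_kaks as dk
from genefam import synthetic_data as sd
from genefam.datasets import maize_sps8_paralog_pairs
from genefam.seq_io import GeneModel


def affine_nw_oracle(a, b, matrix, gap_open=-10.0, gap_extend=-0.5):
    """Independent affine-gap global alignment score by explicit
    three-state dynamic programming (Gotoh)."""
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend, Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend, X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def global_pathway_oracle(seq_a, seq_b):
    """Exhaustive (Nd, Sd) over orderings of ALL differing sites of the
    whole sequence pair, excluding orderings that create a stop codon.
    Independent of the per-codon implementation."""
    diffs = [i for i in range(len(seq_a)) if seq_a[i] != seq_b[i]]
    totals = []
    for order in itertools.permutations(diffs):
        current = list(seq_a)
        nd = sd_count = 0
        blocked = False
        for pos in order:
            c0 = 3 * (pos // 3)
            before = "".join(current[c0 : c0 + 3])
            current[pos] = seq_b[pos]
            after = "".join(current[c0 : c0 + 3])
            if after in {"TAA", "TAG", "TGA"}:
                blocked = True
                break
            if str(Seq(after).translate()) == str(Seq(before).translate()):
                sd_count += 1
            else:
                nd += 1
        if not blocked:
            totals.append((nd, sd_count))
    assert totals, "oracle: every global pathway blocked"
    return (
        sum(t[0] for t in totals) / len(totals),
        sum(t[1] for t in totals) / len(totals),
    )


class TestGlobalAlign:
    def test_identical(self):
        identity, coverage, _ = dk.global_align("MKVLA", "MKVLA")
        assert identity == 100.0
        assert coverage == 1.0

    def test_coverage_definition(self):
        _, coverage, _ = dk.global_align("ACD", "ACDEEE")
        assert coverage == pytest.approx(0.5)

    def test_score_matches_gotoh_oracle(self):
        from Bio.Align import substitution_matrices

        matrix = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(11)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        aligner_score = None
        for _ in range(15):
            a = "".join(rng.choice(aas, size=int(rng.integers(3, 9))))
            b = "".join(rng.choice(aas, size=int(rng.integers(3, 9))))
            aligner = dk._make_aligner(-10.0, -0.5, "BLOSUM62")
            aligner_score = aligner.score(a, b)
            assert aligner_score == pytest.approx(affine_nw_oracle(a, b, matrix))


class TestFindDuplicates:
    def test_boundary_identity_strict(self):
        # 17/20 identical columns = 85.0% exactly -> excluded
        a = "ACDEFGHIKLMNPQRSTVWY"
        b = "ACDEFGHIKLMNPQRSTAAA"
        identity, coverage, _ = dk.global_align(a, b)
        assert identity == pytest.approx(85.0)
        assert dk.find_duplicates({"a": a, "b": b}) == []

    def test_planted_duplication_only(self, family):
        members = {m: family.proteins[m] for m in family.truth.members}
        pairs = dk.find_duplicates(members)
        found = {(p.gene_a, p.gene_b) for p in pairs}
        expected = {tuple(sorted(p)) for p in family.truth.duplicate_pairs}
        assert found == expected

    def test_dissimilar_set_empty(self):
        rng = np.random.default_rng(0)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        members = {f"g{i}": "".join(rng.choice(aas, size=80)) for i in range(4)}
        assert dk.find_duplicates(members) == []


class TestClassifyDuplication:
    def _gm(self, gid, chrom, start, end):
        return GeneModel(gid, chrom, "+", cds_intervals=[(start, end)])

    def test_far_apart_same_chromosome(self):
        a = self._gm("a", "chr5", 1_000, 2_000)
        b = self._gm("b", "chr5", 5_000_000, 5_001_000)
        others = [self._gm(f"x{i}", "chr5", 10_000 + 50_000 * i, 10_500 + 50_000 * i) for i in range(8)]
        assert dk.classify_duplication(a, b, [a, b] + others) == "segmental"

    def test_different_chromosomes(self):
        a = self._gm("a", "chr1", 1, 100)
        b = self._gm("b", "chr2", 1, 100)
        assert dk.classify_duplication(a, b) == "segmental"

    def test_adjacent_genes_tandem(self):
        a = self._gm("a", "chr1", 1_000, 2_000)
        b = self._gm("b", "chr1", 22_000, 23_000)  # 20 kb apart
        assert dk.classify_duplication(a, b) == "tandem"

    def test_few_intervening_genes_tandem(self):
        a = self._gm("a", "chr1", 1_000, 2_000)
        b = self._gm("b", "chr1", 900_000, 901_000)
        others = [self._gm("x1", "chr1", 400_000, 401_000)]
        assert dk.classify_duplication(a, b, [a, b] + others) == "tandem"


class TestCodonAlign:
    def test_ungapped_identical(self):
        aln = dk.codon_align("ATGAAA", "ATGAAA", ("MK", "MK"))
        assert aln.seq_a == "ATGAAA"
        assert aln.seq_b == "ATGAAA"

    def test_gap_drops_codon(self):
        aln = dk.codon_align("ATGGCTAAA", "ATGAAA", ("MAK", "M-K"))
        assert aln.seq_a == "ATGAAA"
        assert aln.seq_b == "ATGAAA"

    def test_roundtrip_translation(self):
        from genefam.seq_io import translate

        aln = dk.codon_align("ATGGCTAAA", "ATGAAA", ("MAK", "M-K"))
        # shared columns only: the gapped residue's codon is dropped
        assert translate(aln.seq_a) == "MK"
        assert translate(aln.seq_b) == "MK"

    def test_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not encode"):
            dk.codon_align("ATGAAA", "ATGAAA", ("MV", "MK"))


class TestNeiGojobori:
    def test_identical_sequences(self):
        aln = dk.CodonAlignment("ATGGCTAAA", "ATGGCTAAA")
        res = dk.nei_gojobori(aln)
        assert res.ka == 0.0
        assert res.ks == 0.0

    def test_phenylalanine_codon_sites(self):
        n, s = dk.codon_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_sites_sum_to_three(self):
        for codon in ("ATG", "TGG", "CGA", "TAC", "TTA", "GGG"):
            n, s = dk.codon_sites(codon)
            assert n + s == pytest.approx(3.0)

    def test_symmetry(self):
        a, b = "ATGGCTAAACGT", "ATGGAAAAACGA"
        r1 = dk.nei_gojobori(dk.CodonAlignment(a, b))
        r2 = dk.nei_gojobori(dk.CodonAlignment(b, a))
        assert r1.ka == pytest.approx(r2.ka)
        assert r1.ks == pytest.approx(r2.ks)

    def test_difference_counts_match_pathway_oracle(self):
        """(Nd, Sd) equal an exhaustive global pathway enumeration on
        random small codon pairs."""
        rng = np.random.default_rng(21)
        checked = 0
        while checked < 12:
            n_codons = int(rng.integers(2, 11))
            anc = sd.reverse_translate(
                "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n_codons)), rng
            )
            a, b, _ = sd.evolve_codon_pair(anc, 0.3, 1.0, seed=int(rng.integers(2**31)))
            n_diffs = sum(x != y for x, y in zip(a, b))
            if not 1 <= n_diffs <= 6:
                continue
            aln = dk.CodonAlignment(a, b)
            res = dk.nei_gojobori(aln)
            nd_exp, sd_exp = global_pathway_oracle(a, b)
            assert res.nd == pytest.approx(nd_exp)
            assert res.sd == pytest.approx(sd_exp)
            checked += 1

    def test_saturation_flag(self):
        assert dk.jukes_cantor(0.8) is None
        assert dk.jukes_cantor(0.1) == pytest.approx(-0.75 * np.log(1 - 4 * 0.1 / 3))


class TestDivergenceTime:
    @pytest.mark.parametrize(
        "ks,expected",
        [(0.014907323, 0.496910769), (0.803034338, 26.76781128)],
    )
    def test_published_pair_dating(self, ks, expected):
        assert dk.divergence_time(ks) == pytest.approx(expected, abs=1e-6)

    def test_zero_and_discarded(self):
        assert dk.divergence_time(0.0) == 0.0
        assert dk.divergence_time(2.5) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            dk.divergence_time(-0.1)


class TestSelectionClass:
    def test_published_pairs_split(self):
        table = maize_sps8_paralog_pairs()
        classes = [dk.classify_selection(ka / ks) for ka, ks in zip(table.Ka, table.Ks)]
        assert classes.count("purifying") == 2
        assert classes.count("positive") == 1


def test_parameter_recovery_small():
    """Estimator recovers planted Ks and omega on a reduced replicate set
    (the full grid runs in the acceptance suite)."""
    rng = np.random.default_rng(5)
    anc = sd.reverse_translate(
        "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=300)), rng
    )
    ks_est, om_est = [], []
    for rep in range(15):
        a, b, _ = sd.evolve_codon_pair(anc, 0.5, 0.3, seed=100 + rep)
        res = dk.nei_gojobori(dk.CodonAlignment(a, b))
        ks_est.append(res.ks)
        om_est.append(res.omega)
    assert np.mean(ks_est) == pytest.approx(0.5, rel=0.15)
    assert np.mean(om_est) == pytest.approx(0.3, rel=0.2)
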