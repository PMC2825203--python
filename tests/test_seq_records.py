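"""Sequence parsing, polyA trimming, translation, ORF finding and alignment."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leascan.seq_records import (AlphabetError, NucleotideSequence, find_longest_orf,
                                 global_align, read_fasta, translate, trim_polya)

DNA = st.text(alphabet="ACGT", min_size=0, max_size=8)


def brute_force_align_score(a: str, b: str, match=1, mismatch=-1, gap=-1) -> int:
    """Independent optimum over the whole alignment space by recursion."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if i == len(a) and j == len(b):
            return 0
        options = []
        if i < len(a) and j < len(b):
            options.append((match if a[i] == b[j] else mismatch) + best(i + 1, j + 1))
        if i < len(a):
            options.append(gap + best(i + 1, j))
        if j < len(b):
            options.append(gap + best(i, j + 1))
        return max(options)

    return best(0, 0)


class TestReadFasta:
    def test_order_and_case(self, fasta_file):
        path = fasta_file({"b": "acgt", "a": "GGNN"})
        recs = read_fasta(path)
        assert [r.id for r in recs] == ["b", "a"]
        assert recs[0].bases == "ACGT"
        assert recs[1].bases == "GGNN"

    def test_empty_file_gives_empty_list(self, fasta_file, caplog):
        path = fasta_file({})
        assert read_fasta(path) == []

    def test_bad_alphabet_names_record(self, fasta_file):
        path = fasta_file({"ok": "ACGT", "bad": "ACG1"})
        with pytest.raises(AlphabetError, match="bad"):
            read_fasta(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_fasta(tmp_path / "nope.fasta")

    def test_duplicate_ids_rejected(self, fasta_file, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">x\nACGT\n>x\nGGGG\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(path)

    def test_protein_mode(self, fasta_file):
        path = fasta_file({"p": "MKKDE"})
        recs = read_fasta(path, mode="protein")
        assert recs[0].residues == "MKKDE"


class TestTrimPolya:
    @pytest.mark.parametrize("bases,expected_trimmed,expected_len", [
        ("ACGT", "ACGT", 0),                       # no tail
        ("ACGT" + "A" * 12, "ACGT", 12),           # clean tail
        ("ACGT" + "A" * 7, "ACGT" + "A" * 7, 0),   # below min_run
        ("ACGTAAAAAAGAAAAA", "ACGT", 12),          # one error inside the tail
    ])
    def test_cases(self, nt, bases, expected_trimmed, expected_len):
        trimmed, n = trim_polya(nt(bases))
        assert trimmed.bases == expected_trimmed
        assert n == expected_len

    def test_all_tail_gives_empty_sequence(self, nt, caplog):
        trimmed, n = trim_polya(nt("A" * 20))
        assert trimmed.bases == ""
        assert n == 20

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_idempotent(self, bases):
        seq = NucleotideSequence("s", bases)
        once, n1 = trim_polya(seq)
        if not once.bases:
            return
        twice, n2 = trim_polya(once)
        assert twice.bases == once.bases
        assert n2 == 0


class TestTranslate:
    @pytest.mark.parametrize("codons,readthrough,expected", [
        ("ATG", 0, "M"),
        ("ATGTGAGCGTAA", 0, "M"),
        ("ATGTGAGCGTAA", 1, "MUA"),
        ("ATGNNN", 0, "MX"),
        ("ATGTAAGCG", 5, "M"),   # UAA always stops, budget notwithstanding
        ("ATGTGATGAGCGTGA", 2, "MUUA"),
    ])
    def test_cases(self, codons, readthrough, expected):
        assert translate(codons, readthrough_uga=readthrough).residues == expected

    def test_length_not_multiple_of_three(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            translate("ATGA")


class TestFindLongestOrf:
    def test_hand_scanned_example(self, nt):
        orf = find_longest_orf(nt("TTATGAAATAATT"))
        assert orf.protein.residues == "MK"
        assert (orf.start, orf.end) == (3, 11)

    def test_no_atg(self, nt):
        assert find_longest_orf(nt("CCCCCC")) is None

    def test_open_end_only_with_flag(self, nt):
        seq = nt("ATGAAAAAA")  # no stop codon
        assert find_longest_orf(seq) is None
        orf = find_longest_orf(seq, allow_open_end=True)
        assert orf.protein.residues == "MKK"
        assert not orf.has_stop

    def test_tie_broken_by_smaller_start(self, nt):
        # two single-codon ORFs in different frames: ATG.TAA at 1, ATG.TAA at 8
        seq = nt("ATGTAAGATGTAA")
        orf = find_longest_orf(seq)
        assert orf.start == 1

    def test_readthrough_extends_orf(self, nt):
        # ATG GCG TGA AAA TAA: stop at TGA without budget, through it with
        seq = nt("ATGGCGTGAAAATAA")
        assert find_longest_orf(seq).protein.residues == "MA"
        orf = find_longest_orf(seq, readthrough_uga=1)
        assert orf.protein.residues == "MAUK"
        assert orf.uga_readthroughs == 1

    def test_reverse_strand_behind_flag(self, nt):
        from leascan.seq_records import reverse_complement
        fwd = "ATGAAAGCGTAA"
        seq = nt(reverse_complement(fwd))
        assert find_longest_orf(seq) is None
        orf = find_longest_orf(seq, forward_only=False)
        assert orf.protein.residues == "MKA"
        assert orf.strand == "-"


class TestGlobalAlign:
    def test_identity(self):
        res = global_align("GATTACA", "GATTACA")
        assert res.score == 7
        assert res.identity_percent == 100.0

    def test_empty_vs_sequence(self):
        res = global_align("ACGT", "")
        assert res.score == -4
        assert res.identity_percent == 0.0
        assert res.aligned_b == "----"

    def test_gap_recovery_invariant(self):
        res = global_align("ACGTAC", "AGTAC")
        assert res.aligned_a.replace("-", "") == "ACGTAC"
        assert res.aligned_b.replace("-", "") == "AGTAC"

    @given(DNA, DNA)
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_optimum(self, a, b):
        assert global_align(a, b).score == brute_force_align_score(a, b)

    @given(DNA, DNA)
    @settings(max_examples=100, deadline=None)
    def test_score_symmetry(self, a, b):
        assert global_align(a, b).score == global_align(b, a).score

    def test_agrees_with_biopython(self):
        from Bio import Align

        aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                        mismatch_score=-1, gap_score=-1)
        import random

        rng = random.Random(0)
        for _ in range(50):
            a = "".join(rng.choices("ACGT", k=rng.randint(1, 12)))
            b = "".join(rng.choices("ACGT", k=rng.randint(1, 12)))
            assert global_align(a, b).score == int(aligner.score(a, b))
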