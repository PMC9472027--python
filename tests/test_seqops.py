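"""Sequence operations against hand values and independent oracles.

The 64-codon translation check uses Biopython's codon table as the external
authority; the ORF finder is checked against a brute-force triplet scan; the
replace-trick GC count is checked against a direct character tally.
"""

import random

import pytest
from Bio.Data import CodonTable
from hypothesis import given, settings
from hypothesis import strategies as st

from biostr.errors import CodeTableError, FrameError
from biostr.model import BioSequence, Molecule
from biostr.seqops import (
    gc_content,
    gc_fraction,
    load_genetic_code,
    reverse_complement,
    search_orfs,
    standard_code,
    transcribe,
    translate,
)
from conftest import brute_force_orfs, dna, gc_tally, random_nucleotides, rna

NUC = st.text(alphabet="ACGTN", max_size=120)


class TestGcContent:
    @pytest.mark.parametrize("s,expected", [("ATGC", 2), ("AATT", 0), ("GGCC", 4), ("", 0)])
    def test_hand_values(self, s, expected):
        assert gc_content(dna(s)) == expected

    def test_matches_direct_tally_on_random_sequence(self):
        rng = random.Random(42)
        s = random_nucleotides(rng, 1000)
        assert gc_content(dna(s)) == gc_tally(s)

    def test_protein_input_rejected(self):
        with pytest.raises(TypeError):
            gc_content(BioSequence("MKV", Molecule.PROTEIN))

    @given(st.text(alphabet="ACGTNRYSWKMBDHV", max_size=200))
    @settings(max_examples=200, derandomize=True)
    def test_gc_plus_at_plus_ambiguity_partitions_length(self, s):
        seq = dna(s)
        at = sum(1 for ch in s if ch in "AT")
        amb = sum(1 for ch in s if ch not in "ACGT")
        assert gc_content(seq) + at + amb == len(s)


class TestGcFraction:
    @pytest.mark.parametrize("s,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("ATGCN", 0.5)])
    def test_ambiguity_excluded_from_denominator(self, s, expected):
        assert gc_fraction(dna(s)) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            gc_fraction(dna(""))


class TestTranscribe:
    @pytest.mark.parametrize("s,expected", [("ATGC", "AUGC"), ("", ""), ("TTTT", "UUUU")])
    def test_t_to_u_in_place(self, s, expected):
        out = transcribe(dna(s))
        assert out.residues == expected and out.molecule is Molecule.RNA

    def test_rna_input_rejected(self):
        with pytest.raises(TypeError):
            transcribe(rna("AUGC"))

    @given(NUC)
    @settings(max_examples=100, derandomize=True)
    def test_length_preserved_and_no_t_left(self, s):
        out = transcribe(dna(s)).residues
        assert len(out) == len(s) and "T" not in out


class TestReverseComplement:
    @pytest.mark.parametrize("s,expected", [("ATGC", "GCAT"), ("AAAA", "TTTT"), ("N", "N")])
    def test_hand_values(self, s, expected):
        assert reverse_complement(dna(s)).residues == expected

    @given(st.text(alphabet="ACGTNRYSWKMBDHV", max_size=120))
    @settings(max_examples=100, derandomize=True)
    def test_involution(self, s):
        seq = dna(s)
        assert reverse_complement(reverse_complement(seq)) == seq


class TestTranslate:
    def test_aug_is_methionine(self):
        assert translate(rna("AUG")).residues == "M"

    def test_truncates_at_first_stop(self):
        assert translate(rna("AUGUUUUAA")).residues == "MF"

    def test_read_through_emits_star(self):
        assert translate(rna("AUGUAAUUU"), stop_policy="read_through").residues == "M*F"

    def test_all_64_codons_match_ncbi_table(self):
        ncbi = CodonTable.unambiguous_rna_by_id[1]
        code = standard_code()
        for a in "ACGU":
            for b in "ACGU":
                for c in "ACGU":
                    codon = a + b + c
                    got = translate(rna(codon), code=code, stop_policy="read_through").residues
                    if codon in ncbi.stop_codons:
                        assert got == "*"
                    else:
                        assert got == ncbi.forward_table[codon]

    @pytest.mark.parametrize("frame,expected", [(1, "MF"), (2, "CF"), (3, "VF")])
    def test_frames_shift_codon_grid(self, frame, expected):
        # AUGUUUU: frame 2 reads UGU UUU, frame 3 reads GUU UU(dropped)
        assert translate(rna("AUGUUUUUC"), frame=frame, stop_policy="read_through").residues[:2] == expected[:2]

    def test_ambiguity_codon_yields_x(self):
        assert translate(rna("AUNGCC"), stop_policy="read_through").residues == "XA"

    def test_bad_frame_rejected(self):
        with pytest.raises(FrameError):
            translate(rna("AUG"), frame=4)

    @given(st.text(alphabet="ACGU", max_size=90), st.sampled_from([1, 2, 3]))
    @settings(max_examples=150, derandomize=True)
    def test_read_through_length_formula(self, s, frame):
        out = translate(rna(s), frame=frame, stop_policy="read_through")
        assert len(out) == max(0, (len(s) - frame + 1) // 3)


class TestSearchOrfs:
    def test_single_orf_by_construction(self):
        (orf,) = search_orfs(rna("AUGUUUUAA"), frame=1, min_peptide_len=1)
        assert (orf.frame, orf.start, orf.end, orf.peptide) == (1, 1, 9, "MF")
        assert orf.nt_length == 9 == 3 * (len(orf.peptide) + 1)

    def test_no_start_codon_no_orfs(self):
        assert search_orfs(rna("UUUUUU"), frame=1, min_peptide_len=1) == []

    def test_unbounded_span_not_reported(self):
        # AUG with no downstream in-frame stop
        assert search_orfs(rna("AUGUUUUUU"), frame=1, min_peptide_len=1) == []

    def test_dna_input_transcribed_first(self):
        (orf,) = search_orfs(dna("ATGTTTTAA"), frame=1, min_peptide_len=1)
        assert orf.peptide == "MF"

    def test_nested_starts_share_stop(self):
        # two in-frame AUGs before one stop -> two ORFs ending together
        orfs = search_orfs(rna("AUGAUGUUUUGA"), frame=1, min_peptide_len=1)
        assert [(o.start, o.end) for o in orfs] == [(1, 12), (4, 12)]
        assert [o.peptide for o in orfs] == ["MMF", "MF"]

    def test_min_peptide_len_filters(self):
        assert search_orfs(rna("AUGUUUUAA"), frame=1, min_peptide_len=3) == []
        with pytest.raises(ValueError):
            search_orfs(rna("AUG"), frame=1, min_peptide_len=0)

    def test_matches_brute_force_oracle_on_random_sequences(self):
        rng = random.Random(7)
        code = standard_code()
        for _ in range(300):
            s = random_nucleotides(rng, 400, alphabet="ACGU")
            for frame in (1, 2, 3):
                got = [
                    (o.start, o.end, o.peptide)
                    for o in search_orfs(rna(s), frame=frame, min_peptide_len=1)
                ]
                assert got == brute_force_orfs(s, frame, 1, code.codon_map)

    @given(st.text(alphabet="ACGUN", max_size=200), st.sampled_from([1, 2, 3]))
    @settings(max_examples=150, derandomize=True)
    def test_records_satisfy_invariants_and_match_oracle(self, s, frame):
        code = standard_code()
        orfs = search_orfs(rna(s), frame=frame, min_peptide_len=1)
        for o in orfs:
            assert o.nt_length % 3 == 0
            assert o.peptide.startswith("M")
            assert o.nt_length == 3 * (len(o.peptide) + 1)
        assert [(o.start, o.end, o.peptide) for o in orfs] == brute_force_orfs(
            s, frame, 1, code.codon_map
        )


class TestLoadGeneticCode:
    def test_missing_codon_rejected(self, tmp_path):
        ref = standard_code()
        rows = [f"{c}\t{aa}\t0" for c, aa in list(ref.codon_map.items())[:63]]
        bad = tmp_path / "bad.tsv"
        bad.write_text("codon\taa\tis_start\n" + "\n".join(rows) + "\n")
        with pytest.raises(CodeTableError):
            load_genetic_code(bad)

    def test_duplicate_codon_rejected(self, tmp_path):
        bad = tmp_path / "dup.tsv"
        bad.write_text("codon\taa\tis_start\nAUG\tM\t1\nAUG\tM\t1\n")
        with pytest.raises(CodeTableError):
            load_genetic_code(bad)

    def test_illegal_amino_acid_rejected(self, tmp_path):
        ref = standard_code()
        rows = [f"{c}\t{aa}\t0" for c, aa in ref.codon_map.items()]
        rows[0] = rows[0].rsplit("\t", 2)[0] + "\tZ\t0"
        bad = tmp_path / "z.tsv"
        bad.write_text("codon\taa\tis_start\n" + "\n".join(rows) + "\n")
        with pytest.raises(CodeTableError):
            load_genetic_code(bad)
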