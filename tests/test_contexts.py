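"""Context classification: SBS96, DBS78, ID83 and SV16.

The ID83 checks compare the classifier against an independent brute-force
repeat/microhomology scanner implemented here on plain strings.
"""

import numpy as np
import pytest

from mutaccum.catalogs import BASES, DBS78, SBS96, revcomp
from mutaccum.contexts import (
    ClassificationError,
    build_spectrum_matrix,
    classify_dbs,
    classify_indel,
    classify_sbs,
    classify_sv,
)
from mutaccum.io import MutationRecord, ReferenceGenome

from conftest import write_fasta


def sbs(ref, alt, pos=500):
    return MutationRecord("chr1", pos, ref, alt, "SBS")


def dbs(ref, alt):
    return MutationRecord("chr1", 500, ref, alt, "DBS")


class TestSbs:
    @pytest.mark.parametrize(
        "ref,alt,flanks,expected",
        [
            ("C", "T", "ACG", "A[C>T]G"),   # already pyrimidine
            ("G", "A", "CGT", "A[C>T]G"),   # purine: reverse complemented
            ("T", "G", "TTT", "T[T>G]T"),
        ],
    )
    def test_examples(self, ref, alt, flanks, expected):
        assert classify_sbs(sbs(ref, alt), flanks) == expected

    def test_n_in_flank_skips(self):
        assert classify_sbs(sbs("C", "T"), "NCG") is None

    def test_center_mismatch_is_integrity_error(self):
        with pytest.raises(ClassificationError, match="mismatch"):
            classify_sbs(sbs("C", "T"), "AAG")

    def test_strand_symmetry_exhaustive(self):
        """Classifying a substitution and its full reverse complement gives
        the identical label, over all 192 (ref, alt, flank) combinations,
        and the labels cover the whole 96-category catalog."""
        seen = set()
        for ref in BASES:
            for alt in BASES:
                if alt == ref:
                    continue
                for f5 in BASES:
                    for f3 in BASES:
                        trinuc = f5 + ref + f3
                        fwd = classify_sbs(sbs(ref, alt), trinuc)
                        rev = classify_sbs(
                            sbs(revcomp(ref), revcomp(alt)), revcomp(trinuc)
                        )
                        assert fwd == rev
                        assert fwd[2] in "CT"  # pyrimidine reference strand
                        seen.add(fwd)
        assert seen == set(SBS96)


class TestDbs:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("CC", "TT", "CC>TT"),  # canonical stays
            ("GG", "AA", "CC>TT"),  # reverse complement both sides
            ("AT", "CG", "AT>CG"),  # palindromic ref, catalog-fixed alt
        ],
    )
    def test_examples(self, ref, alt, expected):
        assert classify_dbs(dbs(ref, alt)) == expected

    def test_identical_ref_alt_rejected(self):
        with pytest.raises(ClassificationError):
            classify_dbs(dbs("CC", "CC"))

    def test_single_base_change_doublet_rejected(self):
        with pytest.raises(ClassificationError, match="catalog"):
            classify_dbs(dbs("AC", "AG"))

    def test_strand_symmetry_exhaustive(self):
        seen = set()
        for r1 in BASES:
            for r2 in BASES:
                for a1 in BASES:
                    for a2 in BASES:
                        if a1 == r1 or a2 == r2:
                            continue
                        ref, alt = r1 + r2, a1 + a2
                        fwd = classify_dbs(dbs(ref, alt))
                        rev = classify_dbs(dbs(revcomp(ref), revcomp(alt)))
                        assert fwd == rev
                        seen.add(fwd)
        assert seen == set(DBS78)


# ---------------------------------------------------------------------------
# ID83: brute-force oracle
# ---------------------------------------------------------------------------

_PYR = {"A": "T", "G": "C", "C": "C", "T": "T"}


def brute_indel_label(genome: str, pos: int, ref: str, alt: str):
    """Independent repeat/microhomology scanner on a plain string.

    Same category semantics as the classifier but implemented by direct
    slicing of the full chromosome string.
    """
    if len(ref) > len(alt) and ref.startswith(alt):
        seq = ref[len(alt):]
        i0 = pos - 1 + len(alt)  # 0-based first deleted base
        size = len(seq)
        n = 1
        j = i0 + size
        while genome[j : j + size] == seq:
            n += 1
            j += size
        j = i0 - size
        while j >= 0 and genome[j : j + size] == seq:
            n += 1
            j -= size
        if size == 1:
            return f"1:Del:{_PYR[seq]}:{'6+' if n >= 6 else n}"
        size_lab = "5+" if size >= 5 else str(size)
        if n >= 2:
            return f"{size_lab}:Del:R:{'6+' if n >= 6 else n}"
        right = genome[i0 + size :]
        left = genome[:i0]
        fwd = 0
        while fwd < size - 1 and fwd < len(right) and right[fwd] == seq[fwd]:
            fwd += 1
        rev = 0
        while rev < size - 1 and rev < len(left) and left[-1 - rev] == seq[-1 - rev]:
            rev += 1
        hom = min(max(fwd, rev), size - 1)
        if hom >= 1:
            return f"{size_lab}:Del:M:{'5+' if hom >= 5 else hom}"
        return f"{size_lab}:Del:R:1"
    if len(alt) > len(ref) and alt.startswith(ref):
        seq = alt[len(ref):]
        i0 = pos - 1 + len(ref)  # 0-based first base after the insertion point
        size = len(seq)
        n = 0
        j = i0
        while genome[j : j + size] == seq:
            n += 1
            j += size
        j = i0 - size
        while j >= 0 and genome[j : j + size] == seq:
            n += 1
            j -= size
        n_lab = "5+" if n >= 5 else str(n)
        if size == 1:
            return f"1:Ins:{_PYR[seq]}:{n_lab}"
        return f"{'5+' if size >= 5 else size}:Ins:R:{n_lab}"
    return None


def indel(pos, ref, alt):
    return MutationRecord("chr1", pos, ref, alt, "INDEL")


class TestIndel:
    def test_1bp_deletion_in_homopolymer_run_of_five(self, tmp_path):
        genome = ReferenceGenome(
            write_fasta(tmp_path / "g.fa", "ACGCATTTTTGCACGA"))
        # delete one T of the TTTTT run (left-aligned anchor at pos 5)
        assert classify_indel(indel(5, "AT", "A"), genome) == "1:Del:T:5"

    def test_2bp_insertion_without_repeat_or_homology(self, tmp_path):
        genome = ReferenceGenome(write_fasta(tmp_path / "g.fa", "ACGTGGTAGCC"))
        assert classify_indel(indel(4, "T", "TCA"), genome) == "2:Ins:R:0"

    def test_4bp_deletion_with_2bp_microhomology(self, tmp_path):
        genome = ReferenceGenome(write_fasta(tmp_path / "g.fa", "CCGGATAGCTATTCC"))
        assert classify_indel(indel(5, "ATAGC", "A"), genome) == "4:Del:M:2"

    def test_complex_indel_excluded(self, toy_genome):
        assert classify_indel(indel(500, "ACG", "TT"), toy_genome) is None

    def test_agrees_with_brute_force_scanner_on_random_indels(
        self, toy_genome, toy_genome_seq
    ):
        """1,000 random toy-genome indels: classifier and the independent
        string scanner agree on every label."""
        rng = np.random.default_rng(2024)
        n_checked = 0
        while n_checked < 1000:
            pos = int(rng.integers(200, len(toy_genome_seq) - 200))
            anchor = toy_genome_seq[pos - 1]
            if rng.random() < 0.5:
                size = int(rng.integers(1, 9))
                ref = toy_genome_seq[pos - 1 : pos + size]
                alt = anchor
            else:
                size = int(rng.integers(1, 9))
                ins = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size)])
                ref = anchor
                alt = anchor + ins
            got = classify_indel(indel(pos, ref, alt), toy_genome)
            expected = brute_indel_label(toy_genome_seq, pos, ref, alt)
            assert got == expected, (pos, ref, alt)
            n_checked += 1


class TestSv:
    def sv(self, sv_type, sv_len):
        alt = f"<{sv_type}>"
        return MutationRecord("chr1", 100, "N", alt, "SV",
                              sv_type=sv_type, sv_len=sv_len)

    def test_deletion_binned_by_length(self):
        assert classify_sv(self.sv("DEL", 25_000)) == "DEL_10kb-100kb"

    def test_translocation_unbinned(self):
        assert classify_sv(self.sv("TRA", None)) == "TRA"

    def test_boundary_is_right_closed(self):
        assert classify_sv(self.sv("INV", 10_000)) == "INV_1kb-10kb"

    def test_missing_length_excluded(self):
        assert classify_sv(self.sv("DUP", None)) is None


class TestSpectrumMatrix:
    def test_single_context_count(self, toy_genome, toy_genome_seq):
        # find an ACG site and mutate its center three times? positions must
        # be distinct records, same category
        idx = [i for i in range(1, len(toy_genome_seq) - 1)
               if toy_genome_seq[i - 1 : i + 2] == "ACG"][:3]
        recs = [sbs("C", "T", pos=i + 1) for i in idx]
        _, matrix = build_spectrum_matrix({"c1": recs}, toy_genome, "SBS")
        col = matrix["c1"]
        assert col["A[C>T]G"] == 3
        assert col.sum() == 3

    def test_clone_without_variants_keeps_zero_column(self, toy_genome):
        _, matrix = build_spectrum_matrix({"empty": []}, toy_genome, "SBS")
        assert "empty" in matrix.columns
        assert matrix["empty"].sum() == 0

    def test_counts_conserved_per_clone(self, toy_genome, toy_genome_seq):
        rng = np.random.default_rng(77)
        recs = []
        for _ in range(50):
            pos = int(rng.integers(2, len(toy_genome_seq) - 1))
            ref = toy_genome_seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            recs.append(sbs(ref, str(alt), pos=pos))
        _, matrix = build_spectrum_matrix({"c": recs}, toy_genome, "SBS")
        assert matrix["c"].sum() == 50
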