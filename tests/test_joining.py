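import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairtax.io_formats import SeqRecord, char_to_phred, reverse_complement
from pairtax.joining import (
    PAD_QUAL,
    direct_join,
    inside_out_join,
    merge_pair,
    optimize_trim_length,
    split_direct_join,
    trim_primer,
    trim_to_length,
)
from pairtax.simulate import miseq_300, simulate_pe_reads

from conftest import random_dna, record_amplicon

dna = st.text(alphabet="ACGT", min_size=1, max_size=120)


class TestDirectJoin:
    def test_definition(self):
        j = direct_join(SeqRecord("x", "ACGT", "IIII"),
                        SeqRecord("x", "AAAA", "FFFF"), pad_len=2)
        assert j.seq == "ACGTNNTTTT"
        assert j.qual == "IIII" + PAD_QUAL * 2 + "FFFF"

    def test_zero_pad_degenerate(self):
        j = direct_join(SeqRecord("x", "A", "I"), SeqRecord("x", "T", "I"), 0)
        assert j.seq == "AA"

    def test_unmergeable_pair_keeps_all_base_calls(self):
        rng = np.random.default_rng(0)
        amp = random_dna(rng, 725)
        r1 = SeqRecord("a", amp[:300], "I" * 300)
        r2 = SeqRecord("a", reverse_complement(amp[-300:]), "I" * 300)
        j = direct_join(r1, r2)
        assert sum(1 for b in j.seq if b != "N") == 600

    def test_split_recovers_reads(self):
        rng = np.random.default_rng(5)
        r1 = SeqRecord("x", random_dna(rng, 40), "I" * 40)
        r2 = SeqRecord("x", random_dna(rng, 35), "J" * 35)
        j = direct_join(r1, r2, pad_len=6)
        b1, b2 = split_direct_join(j, len(r1.seq))
        assert (b1.seq, b1.qual) == (r1.seq, r1.qual)
        assert (b2.seq, b2.qual) == (r2.seq, r2.qual)

    @settings(max_examples=100, derandomize=True)
    @given(dna, dna, st.integers(min_value=0, max_value=20))
    def test_length_bookkeeping(self, s1, s2, pad):
        j = direct_join(SeqRecord("a", s1), SeqRecord("a", s2), pad)
        assert len(j.seq) == len(s1) + pad + len(s2)
        assert len(j.qual) == len(j.seq)
        io = inside_out_join(SeqRecord("a", s1), SeqRecord("a", s2))
        assert len(io.seq) == len(s1) + len(s2)


class TestInsideOutJoin:
    def test_definition(self):
        j = inside_out_join(SeqRecord("x", "ACGT", "IIII"),
                            SeqRecord("x", "AAAA", "FFFF"))
        assert j.seq == "TTTTACGT"
        assert j.pad_len == 0

    def test_mirror_structure_when_reads_identical(self):
        r1 = SeqRecord("x", "ACGTTG")
        j = inside_out_join(r1, r1)
        half = len(j.seq) // 2
        assert j.seq[half:] == reverse_complement(j.seq[:half])

    def test_low_quality_tails_move_to_ends(self):
        # tail-heavy error profile -> worst qualities at the output's two ends
        profile = miseq_300()
        rng = np.random.default_rng(1)
        amp = record_amplicon(SeqRecord("a", random_dna(rng, 700)))
        r1, r2 = simulate_pe_reads(amp, profile, n_pairs=1, seed=2)[0]
        j = inside_out_join(r1, r2)
        quals = [char_to_phred(c) for c in j.qual]
        edge = min(min(quals[:20]), min(quals[-20:]))
        middle = min(quals[280:320])
        assert edge < middle


def _merge_oracle(s1, rc2, min_overlap, max_rate):
    """All-offsets brute force: longest acceptable overlap, else best rate."""
    candidates = []
    for ov in range(min(len(s1), len(rc2)), min_overlap - 1, -1):
        mism = sum(a != b for a, b in zip(s1[len(s1) - ov:], rc2[:ov]))
        candidates.append((ov, mism / ov))
    acceptable = [c for c in candidates if c[1] <= max_rate]
    if not candidates:
        return ("no_overlap", 0)
    if acceptable:
        return ("merged", max(acceptable, key=lambda c: c[0])[0])
    return ("too_many_mismatches", None)


class TestMergePair:
    def test_exact_overlap(self):
        full = "ACGTACGTACGT"
        r1 = SeqRecord("m", full[:10], "I" * 10)
        r2 = SeqRecord("m", reverse_complement(full[2:]), "I" * 10)
        res = merge_pair(r1, r2, min_overlap=8)
        assert res.status == "merged"
        assert res.overlap_len == 8
        assert res.mismatch_rate == 0.0
        assert res.merged.seq == full

    def test_mismatch_rate_threshold(self):
        rng = np.random.default_rng(7)
        full = random_dna(rng, 12)
        r1 = SeqRecord("m", full[:10], "I" * 10)
        tail = list(full[2:])
        # plant 3 mismatches inside the 8-base true overlap
        for pos in (0, 3, 6):
            tail[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[tail[pos]]
        r2 = SeqRecord("m", reverse_complement("".join(tail)), "I" * 10)
        res = merge_pair(r1, r2, min_overlap=8, max_mismatch_rate=0.25)
        assert res.status == "too_many_mismatches"

    def test_minimal_overlap_length_arithmetic(self):
        rng = np.random.default_rng(1)
        frag = random_dna(rng, 590)
        r1 = SeqRecord("m", frag[:300], "I" * 300)
        r2 = SeqRecord("m", reverse_complement(frag[290:]), "I" * 300)
        res = merge_pair(r1, r2, min_overlap=10, max_mismatch_rate=0.25)
        assert res.status == "merged"
        assert len(res.merged.seq) == 590

    def test_quality_based_error_correction(self):
        rng = np.random.default_rng(3)
        frag = random_dna(rng, 60)
        r1s, r2s = frag[:40], frag[20:]
        q1 = ["I"] * 40
        q2 = ["I"] * 40
        # plant errors in r1's copy of the overlap, with low quality
        r1l = list(r1s)
        for pos in (25, 30):
            r1l[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[r1l[pos]]
            q1[pos] = "!"
        res = merge_pair(
            SeqRecord("m", "".join(r1l), "".join(q1)),
            SeqRecord("m", reverse_complement(r2s), "".join(q2)[::-1]),
            min_overlap=15,
        )
        assert res.status == "merged"
        assert res.merged.seq == frag

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        n_checked = 0
        for _ in range(1000):
            frag_len = int(rng.integers(30, 80))
            read_len = int(rng.integers(15, min(40, frag_len)))
            frag = random_dna(rng, frag_len)
            r1s = frag[:read_len]
            r2s = frag[max(0, frag_len - read_len):]
            # random substitutions anywhere
            r1l = list(r1s)
            for pos in rng.choice(len(r1l), size=int(rng.integers(0, 4)),
                                  replace=False):
                r1l[pos] = "ACGT"[rng.integers(4)]
            r1_seq = "".join(r1l)
            rc2 = r2s
            res = merge_pair(
                SeqRecord("m", r1_seq, "I" * len(r1_seq)),
                SeqRecord("m", reverse_complement(rc2), "I" * len(rc2)),
                min_overlap=8,
            )
            status, ov = _merge_oracle(r1_seq, rc2, 8, 0.25)
            assert res.status == status
            if status == "merged":
                assert res.overlap_len == ov
            n_checked += 1
        assert n_checked == 1000


class TestPrimerTrimming:
    PRIMER_27F = "AGAGTTTGATCCTGGCTCAG"

    def test_exact_primer_removed(self):
        read = SeqRecord("r", self.PRIMER_27F + "ACGTACGT")
        out, found = trim_primer(read, self.PRIMER_27F)
        assert found and out.seq == "ACGTACGT"

    def test_one_substitution_within_budget(self):
        prefix = "T" + self.PRIMER_27F[1:]
        out, found = trim_primer(SeqRecord("r", prefix + "ACGT"),
                                 self.PRIMER_27F, maxdiffs=3)
        assert found and out.seq == "ACGT"

    def test_absent_primer_leaves_read(self):
        read = SeqRecord("r", "CCCCCCCCCCCCCCCCCCCCCCCCCCCC")
        out, found = trim_primer(read, self.PRIMER_27F, maxdiffs=3)
        assert not found and out.seq == read.seq

    def test_n_in_read_counts_as_difference(self):
        prefix = "NNNN" + self.PRIMER_27F[4:]
        _, found = trim_primer(SeqRecord("r", prefix + "ACGT"),
                               self.PRIMER_27F, maxdiffs=3)
        assert not found


class TestFixedTrim:
    def test_prefix_kept(self):
        rng = np.random.default_rng(0)
        read = SeqRecord("r", random_dna(rng, 300), "I" * 300)
        out = trim_to_length(read, 260)
        assert out.seq == read.seq[:260] and len(out.qual) == 260

    def test_short_read_unchanged(self):
        read = SeqRecord("r", "ACGT")
        assert trim_to_length(read, 10).seq == "ACGT"

    def test_single_base(self):
        assert trim_to_length(SeqRecord("r", "ACGT"), 1).seq == "A"


class TestOptimizeTrimLength:
    @staticmethod
    def _score_by_length(table):
        return lambda read: table[len(read.seq)]

    def test_peak_found_by_exhaustive_scan(self):
        reads = [SeqRecord("r", "A" * 100, "I" * 100)]
        clf = self._score_by_length({100: 0.2, 80: 0.5, 60: 0.9, 40: 0.7})
        best, trace = optimize_trim_length(reads, clf, step=20, min_len=40)
        assert best == 60
        assert trace == [(100, 0.2), (80, 0.5), (60, 0.9), (40, 0.7)]

    def test_monotone_confidence_keeps_full_length(self):
        reads = [SeqRecord("r", "A" * 100, "I" * 100)]
        clf = self._score_by_length({100: 0.9, 80: 0.8, 60: 0.6, 40: 0.1})
        best, _ = optimize_trim_length(reads, clf, step=20, min_len=40)
        assert best == 100

    def test_tie_goes_to_longer_length(self):
        reads = [SeqRecord("r", "A" * 100, "I" * 100)]
        clf = self._score_by_length({100: 0.8, 80: 0.8, 60: 0.5, 40: 0.5})
        best, _ = optimize_trim_length(reads, clf, step=20, min_len=40)
        assert best == 100

    def test_empty_read_list_is_an_error(self):
        with pytest.raises(ValueError):
            optimize_trim_length([], lambda r: 0.0)
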