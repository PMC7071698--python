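"""Turning paired-end reads into single reads: joining, merging, trimming.

Unmergeable read pairs (fragment longer than twice the read length) can still
be used whole by concatenation:

* direct joining — ``R1 + N*pad + revcomp(R2)``, keeping genomic orientation
  with an N spacer for the unsequenced middle;
* inside-out joining — ``revcomp(R2) + R1``, which needs no spacer and moves
  the error-prone read tails to the two ends of the product.

Overlapping pairs are instead merged with in-overlap error correction, taking
the higher-quality base at each disagreeing overlap position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Optional, Sequence

from .io_formats import (
    SeqRecord,
    char_to_phred,
    iupac_diffs,
    reverse_complement,
)

#: Default N spacer for direct joining. The true per-pair gap is unknown
#: without the amplicon length; a fixed short spacer follows common
#: read-joining practice and is configurable everywhere it is used.
DEFAULT_PAD_LEN = 8

#: Pad positions get phred 0 ("!") so they can never win a downstream
#: quality comparison.
PAD_QUAL = "!"

JoinMode = Literal["direct", "inside_out", "merged"]


@dataclass
class JoinedRead:
    id: str
    mode: JoinMode
    seq: str
    qual: str
    pad_len: int = 0

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"joined read {self.id!r}: seq/qual length mismatch")

    def to_record(self, lineage=None) -> SeqRecord:
        return SeqRecord(id=self.id, seq=self.seq, qual=self.qual, lineage=lineage)


@dataclass
class MergeResult:
    merged: Optional[JoinedRead]
    overlap_len: int
    mismatch_rate: float
    status: Literal["merged", "no_overlap", "too_many_mismatches"]


def direct_join(r1: SeqRecord, r2: SeqRecord, pad_len: int = DEFAULT_PAD_LEN) -> JoinedRead:
    """Concatenate R1, a pad of Ns, and the reverse complement of R2."""
    if pad_len < 0:
        raise ValueError("pad_len must be non-negative")
    q1 = r1.qual if r1.qual is not None else "I" * len(r1)
    q2 = r2.qual if r2.qual is not None else "I" * len(r2)
    return JoinedRead(
        id=r1.id,
        mode="direct",
        seq=r1.seq + "N" * pad_len + reverse_complement(r2.seq),
        qual=q1 + PAD_QUAL * pad_len + q2[::-1],
        pad_len=pad_len,
    )


def split_direct_join(joined: JoinedRead, len1: int) -> tuple[SeqRecord, SeqRecord]:
    """Invert :func:`direct_join` given the original R1 length."""
    if joined.mode != "direct":
        raise ValueError("can only split a direct-joined read")
    r1_seq, r1_q = joined.seq[:len1], joined.qual[:len1]
    tail = len1 + joined.pad_len
    r2_seq = reverse_complement(joined.seq[tail:])
    r2_q = joined.qual[tail:][::-1]
    return (
        SeqRecord(id=joined.id, seq=r1_seq, qual=r1_q),
        SeqRecord(id=joined.id, seq=r2_seq, qual=r2_q),
    )


def inside_out_join(r1: SeqRecord, r2: SeqRecord) -> JoinedRead:
    """Concatenate revcomp(R2) then R1; low-quality tails end up at both ends."""
    q1 = r1.qual if r1.qual is not None else "I" * len(r1)
    q2 = r2.qual if r2.qual is not None else "I" * len(r2)
    return JoinedRead(
        id=r1.id,
        mode="inside_out",
        seq=reverse_complement(r2.seq) + r1.seq,
        qual=q2[::-1] + q1,
        pad_len=0,
    )


def merge_pair(
    r1: SeqRecord,
    r2: SeqRecord,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.25,
) -> MergeResult:
    """Merge an overlapping pair, correcting in-overlap errors by quality.

    Candidate overlaps between R1's 3' end and revcomp(R2)'s 5' end are
    scanned from longest to shortest; the first whose mismatch rate within the
    overlap is at or below *max_mismatch_rate* is accepted. At each overlap
    position the base with the higher quality score wins (ties go to R1, the
    generally more accurate read) and the higher quality is recorded.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    rc2 = reverse_complement(r2.seq)
    q1 = r1.qual if r1.qual is not None else "I" * len(r1)
    q2r = (r2.qual if r2.qual is not None else "I" * len(r2))[::-1]
    max_ov = min(len(r1.seq), len(rc2))
    if max_ov < min_overlap:
        return MergeResult(None, 0, 0.0, "no_overlap")
    best_rate = 1.0
    best_ov = 0
    for ov in range(max_ov, min_overlap - 1, -1):
        a = r1.seq[len(r1.seq) - ov:]
        b = rc2[:ov]
        mism = sum(1 for x, y in zip(a, b) if x != y)
        rate = mism / ov
        if rate <= max_mismatch_rate:
            seq, qual = _merge_at(r1.seq, q1, rc2, q2r, ov)
            return MergeResult(
                JoinedRead(id=r1.id, mode="merged", seq=seq, qual=qual),
                ov,
                rate,
                "merged",
            )
        if rate < best_rate:
            best_rate, best_ov = rate, ov
    return MergeResult(None, best_ov, best_rate, "too_many_mismatches")


def _merge_at(
    s1: str, q1: str, rc2: str, q2r: str, ov: int
) -> tuple[str, str]:
    n1 = len(s1)
    head_s, head_q = s1[: n1 - ov], q1[: n1 - ov]
    tail_s, tail_q = rc2[ov:], q2r[ov:]
    mid_s = []
    mid_q = []
    for i in range(ov):
        b1, c1 = s1[n1 - ov + i], q1[n1 - ov + i]
        b2, c2 = rc2[i], q2r[i]
        if b1 == b2:
            mid_s.append(b1)
        else:
            mid_s.append(b2 if char_to_phred(c2) > char_to_phred(c1) else b1)
        mid_q.append(max(c1, c2, key=char_to_phred))
    return head_s + "".join(mid_s) + tail_s, head_q + "".join(mid_q) + tail_q


def trim_primer(
    read: SeqRecord, primer: str, maxdiffs: int = 3
) -> tuple[SeqRecord, bool]:
    """Remove the primer from the read's 5' start if it matches within *maxdiffs*.

    Primer positions are IUPAC codes; a read base matches when it is in the
    code's base set, except that N in the read never matches (counted as a
    difference). Returns the (possibly trimmed) read and a found flag.
    """
    primer = primer.upper()
    if not primer or len(primer) >= len(read.seq):
        raise ValueError("primer must be non-empty and shorter than the read")
    window = read.seq[: len(primer)]
    if iupac_diffs(primer, window) <= maxdiffs:
        qual = read.qual[len(primer):] if read.qual is not None else None
        return (
            SeqRecord(id=read.id, seq=read.seq[len(primer):], qual=qual,
                      lineage=read.lineage),
            True,
        )
    return read, False


def trim_to_length(read: SeqRecord, target_len: int) -> SeqRecord:
    """Keep the 5'-most *target_len* bases (whole read if already shorter)."""
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    if target_len >= len(read.seq):
        return read
    qual = read.qual[:target_len] if read.qual is not None else None
    return SeqRecord(id=read.id, seq=read.seq[:target_len], qual=qual,
                     lineage=read.lineage)


def optimize_trim_length(
    reads: Sequence[SeqRecord],
    classifier: Callable[[SeqRecord], float],
    step: int = 20,
    min_len: int = 60,
) -> tuple[int, list[tuple[int, float]]]:
    """Pick the fixed trim length maximising mean genus-level confidence.

    Starting from the full read length, candidate lengths L, L-step,
    L-2*step, ... >= *min_len* are each scored by the mean confidence the
    supplied classifier assigns to the trimmed reads; the best length is
    returned together with the full (length, score) trace. Ties go to the
    longer candidate so no information is discarded without a confidence
    gain.
    """
    if not reads:
        raise ValueError("no reads to optimise over")
    if step < 1:
        raise ValueError("step must be >= 1")
    full = max(len(r) for r in reads)
    if min_len > full:
        raise ValueError("min_len exceeds the read length")
    trace: list[tuple[int, float]] = []
    best_len, best_score = full, float("-inf")
    length = full
    while length >= min_len:
        score = sum(classifier(trim_to_length(r, length)) for r in reads) / len(reads)
        trace.append((length, score))
        if score > best_score:  # strict: earlier (longer) candidate wins ties
            best_len, best_score = length, score
        length -= step
    return best_len, trace
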