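"""Reference preparation: main-reference coordinates, amplicon extraction,
and rearrangement of references to match joined reads.

Many database sequences do not span both primer binding sites, so primer
sites cannot be found on them directly. The workflow instead picks one
*main reference* that contains a unique, complete binding site for each
primer, aligns every other reference to it, and converts reference base
positions into main-reference coordinates. Primer sites located once on the
main reference are then mapped onto each reference through its coordinate
list; a reference falling short of a primer site is padded with Ns up to the
primer's outer edge, rescuing sequences that would otherwise be unusable.
Amplicons in which real bases make up less than half the span are rejected.

Extracted amplicons can finally be *rearranged* into the same layout as
direct-joined or inside-out joined reads, so alignment-based classifiers see
reads and references in the same coordinate structure.

All positions are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from . import _align
from .io_formats import Lineage, SeqRecord, iupac_diffs, reverse_complement


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primers as printed 5'->3' (reverse on the minus strand)."""

    forward: str
    reverse: str
    maxdiffs: int = 3

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("both primers must be non-empty")
        if self.maxdiffs < 0:
            raise ValueError("maxdiffs must be >= 0")


@dataclass(frozen=True)
class PrimerSite:
    start: int  # 1-based inclusive on the main reference
    end: int
    strand: Literal["plus", "minus"]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("primer site start > end")


@dataclass
class CoordinateMap:
    """One main-reference coordinate per reference base, in reference order.

    Repeated coordinates mark reference insertions (the inserted base takes
    the coordinate of the previous aligned main-reference base); skipped
    coordinates mark main-reference bases absent from the reference. Bases
    left of the main reference's aligned span get coordinate 0.
    """

    ref_id: str
    coords: list[int]

    def __post_init__(self) -> None:
        if any(b < a for a, b in zip(self.coords, self.coords[1:])):
            raise ValueError(f"coordinate map for {self.ref_id!r} not monotone")


@dataclass
class Amplicon:
    ref_id: str
    seq: str
    ref_start: int  # 1-based inclusive span of the non-pad portion
    ref_end: int
    pad_left: int
    pad_right: int
    lineage: Optional[Lineage] = None

    def to_record(self) -> SeqRecord:
        return SeqRecord(id=self.ref_id, seq=self.seq, lineage=self.lineage)

    @property
    def non_pad_fraction(self) -> float:
        middle = self.seq[self.pad_left: len(self.seq) - self.pad_right or None]
        return sum(1 for b in middle if b != "N") / len(self.seq)


@dataclass
class Rejection:
    """An amplicon that could not be extracted; returned, never raised."""

    ref_id: str
    reason: str
    non_pad_fraction: float = 0.0


@dataclass
class RearrangedRef:
    ref_id: str
    mode: Literal["direct", "inside_out"]
    seq: str
    lineage: Optional[Lineage] = None

    def to_record(self) -> SeqRecord:
        return SeqRecord(id=self.ref_id, seq=self.seq, lineage=self.lineage)


def _site_matches(seq: str, primer: str, maxdiffs: int) -> list[tuple[int, int]]:
    """All (1-based start, diffs) windows matching *primer* within *maxdiffs*."""
    out = []
    for i in range(len(seq) - len(primer) + 1):
        d = iupac_diffs(primer, seq[i: i + len(primer)])
        if d <= maxdiffs:
            out.append((i + 1, d))
    return out


def select_main_reference(refs: Sequence[SeqRecord], primers: PrimerPair) -> str:
    """Pick the reference with unique sites for both primers and the longest
    flanks outside them (sum of the 5' and 3' segments); ties by id."""
    if not refs:
        raise ValueError("no references supplied")
    rev_rc = reverse_complement(primers.reverse)
    best: Optional[tuple[int, str]] = None
    for ref in refs:
        fwd = _site_matches(ref.seq, primers.forward, primers.maxdiffs)
        rev = _site_matches(ref.seq, rev_rc, primers.maxdiffs)
        if len(fwd) != 1 or len(rev) != 1:
            continue
        f_start = fwd[0][0]
        r_start = rev[0][0]
        r_end = r_start + len(rev_rc) - 1
        if r_start <= f_start + len(primers.forward) - 1:
            continue  # reverse site must lie 3' of the forward site
        flank = (f_start - 1) + (len(ref.seq) - r_end)
        key = (-flank, ref.id)
        if best is None or key < best:
            best = key
            best_id = ref.id
    if best is None:
        raise ValueError(
            "no reference carries a unique binding site for both primers"
        )
    return best_id


def locate_primer_sites(
    main_ref: SeqRecord, primers: PrimerPair
) -> tuple[PrimerSite, PrimerSite]:
    """Best primer sites on the main reference (fewest diffs; forward leftmost,
    reverse rightmost and 3' of the forward site)."""
    fwd = _site_matches(main_ref.seq, primers.forward, primers.maxdiffs)
    if not fwd:
        raise ValueError("forward primer site not found within maxdiffs")
    f_start, _ = min(fwd, key=lambda sd: (sd[1], sd[0]))
    f_end = f_start + len(primers.forward) - 1
    rev_rc = reverse_complement(primers.reverse)
    rev = [
        (s, d)
        for s, d in _site_matches(main_ref.seq, rev_rc, primers.maxdiffs)
        if s > f_end
    ]
    if not rev:
        raise ValueError("reverse primer site not found within maxdiffs")
    r_start, _ = min(rev, key=lambda sd: (sd[1], -sd[0]))
    return (
        PrimerSite(f_start, f_end, "plus"),
        PrimerSite(r_start, r_start + len(rev_rc) - 1, "minus"),
    )


def build_coordinate_map(ref: SeqRecord, main_ref: SeqRecord) -> CoordinateMap:
    """Map each reference base to a main-reference coordinate via semi-global
    alignment. Insertions repeat the previous coordinate; deleted main bases
    leave skipped coordinates."""
    aln = _align.best_alignment(main_ref.seq, ref.seq, "semiglobal")
    main_row, ref_row = _align.gapped_rows(aln)
    coords: list[int] = []
    main_pos = 0
    for m, r in zip(main_row, ref_row):
        if m != _align.GAP:
            main_pos += 1
        if r != _align.GAP:
            # when m is a gap (insertion) the counter still holds the
            # previous aligned main base, giving the repeated coordinate
            coords.append(main_pos)
    return CoordinateMap(ref_id=ref.id, coords=coords)


def extract_amplicon(
    ref: SeqRecord,
    cmap: CoordinateMap,
    sites: tuple[PrimerSite, PrimerSite],
) -> Amplicon | Rejection:
    """Extract the primer-to-primer amplicon from a reference via its
    coordinate map, N-padding any shortfall at either primer's outer edge.

    Forward edge: the first reference base (5'->3') whose coordinate exceeds
    the forward site start ``s`` is found, then ``coordinate - s`` literal
    bases are back-traced on the reference; running off the 5' end pads the
    shortfall with Ns. Reverse edge: symmetric from the 3' end against the
    reverse site end ``e``, extending ``e - coordinate`` bases rightward.
    The amplicon is rejected (not an error) when real bases make up less
    than half of its span.
    """
    if cmap.ref_id != ref.id or len(cmap.coords) != len(ref.seq):
        raise ValueError("coordinate map does not match the reference")
    fwd, rev = sites
    s, e = fwd.start, rev.end
    n = len(ref.seq)
    coords = cmap.coords

    i_fwd = next((i for i in range(n) if coords[i] > s), None)
    if i_fwd is None:
        return Rejection(ref.id, "reference lies entirely 5' of the amplicon")
    back = coords[i_fwd] - s
    start_pos = (i_fwd + 1) - back  # 1-based; may run off the 5' end
    pad_left = max(0, 1 - start_pos)
    ref_start = max(1, start_pos)

    i_rev = next((i for i in range(n - 1, -1, -1) if coords[i] < e), None)
    if i_rev is None:
        return Rejection(ref.id, "reference lies entirely 3' of the amplicon")
    ext = e - coords[i_rev]
    end_pos = (i_rev + 1) + ext
    pad_right = max(0, end_pos - n)
    ref_end = min(n, end_pos)

    if ref_start > ref_end:
        return Rejection(ref.id, "empty amplicon span")
    core = ref.seq[ref_start - 1: ref_end]
    seq = "N" * pad_left + core + "N" * pad_right
    non_pad = sum(1 for b in core if b != "N")
    if non_pad < 0.5 * len(seq):
        return Rejection(
            ref.id,
            "real bases cover less than half of the amplicon",
            non_pad / len(seq),
        )
    return Amplicon(
        ref_id=ref.id,
        seq=seq,
        ref_start=ref_start,
        ref_end=ref_end,
        pad_left=pad_left,
        pad_right=pad_right,
        lineage=ref.lineage,
    )


def rearrange_reference(
    amplicon: Amplicon, len1: int, len2: int, mode: Literal["direct", "inside_out"]
) -> RearrangedRef:
    """Reshape an amplicon into the layout of a joined read.

    direct: first *len1* bases + N spacer + last *len2* bases (the whole
    amplicon, unchanged, when it is no longer than len1+len2).
    inside_out: last *len2* bases followed by first *len1* bases.
    """
    if len1 < 1 or len2 < 1:
        raise ValueError("read lengths must be >= 1")
    seq = amplicon.seq
    L = len(seq)
    if mode == "direct":
        if L <= len1 + len2:
            out = seq
        else:
            out = seq[:len1] + "N" * (L - len1 - len2) + seq[L - len2:]
    elif mode == "inside_out":
        out = seq[max(0, L - len2):] + seq[:len1]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return RearrangedRef(
        ref_id=amplicon.ref_id, mode=mode, seq=out, lineage=amplicon.lineage
    )
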