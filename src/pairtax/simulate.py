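"""Synthetic data: taxonomically structured reference databases, paired-end
reads with position-dependent error profiles, and a worked coordinate-mapping
fixture.

The generator stands in for curated 16S benchmark collections and for
empirical read simulators. A reference database is grown from one random
ancestral sequence: genus ancestors diverge from it at ``genus_divergence``
substitutions per site, members of a genus diverge from their genus ancestor
at ``within_divergence``, and the upper ranks (family through phylum) are
assigned by deterministic grouping of genera so that full six-rank lineages
exist. Reads are drawn from the two ends of an amplicon with per-position
substitution probabilities that rise toward the read tail, second read worse
than first, the dominant Illumina error mode; indels are not simulated.
Quality characters are emitted from the local error rate via the phred
relation, so downstream quality-aware merging sees self-consistent data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Lineage, SeqRecord, reverse_complement, phred_to_char
from .reference_prep import Amplicon, PrimerPair

_BASES = np.array(list("ACGT"))


@dataclass
class ErrorProfile:
    """Per-position substitution probabilities for the two reads of a pair."""

    name: str
    sub_rate1: np.ndarray
    sub_rate2: np.ndarray
    read_len: int

    def __post_init__(self) -> None:
        for arr in (self.sub_rate1, self.sub_rate2):
            if len(arr) != self.read_len:
                raise ValueError("rate array length != read_len")
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("rates must lie in [0, 1]")

    @property
    def mean_rate(self) -> float:
        return float(np.concatenate([self.sub_rate1, self.sub_rate2]).mean())


def miseq_300() -> ErrorProfile:
    """MiSeq-like 2 x 300 bp: errors ramp steeply toward the tail, read 2
    roughly twice as error-prone as read 1."""
    n = 300
    ramp = np.linspace(0.0, 1.0, n) ** 2
    return ErrorProfile(
        name="miseq300",
        sub_rate1=0.001 + 0.012 * ramp,
        sub_rate2=0.002 + 0.028 * ramp,
        read_len=n,
    )


def hiseq_250() -> ErrorProfile:
    """HiSeq-like 2 x 250 bp: flatter and lower overall error than MiSeq."""
    n = 250
    ramp = np.linspace(0.0, 1.0, n)
    return ErrorProfile(
        name="hiseq250",
        sub_rate1=0.0005 + 0.002 * ramp,
        sub_rate2=0.001 + 0.004 * ramp,
        read_len=n,
    )


def error_free(read_len: int = 300) -> ErrorProfile:
    zero = np.zeros(read_len)
    return ErrorProfile(name="errorfree", sub_rate1=zero, sub_rate2=zero.copy(),
                        read_len=read_len)


PROFILES = {"miseq300": miseq_300, "hiseq250": hiseq_250}


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def generate_reference_db(
    n_genera: int = 20,
    seqs_per_genus: int = 3,
    seq_len: int = 800,
    genus_divergence: float = 0.10,
    within_divergence: float = 0.02,
    seed: int = 0,
) -> list[SeqRecord]:
    """A lineage-annotated synthetic marker-gene reference database."""
    if min(n_genera, seqs_per_genus, seq_len) < 1:
        raise ValueError("counts must be >= 1")
    if not (0 < genus_divergence < 1 and 0 < within_divergence < 1):
        raise ValueError("divergences must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    ancestor = "".join(rng.choice(_BASES, size=seq_len))
    records = []
    for g in range(n_genera):
        genus_anc = _mutate(ancestor, genus_divergence, rng)
        lineage = Lineage((
            ("d", "Bacteria"),
            ("p", f"p{g // 16 + 1}"),
            ("c", f"c{g // 8 + 1}"),
            ("o", f"o{g // 4 + 1}"),
            ("f", f"f{g // 2 + 1}"),
            ("g", f"g{g + 1}"),
        ))
        for s in range(seqs_per_genus):
            records.append(
                SeqRecord(
                    id=f"G{g + 1}S{s + 1}",
                    seq=_mutate(genus_anc, within_divergence, rng),
                    lineage=lineage,
                )
            )
    return records


def simulate_pe_reads(
    amplicon: Amplicon | SeqRecord,
    profile: ErrorProfile,
    n_pairs: int = 3,
    seed: int = 0,
) -> list[tuple[SeqRecord, SeqRecord]]:
    """Simulate paired-end reads from the two ends of an amplicon.

    R1 is the 5' prefix of ``read_len`` bases; R2 is the reverse complement
    of the 3' suffix. Substitutions are drawn independently per position from
    the profile (N pad positions are never substituted) and the emitted
    quality character encodes each position's error rate.
    """
    seq = amplicon.seq.upper()
    aid = getattr(amplicon, "ref_id", None) or getattr(amplicon, "id")
    n = profile.read_len
    if len(seq) < n:
        raise ValueError(f"amplicon {aid!r} shorter than the read length")
    rng = np.random.default_rng(seed)
    r1_t = seq[:n]
    r2_t = reverse_complement(seq[-n:])
    q1 = _qual_string(profile.sub_rate1)
    q2 = _qual_string(profile.sub_rate2)
    pairs = []
    for i in range(n_pairs):
        r1 = _sequencing_errors(r1_t, profile.sub_rate1, rng)
        r2 = _sequencing_errors(r2_t, profile.sub_rate2, rng)
        pairs.append((
            SeqRecord(id=f"{aid}/{i + 1}", seq=r1, qual=q1,
                      lineage=getattr(amplicon, "lineage", None)),
            SeqRecord(id=f"{aid}/{i + 1}", seq=r2, qual=q2,
                      lineage=getattr(amplicon, "lineage", None)),
        ))
    return pairs


def _sequencing_errors(seq: str, rates: np.ndarray, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hit = (rng.random(len(arr)) < rates) & (arr != "N")
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _qual_string(rates: np.ndarray) -> str:
    with np.errstate(divide="ignore"):
        q = np.where(rates > 0, -10.0 * np.log10(np.maximum(rates, 1e-9)), 40.0)
    return "".join(phred_to_char(int(round(min(40.0, max(2.0, v))))) for v in q)


def worked_amplicon_example(seed: int = 0):
    """A compact main-reference / partial-reference scenario exercising
    N-padded amplicon extraction through coordinate mapping.

    The main reference (80 bp) carries the forward primer at positions 10-17
    and the reverse primer's binding site at 31-36. The partial reference
    (101 bp) starts two bases inside the forward site (first mapped
    coordinate 12), carries one inserted base after the base at coordinate
    14 (hence the repeat "14, 14"), a 32-base insertion block, and lacks the
    main-reference base at coordinate 36, so its last in-band coordinate is
    35 at reference position 57. Extraction must therefore pad two Ns on the
    left (the amplicon begins "NNAGTCTTGA") and extend one base to reference
    position 58 (the amplicon ends "CGAGGTAA").

    The coordinate map is part of the scenario and is returned explicitly:
    the reference packs more inserted bases into the primer-to-primer window
    than an affine-gap aligner would bridge, which is exactly the situation
    the map representation exists to describe. Filler segments are drawn
    from *seed*; the builder re-draws until the planted primer sites are the
    unique exact matches. Returns (main_ref, partial_ref, primers, cmap).
    """
    from .reference_prep import CoordinateMap, locate_primer_sites

    forward = "CAAGTTTG"          # main 10..17
    rev_site = "AGGTAC"           # main 31..36 = revcomp(reverse primer)
    reverse = reverse_complement(rev_site)
    primers = PrimerPair(forward=forward, reverse=reverse, maxdiffs=3)
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        f1 = "".join(rng.choice(_BASES, size=9))        # main 1..9
        f2 = "A" + "".join(rng.choice(_BASES, size=10))  # main 18..28
        f3 = "A" + "".join(rng.choice(_BASES, size=43))  # main 37..80
        main_seq = f1 + forward + f2 + "CG" + rev_site + f3
        assert len(main_seq) == 80
        block = "".join(rng.choice(_BASES, size=32))
        ref_seq = (
            main_seq[11:14]      # coords 12..14
            + "C"                # inserted base -> repeated coordinate 14
            + main_seq[14:20]    # coords 15..20
            + block              # insertion block, coordinate 20 repeated
            + main_seq[20:35]    # coords 21..35 (position 57 = coord 35)
            + main_seq[36:80]    # coords 37..80 (the base at 36 is absent)
        )
        if main_seq.count(forward) != 1 or main_seq.count(rev_site) != 1:
            continue
        main_ref = SeqRecord(id="main", seq=main_seq)
        partial = SeqRecord(id="partial", seq=ref_seq)
        try:
            fwd_site, rv_site = locate_primer_sites(main_ref, primers)
        except ValueError:
            continue
        if (fwd_site.start, fwd_site.end) != (10, 17):
            continue
        if (rv_site.start, rv_site.end) != (31, 36):
            continue
        coords = (
            list(range(12, 15)) + [14] + list(range(15, 21)) + [20] * 32
            + list(range(21, 36)) + list(range(37, 81))
        )
        cmap = CoordinateMap(ref_id="partial", coords=coords)
        assert len(coords) == len(ref_seq)
        return main_ref, partial, primers, cmap
    raise RuntimeError("could not realise the worked example fixture")
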