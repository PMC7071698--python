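"""Sequence records, taxonomy lineages, and FASTA/FASTQ input/output.

Every sequence handled by the package — reads, references, amplicons — is a
:class:`SeqRecord` carrying an id, a DNA string over the IUPAC alphabet, an
optional phred+33 quality string of equal length, and an optional
:class:`Lineage`. Lineages use the six canonical prokaryotic ranks
domain/phylum/class/order/family/genus abbreviated ``d,p,c,o,f,g`` and may
stop early at any rank, but may not skip ranks: a genus without a family is a
malformed annotation and is rejected at parse time, because hierarchical
scoring needs well-formed per-rank lookups.

Two header taxonomy dialects are recognised:

* SINTAX style:     ``>id;tax=d:Bacteria,p:Proteobacteria,...,g:Escherichia;``
* Greengenes style: ``>id d__Bacteria;p__Proteobacteria;...;g__Escherichia``

Both are normalised to :class:`Lineage`; emitted headers use the first style.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

RANKS = ("d", "p", "c", "o", "f", "g")
RANK_NAMES = {
    "d": "domain",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
}

IUPAC_CODES = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
IUPAC_ALPHABET = frozenset(IUPAC_CODES)

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMP_TABLE = str.maketrans(
    "".join(_COMPLEMENT) + "".join(_COMPLEMENT).lower(),
    "".join(_COMPLEMENT.values()) + "".join(_COMPLEMENT.values()).lower(),
)


class RecordError(ValueError):
    """A malformed sequence record or lineage annotation, naming the record."""


@dataclass(frozen=True)
class Lineage:
    """An ordered, gap-free prefix of the six-rank taxonomy path."""

    ranks: tuple[tuple[str, str], ...]  # ((rank_key, name), ...) in d..g order

    def __post_init__(self) -> None:
        keys = [k for k, _ in self.ranks]
        if keys != list(RANKS[: len(keys)]):
            raise RecordError(
                f"lineage ranks {keys} are not a gap-free prefix of {list(RANKS)}"
            )
        for _, name in self.ranks:
            if not name:
                raise RecordError("empty rank name in lineage")

    @classmethod
    def from_dict(cls, d: dict[str, str]) -> "Lineage":
        return cls(tuple((k, d[k]) for k in RANKS if k in d))

    def get(self, rank: str) -> Optional[str]:
        for k, name in self.ranks:
            if k == rank:
                return name
        return None

    def truncate(self, depth: int) -> "Lineage":
        """Keep the first *depth* ranks."""
        return Lineage(self.ranks[:depth])

    @property
    def depth(self) -> int:
        return len(self.ranks)

    def __str__(self) -> str:
        return ",".join(f"{k}:{v}" for k, v in self.ranks)


_TAX_FIELD = re.compile(r"tax=([^;]*)")
_GG_FIELD = re.compile(r"^([dpcofgs])__(.*)$")


def parse_lineage(header: str) -> Optional[Lineage]:
    """Extract a lineage from a FASTA/FASTQ header, or None if unannotated.

    Raises :class:`RecordError` for gapped or malformed annotations.
    """
    m = _TAX_FIELD.search(header)
    if m:
        d: dict[str, str] = {}
        for part in m.group(1).split(","):
            part = part.strip()
            if not part:
                continue
            if ":" not in part:
                raise RecordError(f"malformed tax= field entry {part!r} in {header!r}")
            key, name = part.split(":", 1)
            if key == "s":  # species, below the ranks scored here
                continue
            if key not in RANKS:
                raise RecordError(f"unknown rank key {key!r} in {header!r}")
            d[key] = name.strip()
        return Lineage.from_dict(_check_gap_free(d, header))
    # Greengenes style: whitespace-separated token list of x__Name
    tokens = [t for chunk in header.split() for t in chunk.split(";") if t]
    d = {}
    seen_gg = False
    for tok in tokens:
        g = _GG_FIELD.match(tok)
        if g:
            seen_gg = True
            key, name = g.group(1), g.group(2).strip()
            if key == "s" or not name:
                continue
            d[key] = name
    if seen_gg and d:
        return Lineage.from_dict(_check_gap_free(d, header))
    return None


def _check_gap_free(d: dict[str, str], header: str) -> dict[str, str]:
    present = [k for k in RANKS if k in d]
    if present != list(RANKS[: len(present)]):
        raise RecordError(
            f"gapped lineage in {header!r}: ranks {present} skip a higher rank"
        )
    return d


def lineage_from_string(s: str) -> Optional[Lineage]:
    """Parse a bare ``d:Name,p:Name,...`` lineage string (as written in TSV
    outputs); empty input gives None."""
    s = s.strip()
    if not s:
        return None
    d: dict[str, str] = {}
    for part in s.split(","):
        key, name = part.split(":", 1)
        d[key.strip()] = name.strip()
    return Lineage.from_dict(_check_gap_free(d, s))


def format_lineage(lineage: Lineage) -> str:
    return f"tax={','.join(f'{k}:{v}' for k, v in lineage.ranks)};"


@dataclass
class SeqRecord:
    """A DNA sequence with optional phred+33 quality and optional lineage."""

    id: str
    seq: str
    qual: Optional[str] = None
    lineage: Optional[Lineage] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise RecordError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq.upper()) - IUPAC_ALPHABET
        if bad:
            raise RecordError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise RecordError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string, mapping IUPAC codes to their complements.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    bad = set(seq.upper()) - IUPAC_ALPHABET
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq.translate(_COMP_TABLE)[::-1]


def phred_to_char(q: int) -> str:
    return chr(max(0, min(93, int(q))) + 33)


def char_to_phred(c: str) -> int:
    return ord(c) - 33


def iupac_match(code: str, base: str) -> bool:
    """Does *base* (a read base) satisfy IUPAC *code* (a primer position)?

    N in the read matches nothing: an unknown base cannot be credited as a
    primer match.
    """
    if base == "N":
        return False
    return base in IUPAC_CODES[code]


def iupac_diffs(primer: str, window: str) -> int:
    """Number of primer positions not satisfied by the aligned read window."""
    return sum(
        0 if iupac_match(p, b) else 1 for p, b in zip(primer.upper(), window.upper())
    )


def read_records(path: str | Path, format: str) -> list[SeqRecord]:
    """Read a FASTA or FASTQ file into a list of :class:`SeqRecord`.

    Lineages are parsed from headers carrying a ``tax=`` or Greengenes-style
    annotation; a gapped annotation raises :class:`RecordError` naming the
    record.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    if format == "fasta":
        with open(path) as fh:
            for header, seq in SimpleFastaParser(fh):
                records.append(_make_record(header, seq, None))
    elif format == "fastq":
        with open(path) as fh:
            try:
                entries = list(FastqGeneralIterator(fh))
            except ValueError as e:
                raise RecordError(f"malformed FASTQ in {path}: {e}") from e
        for header, seq, qual in entries:
            if len(qual) != len(seq):
                rid = header.split()[0] if header.split() else header
                raise RecordError(
                    f"record {rid!r}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            records.append(_make_record(header, seq, qual))
    else:
        raise ValueError(f"unknown format {format!r}")
    return records


def _make_record(header: str, seq: str, qual: Optional[str]) -> SeqRecord:
    rid = header.split(";")[0].split()[0] if header.strip() else header
    try:
        lineage = parse_lineage(header)
    except RecordError as e:
        raise RecordError(f"record {rid!r}: {e}") from e
    return SeqRecord(id=rid, seq=seq.upper(), qual=qual, lineage=lineage)


def write_records(
    records: Iterable[SeqRecord], path: str | Path, format: str
) -> None:
    """Write records to FASTA or FASTQ; round-trips id, seq, qual, lineage."""
    records = list(records)
    path = Path(path)
    if format == "fastq":
        missing = [r.id for r in records if r.qual is None]
        if missing:
            raise ValueError(
                f"FASTQ output requested but records lack quality: {missing[:5]}"
            )
    elif format != "fasta":
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w") as fh:
        for r in records:
            header = r.id
            if r.lineage is not None:
                header = f"{r.id};{format_lineage(r.lineage)}"
            if format == "fasta":
                fh.write(f">{header}\n{r.seq}\n")
            else:
                fh.write(f"@{header}\n{r.seq}\n+\n{r.qual}\n")
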