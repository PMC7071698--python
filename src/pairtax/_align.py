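"""Shared pairwise-alignment machinery (Biopython ``PairwiseAligner``).

All alignment in the package goes through here so that one scoring scheme is
used consistently: match +1, mismatch -2, gap open -4, gap extend -1 for
semi-global alignments with free end gaps (coordinate maps, identities,
global top-hit), and match +2, mismatch -3, gap open -5, gap extend -2 for
local top-hit search. N is a universal mismatch: it never scores as a match
against anything, including another N, so pad characters are
information-free.

Two identity conventions are derived from the same semi-global alignment:

* ``identity_semiglobal`` — matching columns over the mutual overlap
  (terminal-overhang columns where one sequence has not started or has
  already ended are excluded). Used for amplicon-vs-amplicon identities.
* ``identity_query_global`` — matching columns over every column touched by
  the query span, so query bases that cannot be placed on the reference
  (e.g. the misplaced half of an inside-out read against an unrearranged
  amplicon) dilute the identity instead of hiding in a free overhang. This
  emulates a query-must-align-full-length database search.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

ALPHABET = "ACGTRYSWKMBDHVN"

GAP = "-"


def _matrix(match: float, mismatch: float):
    m = substitution_matrices.Array(ALPHABET, dims=2)
    for x in ALPHABET:
        for y in ALPHABET:
            m[x, y] = match if (x == y and x != "N") else mismatch
    return m


@lru_cache(maxsize=None)
def get_aligner(kind: str) -> PairwiseAligner:
    """A configured aligner; kinds: ``semiglobal``, ``local``."""
    a = PairwiseAligner()
    if kind == "local":
        a.mode = "local"
        a.substitution_matrix = _matrix(2.0, -3.0)
        a.open_gap_score = -5.0
        a.extend_gap_score = -2.0
        return a
    if kind != "semiglobal":
        raise ValueError(f"unknown aligner kind {kind!r}")
    a.mode = "global"
    a.substitution_matrix = _matrix(1.0, -2.0)
    a.open_gap_score = -4.0
    a.extend_gap_score = -1.0
    # free end gaps on both rows; Biopython >=1.88 renamed the attributes
    try:
        a.end_insertion_score = 0.0
        a.end_deletion_score = 0.0
    except AttributeError:  # pragma: no cover - older biopython
        a.target_end_gap_score = 0.0
        a.query_end_gap_score = 0.0
    return a


def best_alignment(target: str, query: str, kind: str):
    """The first optimal alignment of *query* against *target* (deterministic)."""
    return get_aligner(kind).align(target.upper(), query.upper())[0]


def gapped_rows(alignment) -> tuple[str, str]:
    return str(alignment[0]), str(alignment[1])


def _span(row: str) -> tuple[int, int]:
    """First and one-past-last non-gap column of a gapped row."""
    first = next(i for i, c in enumerate(row) if c != GAP)
    last = len(row) - next(i for i, c in enumerate(reversed(row)) if c != GAP)
    return first, last


def _column_identity(a_row: str, b_row: str, start: int, stop: int) -> float:
    """Percent of informative columns in [start, stop) that match.

    A column where both rows carry N (pad aligned to pad) is uninformative
    and excluded entirely; an N against a real base or a gap is a mismatched
    column like any other.
    """
    matches = total = 0
    for i in range(start, stop):
        x, y = a_row[i], b_row[i]
        if x == "N" and y == "N":
            continue
        total += 1
        if x == y and x != GAP:
            matches += 1
    return 100.0 * matches / total if total else 0.0


def identity_semiglobal(a: str, b: str) -> float:
    """Percent identity (0-100) over the mutual overlap of a semi-global alignment."""
    aln = best_alignment(a, b, "semiglobal")
    ra, rb = gapped_rows(aln)
    a0, a1 = _span(ra)
    b0, b1 = _span(rb)
    start, stop = max(a0, b0), min(a1, b1)
    if stop <= start:
        return 0.0
    return _column_identity(ra, rb, start, stop)


def identity_query_global(ref: str, query: str) -> float:
    """Percent identity (0-100) over the query's full aligned span."""
    aln = best_alignment(ref, query, "semiglobal")
    rr, rq = gapped_rows(aln)
    q0, q1 = _span(rq)
    if q1 <= q0:
        return 0.0
    return _column_identity(rr, rq, q0, q1)
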