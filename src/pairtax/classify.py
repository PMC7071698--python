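"""Built-in taxonomy classifiers: global top-hit, local top-hit, and a
k-mer naive-Bayes word-counting classifier with bootstrap confidence.

These are deliberately simplified stand-ins for the four classifier families
commonly used on 16S amplicons (alignment-based top-hit search by global or
local alignment, and word-counting classifiers with bootstrap confidence at
50%/80% cutoffs). They reproduce the behaviours that matter for read joining
and reference rearrangement — a global top-hit search cannot place an
inside-out read on an unrearranged amplicon, a local one silently drops half
of it, a word-counting classifier is indifferent to base order — without
cloning any external tool's exact scoring.

The global top-hit search computes identity over the query's full span and
reports no hit below a minimum identity (default 80%), the way a database
search with an identity cutoff behaves; a query whose halves are in the
wrong order therefore goes unclassified rather than matching half-way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._align import best_alignment, identity_query_global
from .io_formats import Lineage, SeqRecord


@dataclass
class TaxonomyPrediction:
    query_id: str
    predicted: Optional[Lineage]  # None or truncated when below cutoff
    confidence: Optional[dict[str, float]] = None  # rank key -> fraction
    top_hit_id: Optional[str] = None
    top_hit_identity: Optional[float] = None  # percent

    @property
    def depth(self) -> int:
        return self.predicted.depth if self.predicted is not None else 0


def _require_lineages(refs: Sequence[SeqRecord]) -> None:
    if not refs:
        raise ValueError("no reference sequences")
    missing = [r.id for r in refs if r.lineage is None]
    if missing:
        raise ValueError(f"references without lineage: {missing[:5]}")


def classify_tophit_global(
    query: SeqRecord,
    refs: Sequence[SeqRecord],
    min_identity: float = 80.0,
) -> TaxonomyPrediction:
    """Predict the lineage of the best global-alignment hit.

    Identity is matches over the query's full aligned span (percent); ties
    go to the lexicographically smallest reference id. Below *min_identity*
    the query is left unclassified (empty prediction, identity recorded).
    """
    _require_lineages(refs)
    best_id, best_ident = None, -1.0
    for ref in sorted(refs, key=lambda r: r.id):
        ident = identity_query_global(ref.seq, query.seq)
        if ident > best_ident:
            best_id, best_ident = ref.id, ident
    if best_ident < min_identity:
        return TaxonomyPrediction(
            query_id=query.id, predicted=None,
            top_hit_id=best_id, top_hit_identity=max(best_ident, 0.0),
        )
    lineage = next(r.lineage for r in refs if r.id == best_id)
    return TaxonomyPrediction(
        query_id=query.id, predicted=lineage,
        top_hit_id=best_id, top_hit_identity=best_ident,
    )


def best_local_hit(
    query: SeqRecord, refs: Sequence[SeqRecord]
) -> tuple[str, float, tuple[int, int]]:
    """Best local alignment (ref_id, score, query span) across references.

    The query span is the half-open [start, stop) interval of query bases
    covered by the winning local alignment — useful for seeing that only one
    half of an inside-out read is used against unrearranged references.
    """
    best = None
    for ref in sorted(refs, key=lambda r: r.id):
        aln = best_alignment(ref.seq, query.seq, "local")
        if best is None or aln.score > best[1]:
            qa = aln.aligned[1]
            span = (int(qa[0][0]), int(qa[-1][1])) if len(qa) else (0, 0)
            best = (ref.id, float(aln.score), span)
    return best


def classify_tophit_local(
    query: SeqRecord, refs: Sequence[SeqRecord]
) -> TaxonomyPrediction:
    """Predict the lineage of the best local-alignment (Smith-Waterman) hit."""
    _require_lineages(refs)
    ref_id, score, span = best_local_hit(query, refs)
    if score <= 0:
        return TaxonomyPrediction(query_id=query.id, predicted=None,
                                  top_hit_id=None, top_hit_identity=0.0)
    lineage = next(r.lineage for r in refs if r.id == ref_id)
    cov = span[1] - span[0]
    return TaxonomyPrediction(
        query_id=query.id, predicted=lineage, top_hit_id=ref_id,
        top_hit_identity=100.0 * cov / len(query.seq) if query.seq else None,
    )


def _kmers(seq: str, k: int) -> list[str]:
    """Unique k-mers over A,C,G,T only; any window touching an ambiguous base
    (including pad Ns) contributes nothing."""
    out = set()
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        w = seq[i: i + k]
        if all(c in "ACGT" for c in w):
            out.add(w)
    return sorted(out)


class WordCountModel:
    """Per-genus k-mer presence model with add-one smoothing.

    References are grouped by their lineage truncated at genus; the
    conditional probability of a k-mer given a genus is
    (number of genus references containing it + 1) / (genus size + 2).
    """

    def __init__(self, refs: Sequence[SeqRecord], k: int = 8):
        if k < 4:
            raise ValueError("k must be >= 4")
        _require_lineages(refs)
        self.k = k
        groups: dict[str, list[SeqRecord]] = {}
        for r in refs:
            groups.setdefault(str(r.lineage), []).append(r)
        self.genus_keys = sorted(groups)
        self.lineages = {key: groups[key][0].lineage for key in self.genus_keys}
        self._df: list[dict[str, int]] = []
        self._n: list[int] = []
        for key in self.genus_keys:
            df: dict[str, int] = {}
            for r in groups[key]:
                for w in _kmers(r.seq, k):
                    df[w] = df.get(w, 0) + 1
            self._df.append(df)
            self._n.append(len(groups[key]))

    def log_likelihood_matrix(self, kmers: Sequence[str]) -> np.ndarray:
        """(n_genera, n_kmers) matrix of log P(kmer | genus)."""
        G, U = len(self.genus_keys), len(kmers)
        out = np.empty((G, U))
        for g in range(G):
            df, n = self._df[g], self._n[g]
            out[g] = [np.log((df.get(w, 0) + 1) / (n + 2)) for w in kmers]
        return out


def classify_wordcount(
    query: SeqRecord,
    refs: Sequence[SeqRecord] | WordCountModel,
    k: int = 8,
    n_bootstrap: int = 100,
    subsample_frac: float = 0.125,
    cutoff: float = 0.5,
    seed: int = 0,
) -> TaxonomyPrediction:
    """Naive-Bayes genus assignment with bootstrap per-rank confidence.

    The genus posterior uses all of the query's k-mers; confidence at each
    rank is the fraction of *n_bootstrap* subsamples (each drawing
    ``subsample_frac`` of the query's k-mers, with replacement) whose winning
    genus lineage carries the same name at that rank. The reported lineage is
    truncated at the deepest rank whose confidence reaches *cutoff*. A model
    can be prebuilt with :class:`WordCountModel` and reused across queries.
    """
    model = refs if isinstance(refs, WordCountModel) else WordCountModel(refs, k)
    kmers = _kmers(query.seq, model.k)
    if not kmers:
        return TaxonomyPrediction(query_id=query.id, predicted=None,
                                  confidence={})
    ll = model.log_likelihood_matrix(kmers)
    full_scores = ll.sum(axis=1)
    best_g = _argmax_tiebreak(full_scores, model.genus_keys)
    predicted_full = model.lineages[model.genus_keys[best_g]]

    rng = np.random.default_rng(seed)
    n_draw = max(1, int(round(subsample_frac * len(kmers))))
    agree = np.zeros(predicted_full.depth)
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(kmers), size=n_draw)
        scores = ll[:, idx].sum(axis=1)
        win = model.lineages[model.genus_keys[_argmax_tiebreak(scores, model.genus_keys)]]
        for depth, (rank, name) in enumerate(predicted_full.ranks):
            if win.get(rank) == name:
                agree[depth] += 1
            else:
                break
    conf_values = agree / n_bootstrap
    confidence = {rank: float(conf_values[i])
                  for i, (rank, _) in enumerate(predicted_full.ranks)}
    depth = 0
    for i, (rank, _) in enumerate(predicted_full.ranks):
        if conf_values[i] >= cutoff:
            depth = i + 1
        else:
            break
    predicted = predicted_full.truncate(depth) if depth else None
    return TaxonomyPrediction(
        query_id=query.id, predicted=predicted, confidence=confidence,
    )


def _argmax_tiebreak(scores: np.ndarray, keys: Sequence[str]) -> int:
    """Index of the maximal score; exact ties go to the smallest genus key."""
    best = np.flatnonzero(scores == scores.max())
    if len(best) == 1:
        return int(best[0])
    return int(min(best, key=lambda i: keys[i]))
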