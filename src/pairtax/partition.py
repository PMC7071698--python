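"""Cross-validation by identity: pairwise identities and the greedy split.

Benchmarking a taxonomy classifier on test sequences that have a near-twin in
the training set inflates accuracy, because real environmental sequences
rarely have such a twin in reference databases. Cross-validation by identity
instead controls the *top-hit identity*: every test sequence's best match in
the training set must lie within a band d ± δ (e.g. 97 ± 0.5%).

Given an all-vs-all identity table over amplicons, a greedy procedure builds
a test set S and training set A as large as possible under that constraint.
For a reference r, z(r) are its hits with identity above d+δ (these must be
excluded from training if r is tested) and t(r) are its hits inside the band
(eligible training top hits). References excluding fewer sequences are
processed first — sorted ascending by |z(r)| then |tz(r)|, where tz(r) pools
the z-sets of r's in-band hits — and the training set is grown slowly, at
most three additions per accepted test sequence. Hits below d-δ (the set W)
may always stay in training; A = T ∪ W. At d = 100 the whole collection
serves as both training and test set, since each sequence's top training hit
is then itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._align import identity_semiglobal
from .reference_prep import Amplicon

#: Band half-widths used at the standard identity levels.
DEFAULT_DELTAS = {99.0: 0.5, 97.0: 0.5, 95.0: 0.5, 90.0: 1.0}

#: Training-set additions allowed per accepted test sequence ("grow A slowly").
MAX_TRAIN_ADDITIONS = 3


def default_delta(d: float) -> float:
    return DEFAULT_DELTAS.get(float(d), 0.5)


@dataclass
class IdentityTable:
    """All-vs-all identities; per id a descending (other_id, identity%) list."""

    ids: list[str]
    hits: dict[str, list[tuple[str, float]]]

    def identity(self, a: str, b: str) -> float:
        for other, ident in self.hits[a]:
            if other == b:
                return ident
        return 0.0

    def top_hit(self, a: str, within: Optional[set[str]] = None
                ) -> Optional[tuple[str, float]]:
        """Best hit of *a*, optionally restricted to a candidate id set."""
        for other, ident in self.hits[a]:
            if within is None or other in within:
                return other, ident
        return None


@dataclass
class PartitionResult:
    d: float
    delta: float
    S: set[str]  # test set
    A: set[str]  # training set
    Z: set[str]  # excluded
    T: set[str] = field(default_factory=set)  # A members with an in-band hit to S
    W: set[str] = field(default_factory=set)  # A members entirely below d - delta


def pairwise_identities(amplicons: Sequence) -> IdentityTable:
    """All-vs-all global alignment identities (percent; pads never match).

    Accepts :class:`Amplicon` objects or anything with ``.seq`` and an id
    (``ref_id`` or ``id``). Each unordered pair is aligned once, so the table
    is exactly symmetric.
    """
    if len(amplicons) < 2:
        raise ValueError("need at least two amplicons")
    ids = [getattr(a, "ref_id", None) or getattr(a, "id") for a in amplicons]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate amplicon ids")
    seqs = {i: a.seq for i, a in zip(ids, amplicons)}
    hits: dict[str, list[tuple[str, float]]] = {i: [] for i in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ident = identity_semiglobal(seqs[a], seqs[b])
            hits[a].append((b, ident))
            hits[b].append((a, ident))
    for i in ids:
        hits[i].sort(key=lambda x: (-x[1], x[0]))
    return IdentityTable(ids=list(ids), hits=hits)


def greedy_partition(
    table: IdentityTable, d: float, delta: Optional[float] = None
) -> PartitionResult:
    """Split an identity table into test (S), training (A) and excluded (Z)
    sets such that every S member's top-hit identity to A lies in [d-δ, d+δ].

    References are processed in ascending (|z|, |tz|, id) order. One is
    admitted to S only when at least one of its in-band hits can serve in A
    and when excluding its z-set would not strip any earlier S member of its
    last in-band training hit; otherwise it joins A (unless excluded).
    Fully deterministic.
    """
    z, t, tz = _hit_sets(table, d, delta)
    if z is None:  # d == 100
        all_ids = set(table.ids)
        dl = default_delta(d) if delta is None else delta
        return PartitionResult(d, dl, set(all_ids), set(all_ids), set(),
                               set(all_ids), set())
    order = sorted(table.ids, key=lambda r: (len(z[r]), len(tz[r]), r))
    return _assign(table, d, delta, order, z, t)


def naive_partition(
    table: IdentityTable, d: float, delta: Optional[float] = None
) -> PartitionResult:
    """First-come baseline: identical assignment rule but in plain id order,
    without the fewest-exclusions sort. Gauges the greedy ordering's benefit."""
    z, t, _ = _hit_sets(table, d, delta)
    if z is None:
        return greedy_partition(table, d, delta)
    return _assign(table, d, delta, sorted(table.ids), z, t)


def _hit_sets(table: IdentityTable, d: float, delta: Optional[float]):
    if not table.ids:
        raise ValueError("empty identity table")
    if d >= 100.0:
        return None, None, None
    if delta is None:
        delta = default_delta(d)
    if delta <= 0:
        raise ValueError("delta must be positive for d < 100")
    lo, hi = d - delta, d + delta
    z = {r: {h for h, i in table.hits[r] if i > hi} for r in table.ids}
    t = {r: {h for h, i in table.hits[r] if lo <= i <= hi} for r in table.ids}
    tz = {r: set().union(*(z[h] for h in t[r])) if t[r] else set()
          for r in table.ids}
    return z, t, tz


def _assign(table, d, delta, order, z, t) -> PartitionResult:
    if delta is None:
        delta = default_delta(d)
    S: set[str] = set()
    A: set[str] = set()
    Z: set[str] = set()
    # per S member: its in-band hits currently in A, so an exclusion that
    # would strand an earlier test sequence can be vetoed
    band_support: dict[str, set[str]] = {}

    for r in order:
        if r in Z or r in A:
            continue
        usable = t[r] - S - Z
        if usable and not any(
            support <= z[r] for support in band_support.values()
        ):
            S.add(r)
            newly_excluded = z[r] - S
            Z |= newly_excluded
            A -= newly_excluded
            for support in band_support.values():
                support -= newly_excluded
            additions = sorted(usable - A - Z)[:MAX_TRAIN_ADDITIONS]
            A.update(additions)
            band_support[r] = (t[r] & A) - Z
        else:
            A.add(r)
            for s in S:
                if r in t[s]:
                    band_support[s].add(r)

    leftovers = set(table.ids) - S - A - Z
    A |= leftovers

    T = {a for a in A if any(a in t[s] for s in S)}
    return PartitionResult(d, delta, S, A, Z, T, A - T)
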