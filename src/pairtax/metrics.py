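"""Hierarchical scoring of taxonomy predictions and the paired OTU screen.

Taxonomy prediction is hierarchical, so a flat right/wrong count misses the
structure of its failures. At each rank, every test sequence falls into one
of four outcomes relative to the training data:

* TP — the predicted name equals the true name;
* OC (over-classification) — a name was predicted that does not exist in the
  training data at that rank (it could not possibly be verified);
* UC (under-classification) — the sequence's true name exists in training
  but nothing was predicted at that rank;
* MC (misclassification) — a training name was predicted but it is wrong.

With K the number of test sequences whose true name at the rank exists in
training, accuracy is TP / (K + OC): over-calls dilute accuracy even though
they fall outside K. A sequence whose true name is absent from training and
which receives no prediction at the rank is a correct rejection and counts
in no class. Under cross-validation by identity the accuracy is averaged,
unweighted, over the identity levels (100, 99, 97, 95, 90%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .classify import TaxonomyPrediction
from .io_formats import Lineage, RANKS


@dataclass
class RankMetrics:
    rank: str
    TP: int
    K: int
    OC: int
    UC: int
    MC: int

    @property
    def accuracy(self) -> float:
        denom = self.K + self.OC
        return self.TP / denom if denom else 0.0


@dataclass
class EvalReport:
    per_identity: dict[float, dict[str, RankMetrics]]
    mean_accuracy_by_rank: dict[str, float]


def training_taxa(lineages: Sequence[Lineage]) -> dict[str, set[str]]:
    """Per-rank name sets present in the training data."""
    taxa: dict[str, set[str]] = {r: set() for r in RANKS}
    for lin in lineages:
        for rank, name in lin.ranks:
            taxa[rank].add(name)
    return taxa


def score_predictions(
    preds: Sequence[TaxonomyPrediction],
    truths: Mapping[str, Lineage],
    train_taxa: Mapping[str, set[str]],
) -> dict[str, RankMetrics]:
    """Count TP/OC/UC/MC per rank for a batch of predictions."""
    missing = [p.query_id for p in preds if p.query_id not in truths]
    if missing:
        raise ValueError(f"predictions without truth: {missing[:5]}")
    out: dict[str, RankMetrics] = {}
    for rank in RANKS:
        tp = k = oc = uc = mc = 0
        known = train_taxa.get(rank, set())
        for p in preds:
            truth_name = truths[p.query_id].get(rank)
            pred_name = p.predicted.get(rank) if p.predicted else None
            in_training = truth_name is not None and truth_name in known
            if in_training:
                k += 1
            if pred_name is None:
                if in_training:
                    uc += 1
                # else: correct rejection, no class
            elif pred_name not in known:
                oc += 1
            elif pred_name == truth_name:
                tp += 1
            else:
                mc += 1
        out[rank] = RankMetrics(rank=rank, TP=tp, K=k, OC=oc, UC=uc, MC=mc)
    return out


def mean_accuracy(
    reports: Mapping[float, Mapping[str, RankMetrics]],
    levels: Sequence[float] = (100.0, 99.0, 97.0, 95.0, 90.0),
) -> dict[str, float]:
    """Unweighted mean accuracy per rank over the identity levels."""
    missing = [d for d in levels if d not in reports]
    if missing:
        raise ValueError(f"missing identity levels: {missing}")
    return {
        rank: sum(reports[d][rank].accuracy for d in levels) / len(levels)
        for rank in RANKS
    }


def evaluate(
    reports: Mapping[float, Mapping[str, RankMetrics]],
    levels: Sequence[float] = (100.0, 99.0, 97.0, 95.0, 90.0),
) -> EvalReport:
    return EvalReport(
        per_identity={d: dict(reports[d]) for d in levels},
        mean_accuracy_by_rank=mean_accuracy(reports, levels),
    )


def differential_otu_screen(
    attack: pd.DataFrame,
    recovery: pd.DataFrame,
    min_delta: float = 0.03,
    min_fold: float = 3.0,
    min_diff: int = 3,
) -> pd.DataFrame:
    """Flag OTUs whose proportion shifts consistently between paired phases.

    *attack* and *recovery* are OTU x patient proportion tables with
    identical row/column labels (each patient sampled once per phase). Per
    OTU, ``n_up`` counts patients with attack - recovery >= *min_delta* and
    ``n_down`` the reverse. An OTU is flagged "up" when
    ``n_up >= min_fold * n_down`` and ``n_up >= n_down + min_diff``
    (both conditions), and symmetrically "down". Returns a DataFrame indexed
    by OTU with columns n_up, n_down, direction (up/down/none).
    """
    if list(attack.columns) != list(recovery.columns) or list(attack.index) != list(
        recovery.index
    ):
        raise ValueError("attack/recovery tables are not paired identically")
    if ((attack < 0) | (attack > 1) | (recovery < 0) | (recovery > 1)).any().any():
        raise ValueError("proportions must lie in [0, 1]")
    diff = attack - recovery
    n_up = (diff >= min_delta).sum(axis=1)
    n_down = (-diff >= min_delta).sum(axis=1)
    direction = []
    for u, dn in zip(n_up, n_down):
        if u >= min_fold * dn and u >= dn + min_diff:
            direction.append("up")
        elif dn >= min_fold * u and dn >= u + min_diff:
            direction.append("down")
        else:
            direction.append("none")
    return pd.DataFrame(
        {"n_up": n_up.astype(int), "n_down": n_down.astype(int),
         "direction": direction},
        index=attack.index,
    )
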