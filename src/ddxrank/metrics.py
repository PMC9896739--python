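"""Graded-relevance ranking metrics: DCG, NDCG, NDCG@k, rank and top-k hit.

The evaluation functions used throughout the package are the ndcg family
(full-list and the cutoffs 5/10/20) plus a top-k hit criterion that mirrors
how physicians use a differential list: the confirmed (or a related) disease
should appear within the first k suggestions.

Conventions: 1-based ranks, discount ``log2(i+1)``, ties between equal scores
broken by vocabulary index (input order), so every ranking is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .casedata import ScoredList


@dataclass(frozen=True)
class MetricConfig:
    """Gain/cutoff configuration for the DCG family.

    gain
        ``identity`` uses g(r) = r (default — relevance labels here are real
        scores that can exceed 17, for which the exponential gain 2^r − 1 is
        numerically explosive); ``exponential`` uses g(r) = 2^r − 1 for
        integer-graded data.
    k
        cutoff; ``None`` evaluates the full list.
    zero_ideal_policy
        value returned by :func:`ndcg` when the ideal DCG is 0 (all labels
        zero); 0 by convention.
    """

    gain: Literal["identity", "exponential"] = "identity"
    k: int | None = None
    zero_ideal_policy: float = 0.0

    def __post_init__(self) -> None:
        if self.k is not None and self.k < 1:
            raise ValueError(f"cutoff k must be >= 1, got {self.k}")
        if self.gain not in ("identity", "exponential"):
            raise ValueError(f"unknown gain {self.gain!r}")

    def gain_of(self, labels: np.ndarray) -> np.ndarray:
        labels = np.asarray(labels, dtype=float)
        if self.gain == "identity":
            return labels
        return np.exp2(labels) - 1.0


def ranking_order(scores: np.ndarray) -> np.ndarray:
    """Indices ordered by descending score, ties broken by ascending index.

    The single source of truth for ranking in the package: a stable argsort of
    the negated scores keeps input (vocabulary) order among ties.
    """
    return np.argsort(-np.asarray(scores, dtype=float), kind="stable")


def dcg(ordered_labels: Iterable[float], config: MetricConfig = MetricConfig()) -> float:
    """Discounted cumulative gain of labels already in ranked order.

    DCG@k = sum_{i=1..k} g(rel_i) / log2(i + 1).
    """
    labels = np.asarray(list(ordered_labels) if not isinstance(ordered_labels, np.ndarray) else ordered_labels, dtype=float)
    if config.k is not None:
        labels = labels[: config.k]
    if labels.size == 0:
        return 0.0
    gains = config.gain_of(labels)
    discounts = np.log2(np.arange(2, labels.size + 2))
    return float(np.sum(gains / discounts))


def ideal_dcg(labels: np.ndarray, config: MetricConfig = MetricConfig()) -> float:
    """DCG of the best possible ordering (labels sorted descending)."""
    ordered = np.asarray(labels, dtype=float)[ranking_order(labels)]
    return dcg(ordered, config)


def ndcg(scored: ScoredList, config: MetricConfig = MetricConfig()) -> float:
    """Normalized DCG of the model's ranking, in [0, 1].

    Labels are ordered by descending model score (vocabulary-index
    tie-break) and their DCG is divided by the ideal DCG. When every label is
    zero the ideal DCG is 0 and ``config.zero_ideal_policy`` is returned.
    """
    idcg = ideal_dcg(scored.labels, config)
    if idcg == 0.0:
        return config.zero_ideal_policy
    ordered = scored.labels[ranking_order(scored.scores)]
    return dcg(ordered, config) / idcg


def rank_of(scored: ScoredList, disease_index: int) -> int:
    """1-based rank of one disease under the model's scores.

    Descending-score order with vocabulary-index tie-break; a bijection over
    indices for fixed scores.
    """
    n = len(scored)
    if not (0 <= disease_index < n):
        raise IndexError(f"disease index {disease_index} out of range [0, {n})")
    order = ranking_order(scored.scores)
    return int(np.argmax(order == disease_index)) + 1


def topk_hit(scored: ScoredList, target_indices: Iterable[int], k: int) -> bool:
    """True iff any target disease is ranked within the top k."""
    targets = list(target_indices)
    if not targets:
        raise ValueError("target set must be non-empty")
    return min(rank_of(scored, t) for t in targets) <= k


def mse(scored: ScoredList) -> float:
    """Mean squared error between scores and labels (an evaluation function)."""
    return float(np.mean((scored.scores - scored.labels) ** 2))
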