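"""Physician-facing prediction workflow: ranked disease lists and trajectories.

``predict`` turns an ordered list of symptom codes into the top-n candidate
diseases with scores. ``rank_trajectory`` replays the symptoms one prefix at
a time — the way findings accumulate during a workup — and records each
target disease's rank after every new symptom, flagging the earliest point at
which a target enters the top of the list. ``topk_report`` measures, over a
corpus, how often the confirmed disease lands in the top k suggestions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .casedata import CaseCorpus, ScoredList, Vocabulary, densify_corpus
from .metrics import rank_of, ranking_order
from .model import RankingModel


class UnknownSymptomError(KeyError):
    """An inputted symptom code is not in the model's vocabulary."""


@dataclass(frozen=True)
class Prediction:
    """Ranked disease list for one symptom input (rank / score / disease)."""

    rows: tuple[tuple[int, str, str, float], ...]  # (rank, code, label, score)
    symptoms: tuple[str, ...]
    model_id: str

    def to_text(self) -> str:
        """Aligned human-readable table; scores shown to 2 decimals."""
        lines = [f"Inputted symptoms: {', '.join(self.symptoms)}", ""]
        width = max((len(label) for _, _, label, _ in self.rows), default=7)
        lines.append(f"{'rank':>4}  {'score':>7}  {'disease':<{width}}  code")
        for rank, code, label, score in self.rows:
            lines.append(f"{rank:>4}  {score:>7.2f}  {label:<{width}}  {code}")
        return "\n".join(lines)

    def to_json(self) -> str:
        """Machine output at full precision."""
        return json.dumps(
            {
                "model": self.model_id,
                "symptoms": list(self.symptoms),
                "ranking": [
                    {"rank": r, "code": c, "label": l, "score": s}
                    for r, c, l, s in self.rows
                ],
            },
            ensure_ascii=False,
        )


@dataclass(frozen=True)
class Trajectory:
    """Target-disease ranks after each symptom prefix.

    ``rows[t-1]`` holds ``(t, symptom added at step t, {target code: rank})``.
    ``first_hit`` is the smallest prefix length at which any target ranks
    within ``cutoff`` (None if never).
    """

    rows: tuple[tuple[int, str, dict[str, int]], ...]
    targets: tuple[str, ...]
    cutoff: int
    first_hit: int | None

    def to_text(self) -> str:
        lines = [
            f"Targets: {', '.join(self.targets)} (cutoff: top {self.cutoff})",
            f"{'step':>4}  {'symptom':<14}  " + "  ".join(f"{t:>8}" for t in self.targets),
        ]
        for t, symptom, ranks in self.rows:
            cells = "  ".join(
                f"{ranks[c]:>8}" if ranks[c] <= self.cutoff else f"{'>'+str(self.cutoff):>8}"
                for c in self.targets
            )
            lines.append(f"{t:>4}  {symptom:<14}  {cells}")
        if self.first_hit is not None:
            lines.append(f"first top-{self.cutoff} hit after {self.first_hit} symptom(s)")
        else:
            lines.append(f"no target entered the top {self.cutoff}")
        return "\n".join(lines)


def _vectorize_symptoms(
    symptoms: tuple[str, ...],
    vocab: Vocabulary,
    on_unknown: str,
) -> tuple[np.ndarray, tuple[str, ...]]:
    if not symptoms:
        raise ValueError("at least one symptom is required")
    x = np.zeros(len(vocab))
    kept: list[str] = []
    skipped: list[str] = []
    for s in symptoms:
        if s in vocab:
            x[vocab.index(s)] = 1.0
            kept.append(s)
        elif on_unknown == "skip":
            skipped.append(s)
        else:
            raise UnknownSymptomError(f"unknown symptom code {s!r}")
    if skipped:
        import warnings

        warnings.warn(f"skipped unknown symptom codes: {skipped}", stacklevel=3)
    if not kept:
        raise UnknownSymptomError("no inputted symptom code is known to the model")
    return x, tuple(kept)


def predict(
    model: RankingModel,
    symptom_vocab: Vocabulary,
    disease_vocab: Vocabulary,
    symptoms: tuple[str, ...] | list[str],
    top_n: int = 10,
    on_unknown: str = "error",
) -> Prediction:
    """Rank all diseases for the given symptoms and keep the top ``top_n``.

    Unknown symptom codes raise :class:`UnknownSymptomError` by default;
    ``on_unknown="skip"`` drops them with a warning instead.
    """
    symptoms = tuple(symptoms)
    x, _ = _vectorize_symptoms(symptoms, symptom_vocab, on_unknown)
    scores = model.forward(x)
    order = ranking_order(scores)[:top_n]
    rows = tuple(
        (
            rank,
            disease_vocab.code(int(d)),
            disease_vocab.label(disease_vocab.code(int(d))),
            float(scores[d]),
        )
        for rank, d in enumerate(order, start=1)
    )
    model_id = f"ddxrank[{(model.disease_checksum or 'unbound')[:12]}]"
    return Prediction(rows=rows, symptoms=symptoms, model_id=model_id)


def rank_trajectory(
    model: RankingModel,
    symptom_vocab: Vocabulary,
    disease_vocab: Vocabulary,
    symptoms: tuple[str, ...] | list[str],
    targets: tuple[str, ...] | list[str],
    cutoff: int = 10,
    on_unknown: str = "error",
) -> Trajectory:
    """Replay symptoms prefix by prefix, tracking each target's rank."""
    symptoms = tuple(symptoms)
    targets = tuple(targets)
    if not symptoms:
        raise ValueError("at least one symptom is required")
    if not targets:
        raise ValueError("at least one target disease is required")
    target_idx = {t: disease_vocab.index(t) for t in targets}

    rows: list[tuple[int, str, dict[str, int]]] = []
    first_hit: int | None = None
    for t in range(1, len(symptoms) + 1):
        x, _ = _vectorize_symptoms(symptoms[:t], symptom_vocab, on_unknown)
        scores = model.forward(x)
        dummy_labels = np.zeros_like(scores)
        ranks = {
            code: rank_of(ScoredList(scores, dummy_labels), idx)
            for code, idx in target_idx.items()
        }
        rows.append((t, symptoms[t - 1], ranks))
        if first_hit is None and min(ranks.values()) <= cutoff:
            first_hit = t
    return Trajectory(
        rows=tuple(rows), targets=targets, cutoff=cutoff, first_hit=first_hit
    )


def topk_report(
    model: RankingModel, corpus: CaseCorpus, k: int = 10
) -> tuple[float, dict[str, bool]]:
    """Fraction of cases whose confirmed (max-label) disease ranks within k.

    Returns the fraction and the per-case hit booleans.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    X, Y = densify_corpus(corpus)
    S = model.forward_batch(X)
    hits: dict[str, bool] = {}
    for i, case in enumerate(corpus.cases):
        top = Y[i].max()
        targets = np.flatnonzero(Y[i] == top)
        scored = ScoredList(S[i], Y[i])
        hits[case.case_id] = min(rank_of(scored, int(t)) for t in targets) <= k
    return float(np.mean(list(hits.values()))), hits
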