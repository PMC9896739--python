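"""Shared fixtures: tiny vocabularies, corpora, and an independent NDCG oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ddxrank import CaseCorpus, CaseRecord, Vocabulary


def ndcg_bruteforce(scores, labels, k=None, gain="identity") -> float:
    """Independent NDCG oracle: explicit sort + positionwise sum.

    Deliberately naive (pure-python loops) so it shares no code with the
    implementation under test. Ties broken by ascending index.
    """
    n = len(scores)
    g = (lambda r: r) if gain == "identity" else (lambda r: 2.0**r - 1.0)
    cut = n if k is None else min(k, n)

    def dcg_of(order):
        return sum(
            g(labels[order[i]]) / math.log2(i + 2) for i in range(cut)
        )

    by_score = sorted(range(n), key=lambda i: (-scores[i], i))
    by_label = sorted(range(n), key=lambda i: (-labels[i], i))
    ideal = dcg_of(by_label)
    if ideal == 0.0:
        return 0.0
    return dcg_of(by_score) / ideal


@pytest.fixture
def symptom_vocab() -> Vocabulary:
    return Vocabulary.from_pairs(
        "symptom",
        [
            ("Fever", "Fever"),
            ("Head", "Headache"),
            ("Sore", "Sore throat"),
            ("Myalg", "Muscles ache"),
            ("Fatig", "Fatigue"),
        ],
    )


@pytest.fixture
def disease_vocab() -> Vocabulary:
    return Vocabulary.from_pairs(
        "disease",
        [
            ("548", "Acute HIV-1 infection"),
            ("296", "Acute hepatitis"),
            ("102", "Toxoplasmosis"),
            ("491", "SFTS"),
        ],
    )


@pytest.fixture
def tiny_corpus(symptom_vocab, disease_vocab) -> CaseCorpus:
    cases = (
        CaseRecord(
            case_id="c1",
            symptoms=("Fever", "Head", "Sore"),
            relevances=(("548", 17.078), ("296", 12.086), ("102", 11.25)),
            provenance="fixture",
        ),
        CaseRecord(
            case_id="c2",
            symptoms=("Fatig", "Myalg"),
            relevances=(("296", 17.0), ("491", 8.0)),
            provenance="fixture",
        ),
    )
    return CaseCorpus(
        symptom_vocab=symptom_vocab, disease_vocab=disease_vocab, cases=cases
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
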