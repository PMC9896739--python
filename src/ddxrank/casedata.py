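"""Case-data model and I/O for graded differential-diagnosis corpora.

A corpus pairs two vocabularies (symptom codes, disease codes) with a list of
diagnostic cases. Each case carries the symptoms observed for one patient, in
the order they were acquired clinically, together with a graded relevance list:
the confirmed disease(s) receive the highest score and the differential
diseases (related, or important to exclude) receive smaller positive scores.
Diseases not mentioned by a case have relevance exactly 0. This graded list is
the unit the listwise ranking loss consumes.

File formats
------------
* Vocabulary: two-column TSV ``code<TAB>label`` with a mandatory header row.
* Corpus: UTF-8 JSON lines. The first line is a header object
  ``{"format": "ddxrank-corpus", "version": 1}``; every further line is one
  case: ``{"case_id": ..., "symptoms": [...], "relevances": [[code, score],
  ...], "provenance": ...}``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

CORPUS_FORMAT = "ddxrank-corpus"
CORPUS_VERSION = 1


class CorpusValidationError(ValueError):
    """A corpus, case or vocabulary violates a structural invariant."""


@dataclass(frozen=True)
class Vocabulary:
    """Ordered, unique ``code -> index`` map for symptoms or diseases.

    Iteration order equals file order and defines the deterministic
    tie-breaking order used by every ranking operation in the package.
    """

    kind: Literal["symptom", "disease"]
    entries: tuple[tuple[str, str], ...]  # (code, label)
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.entries]
        if any(not c for c in codes):
            raise CorpusValidationError(f"{self.kind} vocabulary has an empty code")
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise CorpusValidationError(
                f"duplicate {self.kind} codes in vocabulary: {dupes}"
            )
        object.__setattr__(self, "_index", {c: i for i, (c, _) in enumerate(self.entries)})

    @classmethod
    def from_pairs(
        cls, kind: Literal["symptom", "disease"], pairs: Iterable[tuple[str, str]]
    ) -> "Vocabulary":
        return cls(kind=kind, entries=tuple((str(c), str(l)) for c, l in pairs))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self._index

    def __iter__(self) -> Iterator[str]:
        return (c for c, _ in self.entries)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.entries)

    def index(self, code: str) -> int:
        try:
            return self._index[code]
        except KeyError:
            raise KeyError(f"unknown {self.kind} code {code!r}") from None

    def code(self, index: int) -> str:
        return self.entries[index][0]

    def label(self, code: str) -> str:
        return self.entries[self.index(code)][1]

    def checksum(self) -> str:
        """SHA-256 over the ordered codes; guards model/vocabulary pairing."""
        h = hashlib.sha256()
        for c, _ in self.entries:
            h.update(c.encode("utf-8"))
            h.update(b"\x00")
        return h.hexdigest()


@dataclass(frozen=True)
class CaseRecord:
    """One diagnostic case: ordered symptoms plus graded disease relevances.

    ``symptoms`` preserve clinical acquisition order (used by the progressive
    rank-trajectory evaluation). ``relevances`` grade each mentioned disease;
    the maximum-scoring entry(ies) designate the confirmed disease(s).
    """

    case_id: str
    symptoms: tuple[str, ...]
    relevances: tuple[tuple[str, float], ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.symptoms:
            raise CorpusValidationError(f"case {self.case_id!r}: no symptoms")
        if len(set(self.symptoms)) != len(self.symptoms):
            raise CorpusValidationError(
                f"case {self.case_id!r}: duplicate symptom codes"
            )
        codes = [c for c, _ in self.relevances]
        if len(set(codes)) != len(codes):
            raise CorpusValidationError(
                f"case {self.case_id!r}: duplicate disease codes in relevances"
            )
        if any(s < 0 for _, s in self.relevances):
            raise CorpusValidationError(
                f"case {self.case_id!r}: negative relevance score"
            )
        if not any(s > 0 for _, s in self.relevances):
            raise CorpusValidationError(
                f"case {self.case_id!r}: needs at least one positive relevance"
            )

    @property
    def confirmed_diseases(self) -> tuple[str, ...]:
        """Disease code(s) carrying the maximal relevance score."""
        top = max(s for _, s in self.relevances)
        return tuple(c for c, s in self.relevances if s == top)


@dataclass(frozen=True)
class CaseCorpus:
    """A validated collection of cases over fixed vocabularies."""

    symptom_vocab: Vocabulary
    disease_vocab: Vocabulary
    cases: tuple[CaseRecord, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for case in self.cases:
            if case.case_id in seen:
                raise CorpusValidationError(f"duplicate case_id {case.case_id!r}")
            seen.add(case.case_id)
            for s in case.symptoms:
                if s not in self.symptom_vocab:
                    raise CorpusValidationError(
                        f"case {case.case_id!r}: unknown symptom code {s!r}"
                    )
            for d, _ in case.relevances:
                if d not in self.disease_vocab:
                    raise CorpusValidationError(
                        f"case {case.case_id!r}: unknown disease code {d!r}"
                    )

    def __len__(self) -> int:
        return len(self.cases)

    def subset(self, indices: Sequence[int]) -> "CaseCorpus":
        return CaseCorpus(
            symptom_vocab=self.symptom_vocab,
            disease_vocab=self.disease_vocab,
            cases=tuple(self.cases[i] for i in indices),
        )


@dataclass(frozen=True)
class ScoredList:
    """Parallel model-score / relevance-label vectors over the disease vocabulary.

    ``labels`` is the dense expansion of a case's graded relevance list
    (0 for unlisted diseases); ``scores`` are the model's real-valued outputs.
    """

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels, dtype=float)
        if scores.ndim != 1 or labels.ndim != 1 or scores.shape != labels.shape:
            raise ValueError(
                f"scores and labels must be equal-length 1-d vectors, got "
                f"{scores.shape} and {labels.shape}"
            )
        if np.any(labels < 0):
            raise ValueError("relevance labels must be nonnegative")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------------------
# Vectorization


def densify(
    case: CaseRecord, symptom_vocab: Vocabulary, disease_vocab: Vocabulary
) -> tuple[np.ndarray, np.ndarray]:
    """Expand a case to a symptom multi-hot vector and a dense label vector.

    Returns ``(x, labels)`` where ``x[j] = 1`` iff symptom ``j`` was observed
    and ``labels[i]`` is the case's relevance score for disease ``i`` (0 when
    the case does not mention the disease).
    """
    x = np.zeros(len(symptom_vocab))
    for s in case.symptoms:
        x[symptom_vocab.index(s)] = 1.0
    labels = np.zeros(len(disease_vocab))
    for d, score in case.relevances:
        labels[disease_vocab.index(d)] = float(score)
    return x, labels


def densify_corpus(corpus: CaseCorpus) -> tuple[np.ndarray, np.ndarray]:
    """Stack :func:`densify` over all cases → (X, Y) design matrices."""
    X = np.zeros((len(corpus), len(corpus.symptom_vocab)))
    Y = np.zeros((len(corpus), len(corpus.disease_vocab)))
    for i, case in enumerate(corpus.cases):
        X[i], Y[i] = densify(case, corpus.symptom_vocab, corpus.disease_vocab)
    return X, Y


# ---------------------------------------------------------------------------
# File I/O


def read_vocabulary(path: str | Path, kind: Literal["symptom", "disease"]) -> Vocabulary:
    """Read a two-column TSV vocabulary (header row required)."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise CorpusValidationError(f"{path}: missing header row")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusValidationError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            pairs.append((parts[0], parts[1]))
    return Vocabulary.from_pairs(kind, pairs)


def write_vocabulary(vocab: Vocabulary, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("code\tlabel\n")
        for code, label in vocab.entries:
            fh.write(f"{code}\t{label}\n")


def read_corpus(
    path: str | Path,
    symptom_vocab_path: str | Path,
    disease_vocab_path: str | Path,
) -> CaseCorpus:
    """Read and validate a JSON-lines corpus against its two vocabularies.

    Raises :class:`CorpusValidationError` naming the offending case and code
    for unknown codes, duplicated case ids, or malformed lines (with the line
    number).
    """
    symptom_vocab = read_vocabulary(symptom_vocab_path, "symptom")
    disease_vocab = read_vocabulary(disease_vocab_path, "disease")
    path = Path(path)
    cases: list[CaseRecord] = []
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise CorpusValidationError(f"{path}: empty file, missing header line")
        try:
            header = json.loads(header_line)
        except json.JSONDecodeError as exc:
            raise CorpusValidationError(f"{path}:1: malformed header: {exc}") from exc
        if header.get("format") != CORPUS_FORMAT:
            raise CorpusValidationError(
                f"{path}:1: not a {CORPUS_FORMAT} file (format={header.get('format')!r})"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                case = CaseRecord(
                    case_id=str(rec["case_id"]),
                    symptoms=tuple(str(s) for s in rec["symptoms"]),
                    relevances=tuple(
                        (str(c), float(s)) for c, s in rec["relevances"]
                    ),
                    provenance=str(rec.get("provenance", "")),
                )
            except CorpusValidationError:
                raise
            except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
                raise CorpusValidationError(
                    f"{path}:{lineno}: malformed case record: {exc}"
                ) from exc
            cases.append(case)
    return CaseCorpus(
        symptom_vocab=symptom_vocab, disease_vocab=disease_vocab, cases=tuple(cases)
    )


def write_corpus(
    corpus: CaseCorpus,
    path: str | Path,
    symptom_vocab_path: str | Path | None = None,
    disease_vocab_path: str | Path | None = None,
) -> None:
    """Write a corpus as JSON lines; optionally write the vocabularies too.

    ``read_corpus(write_corpus(c))`` reproduces ``c`` exactly.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(
            json.dumps({"format": CORPUS_FORMAT, "version": CORPUS_VERSION}) + "\n"
        )
        for case in corpus.cases:
            fh.write(
                json.dumps(
                    {
                        "case_id": case.case_id,
                        "symptoms": list(case.symptoms),
                        "relevances": [[c, s] for c, s in case.relevances],
                        "provenance": case.provenance,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
    if symptom_vocab_path is not None:
        write_vocabulary(corpus.symptom_vocab, symptom_vocab_path)
    if disease_vocab_path is not None:
        write_vocabulary(corpus.disease_vocab, disease_vocab_path)
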