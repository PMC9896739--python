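"""Seeded generator of synthetic diagnostic case corpora.

Real graded case corpora for diagnosis ranking are private clinical assets, so
this module fabricates corpora with the same statistical shape: each disease
has a characteristic symptom profile (profiles may overlap, which is what
makes differential diagnoses plausible); a case draws a confirmed disease in
proportion to its prevalence weight, observes each profile symptom with a
fixed sensitivity, adds a Poisson number of off-profile noise symptoms, and
grades the differentials — the diseases whose profiles best overlap the
observed symptoms (Jaccard similarity) — with geometrically decaying scores
below the confirmed disease's score.

The default scores (confirmed 17.0, decay 0.7 giving 11.9, 8.3, ...) imitate
the magnitude and smooth decrease of graded clinical relevance lists; the
scheme itself is an invented, documented stand-in, isolated in
:class:`GeneratorConfig`.

Everything is driven by ``config.seed`` through independent named streams, so
a corpus is byte-identical across runs for a fixed config.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .casedata import CaseCorpus, CaseRecord, Vocabulary

_PROFILE_STREAM = 0
_CASE_STREAM = 1
_TRAJECTORY_STREAM = 2


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus; defaults define the standard study corpus.

    symptoms_per_disease
        inclusive (lo, hi) range of characteristic-profile sizes.
    sensitivity
        probability that each profile symptom is actually observed in a case.
    noise_rate
        expected count (Poisson mean) of off-profile symptoms per case.
    n_differentials
        inclusive (lo, hi) range of graded differential diseases per case.
    confirmed_score / differential_score_decay
        the confirmed disease scores ``confirmed_score``; the r-th ranked
        differential scores ``confirmed_score * decay**(r+1)``.
    disjoint_profiles
        partition the symptom space so no two diseases share a profile
        symptom; used for separability checks.
    """

    n_diseases: int = 200
    n_symptoms: int = 400
    n_cases: int = 2000
    symptoms_per_disease: tuple[int, int] = (6, 12)
    sensitivity: float = 0.75
    noise_rate: float = 1.5
    n_differentials: tuple[int, int] = (5, 9)
    confirmed_score: float = 17.0
    differential_score_decay: float = 0.7
    disjoint_profiles: bool = False
    seed: int = 7

    def __post_init__(self) -> None:
        lo, hi = self.symptoms_per_disease
        if not (1 <= lo <= hi):
            raise ValueError("symptoms_per_disease must be a range with 1 <= lo <= hi")
        dlo, dhi = self.n_differentials
        if not (1 <= dlo <= dhi):
            raise ValueError("n_differentials must be a range with 1 <= lo <= hi")
        if min(self.n_diseases, self.n_symptoms, self.n_cases) < 1:
            raise ValueError("n_diseases, n_symptoms, n_cases must all be >= 1")
        if not (0.0 <= self.sensitivity <= 1.0):
            raise ValueError("sensitivity must be a probability")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be >= 0")
        if self.confirmed_score <= 0:
            raise ValueError("confirmed_score must be positive")
        if not (0.0 < self.differential_score_decay < 1.0):
            raise ValueError("differential_score_decay must be in (0, 1)")
        if hi > self.n_symptoms:
            raise ValueError(
                f"profile size up to {hi} infeasible with {self.n_symptoms} symptoms"
            )
        if self.disjoint_profiles and self.n_diseases * hi > self.n_symptoms:
            raise ValueError(
                "disjoint profiles need n_symptoms >= n_diseases * max profile size"
            )
        if dhi > self.n_diseases - 1:
            raise ValueError("cannot grade more differentials than other diseases")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        for key in ("symptoms_per_disease", "n_differentials"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["symptoms_per_disease"] = list(d["symptoms_per_disease"])
        d["n_differentials"] = list(d["n_differentials"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")


@dataclass(frozen=True)
class DiseaseProfile:
    """Latent generator state for one disease."""

    code: str
    symptom_indices: tuple[int, ...]
    prevalence: float

    def __post_init__(self) -> None:
        if not self.symptom_indices:
            raise ValueError(f"profile {self.code!r} is empty")
        if self.prevalence <= 0:
            raise ValueError(f"profile {self.code!r} needs positive prevalence")


def _vocabularies(config: GeneratorConfig) -> tuple[Vocabulary, Vocabulary]:
    width_s = len(str(config.n_symptoms))
    width_d = len(str(config.n_diseases))
    symptom_vocab = Vocabulary.from_pairs(
        "symptom",
        [(f"s{i:0{width_s}d}", f"Symptom {i}") for i in range(1, config.n_symptoms + 1)],
    )
    disease_vocab = Vocabulary.from_pairs(
        "disease",
        [(f"d{i:0{width_d}d}", f"Disease {i}") for i in range(1, config.n_diseases + 1)],
    )
    return symptom_vocab, disease_vocab


def make_profiles(config: GeneratorConfig) -> list[DiseaseProfile]:
    """Draw the per-disease characteristic symptom profiles and prevalences."""
    rng = np.random.default_rng([config.seed, _PROFILE_STREAM])
    _, disease_vocab = _vocabularies(config)
    lo, hi = config.symptoms_per_disease
    sizes = rng.integers(lo, hi + 1, size=config.n_diseases)
    # gamma-distributed prevalence: a few common diseases, a long rare tail
    prevalences = rng.gamma(shape=3.0, scale=1.0, size=config.n_diseases) + 1e-3

    profiles: list[DiseaseProfile] = []
    if config.disjoint_profiles:
        pool = rng.permutation(config.n_symptoms)
        offset = 0
        for d in range(config.n_diseases):
            chunk = pool[offset : offset + sizes[d]]
            offset += sizes[d]
            profiles.append(
                DiseaseProfile(
                    code=disease_vocab.code(d),
                    symptom_indices=tuple(int(s) for s in np.sort(chunk)),
                    prevalence=float(prevalences[d]),
                )
            )
    else:
        for d in range(config.n_diseases):
            chunk = rng.choice(config.n_symptoms, size=sizes[d], replace=False)
            profiles.append(
                DiseaseProfile(
                    code=disease_vocab.code(d),
                    symptom_indices=tuple(int(s) for s in np.sort(chunk)),
                    prevalence=float(prevalences[d]),
                )
            )
    return profiles


def _profile_matrix(config: GeneratorConfig, profiles: list[DiseaseProfile]) -> np.ndarray:
    M = np.zeros((config.n_diseases, config.n_symptoms), dtype=bool)
    for d, prof in enumerate(profiles):
        M[d, list(prof.symptom_indices)] = True
    return M


def _sample_case_symptoms(
    rng: np.random.Generator, config: GeneratorConfig, profile: DiseaseProfile
) -> np.ndarray:
    prof = np.asarray(profile.symptom_indices)
    keep = rng.random(len(prof)) < config.sensitivity
    observed = prof[keep]
    n_noise = rng.poisson(config.noise_rate)
    if n_noise > 0:
        off = np.setdiff1d(np.arange(config.n_symptoms), prof)
        n_noise = min(n_noise, len(off))
        observed = np.concatenate([observed, rng.choice(off, n_noise, replace=False)])
    if len(observed) == 0:  # a case must show at least one symptom
        observed = np.array([prof[rng.integers(len(prof))]])
    return observed


def _grade_differentials(
    rng: np.random.Generator,
    config: GeneratorConfig,
    M: np.ndarray,
    confirmed: int,
    observed: np.ndarray,
) -> list[tuple[int, float]]:
    """Top-overlap diseases with geometrically decaying scores."""
    obs = np.zeros(config.n_symptoms, dtype=bool)
    obs[observed] = True
    inter = (M & obs).sum(axis=1).astype(float)
    union = M.sum(axis=1) + obs.sum() - inter
    sim = np.where(union > 0, inter / union, 0.0)
    sim[confirmed] = -np.inf
    dlo, dhi = config.n_differentials
    n_diff = int(rng.integers(dlo, dhi + 1))
    # ties in overlap (common when profiles are disjoint) break by circular
    # code distance from the confirmed disease, then by index: deterministic,
    # and avoids every case sharing the same low-index differentials
    n = len(sim)
    circ_dist = (np.arange(n) - confirmed) % n
    order = np.lexsort((np.arange(n), circ_dist, -sim))[:n_diff]
    decay = config.differential_score_decay
    return [
        (int(d), config.confirmed_score * decay ** (r + 1))
        for r, d in enumerate(order)
    ]


def generate_corpus(config: GeneratorConfig) -> CaseCorpus:
    """Generate the full synthetic corpus (profiles + ``n_cases`` cases)."""
    profiles = make_profiles(config)
    symptom_vocab, disease_vocab = _vocabularies(config)
    M = _profile_matrix(config, profiles)
    weights = np.array([p.prevalence for p in profiles])
    weights = weights / weights.sum()
    rng = np.random.default_rng([config.seed, _CASE_STREAM])

    width = len(str(config.n_cases))
    cases: list[CaseRecord] = []
    for i in range(config.n_cases):
        confirmed = int(rng.choice(config.n_diseases, p=weights))
        observed = _sample_case_symptoms(rng, config, profiles[confirmed])
        observed = observed[rng.permutation(len(observed))]  # acquisition order
        relevances = [(disease_vocab.code(confirmed), config.confirmed_score)]
        relevances += [
            (disease_vocab.code(d), s)
            for d, s in _grade_differentials(rng, config, M, confirmed, observed)
        ]
        cases.append(
            CaseRecord(
                case_id=f"case{i + 1:0{width}d}",
                symptoms=tuple(symptom_vocab.code(int(s)) for s in observed),
                relevances=tuple(relevances),
                provenance=f"synthetic:{config.seed}:{profiles[confirmed].code}",
            )
        )
    return CaseCorpus(
        symptom_vocab=symptom_vocab, disease_vocab=disease_vocab, cases=tuple(cases)
    )


def generate_trajectory_fixture(
    config: GeneratorConfig, target_disease: str
) -> CaseRecord:
    """One case for ``target_disease`` with symptoms ordered least-specific-first.

    Emulates progressive symptom acquisition: common (low inverse document
    frequency across disease profiles) symptoms arrive before disease-specific
    ones, which is the ordering the rank-trajectory evaluation probes.
    """
    profiles = make_profiles(config)
    symptom_vocab, disease_vocab = _vocabularies(config)
    codes = [p.code for p in profiles]
    if target_disease not in codes:
        raise KeyError(f"unknown disease code {target_disease!r}")
    target = codes.index(target_disease)
    rng = np.random.default_rng([config.seed, _TRAJECTORY_STREAM, target])

    observed = _sample_case_symptoms(rng, config, profiles[target])
    M = _profile_matrix(config, profiles)
    doc_freq = M.sum(axis=0)  # in how many profiles each symptom appears
    # ascending IDF == descending document frequency; ties by symptom index
    order = np.lexsort((observed, -doc_freq[observed]))
    observed = observed[order]

    relevances = [(disease_vocab.code(target), config.confirmed_score)]
    relevances += [
        (disease_vocab.code(d), s)
        for d, s in _grade_differentials(rng, config, M, target, observed)
    ]
    return CaseRecord(
        case_id=f"trajectory-{target_disease}",
        symptoms=tuple(symptom_vocab.code(int(s)) for s in observed),
        relevances=tuple(relevances),
        provenance=f"synthetic-trajectory:{config.seed}:{target_disease}",
    )


def separable_config(
    n_diseases: int = 20,
    n_cases: int = 200,
    seed: int = 7,
    profile_size: int = 6,
) -> GeneratorConfig:
    """Noiseless, disjoint-profile config: every case shows exactly its
    disease's full profile, so a ranker can order the corpus perfectly."""
    return GeneratorConfig(
        n_diseases=n_diseases,
        n_symptoms=n_diseases * profile_size,
        n_cases=n_cases,
        symptoms_per_disease=(profile_size, profile_size),
        sensitivity=1.0,
        noise_rate=0.0,
        n_differentials=(3, 3),
        disjoint_profiles=True,
        seed=seed,
    )
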