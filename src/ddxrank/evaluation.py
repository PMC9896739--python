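"""k-fold cross-validated comparison of the listwise and pointwise systems.

The protocol: split the corpus into k folds at the case level, train one model
per fold on the remaining cases, and average the evaluation functions (ndcg,
ndcg@5, ndcg@10, ndcg@20, mse) over the held-out cases. Two systems — the
ApproxNDCG-trained listwise ranker and the MSE-trained pointwise baseline —
are compared on byte-identical fold splits and training configuration, so the
only difference between the rows of the report is the loss function.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .casedata import CaseCorpus
from .model import DiseaseRanker, LearningCurves, LossConfig, TrainConfig

EVALUATION_FUNCTIONS = ("ndcg", "ndcg@5", "ndcg@10", "ndcg@20", "mse")


@dataclass(frozen=True)
class EvalConfig:
    """Cross-validation protocol shared by every system under comparison."""

    k: int = 5
    cutoffs: tuple[int, ...] = (5, 10, 20)
    train: TrainConfig = field(default_factory=TrainConfig)
    split_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if any(c < 1 for c in self.cutoffs):
            raise ValueError("cutoffs must be positive")


def kfold_split(
    corpus: CaseCorpus, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic case-level folds: disjoint test sets covering the corpus,
    sizes differing by at most one."""
    if len(corpus) < k:
        raise ValueError(f"corpus has {len(corpus)} cases, fewer than k={k}")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train_idx, test_idx)
        for train_idx, test_idx in splitter.split(np.arange(len(corpus)))
    ]


@dataclass
class SystemReport:
    """Per-fold evaluation of one system (one loss function)."""

    system: str
    loss_config: LossConfig
    per_fold: pd.DataFrame  # index: fold, columns: evaluation functions
    curves: list[LearningCurves]

    @property
    def means(self) -> pd.Series:
        return self.per_fold.mean(axis=0)

    @property
    def sds(self) -> pd.Series:
        return self.per_fold.std(axis=0, ddof=1)


@dataclass
class EvaluationReport:
    """Two-system (or more) cross-validation report, Table-style."""

    rows: list[SystemReport]
    k: int
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            for metric in row.per_fold.columns:
                rec = {
                    "system": row.system,
                    "metric": metric,
                    "mean": row.means[metric],
                    "sd": row.sds[metric],
                }
                for f in range(self.k):
                    rec[f"fold_{f + 1}"] = row.per_fold.iloc[f][metric]
                records.append(rec)
        return pd.DataFrame.from_records(records)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def summary(self) -> str:
        lines = ["Cross-validated evaluation functions (mean over folds)", "-" * 60]
        header = "system".ljust(12) + "".join(m.rjust(10) for m in EVALUATION_FUNCTIONS)
        lines.append(header)
        for row in self.rows:
            vals = "".join(f"{row.means[m]:>10.4f}" for m in EVALUATION_FUNCTIONS)
            lines.append(row.system.ljust(12) + vals)
        return "\n".join(lines)


def _eval_fold(
    corpus: CaseCorpus,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    loss_cfg: LossConfig,
    train_cfg: TrainConfig,
    cutoffs: tuple[int, ...],
) -> tuple[dict[str, float], LearningCurves]:
    ranker = DiseaseRanker(corpus.subset(train_idx), loss_cfg, train_cfg)
    res = ranker.fit()
    X_test, Y_test = _densify_subset(corpus, test_idx)
    return res.evaluate(X_test, Y_test, cutoffs), res.curves


def _densify_subset(corpus: CaseCorpus, idx: np.ndarray):
    from .casedata import densify_corpus

    sub = corpus.subset(idx)
    return densify_corpus(sub)


def evaluate_system(
    corpus: CaseCorpus,
    loss_cfg: LossConfig,
    eval_cfg: EvalConfig,
    system_name: str | None = None,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> SystemReport:
    """Cross-validate one loss function; returns its per-fold report row."""
    if folds is None:
        folds = kfold_split(corpus, eval_cfg.k, eval_cfg.split_seed)
    rows = []
    curves = []
    for train_idx, test_idx in folds:
        metrics, c = _eval_fold(
            corpus, train_idx, test_idx, loss_cfg, eval_cfg.train, eval_cfg.cutoffs
        )
        rows.append(metrics)
        curves.append(c)
    per_fold = pd.DataFrame(rows)
    name = system_name or ("A-NDCG" if loss_cfg.loss == "approx_ndcg" else "MSE")
    return SystemReport(
        system=name, loss_config=loss_cfg, per_fold=per_fold, curves=curves
    )


def compare_systems(corpus: CaseCorpus, eval_cfg: EvalConfig) -> EvaluationReport:
    """Listwise vs pointwise under identical folds and training configuration.

    Fairness is structural: both systems receive the same fold index arrays
    and the same :class:`TrainConfig`; their :class:`LossConfig` objects
    differ only in the ``loss`` field.
    """
    folds = kfold_split(corpus, eval_cfg.k, eval_cfg.split_seed)
    listwise = LossConfig(loss="approx_ndcg")
    pointwise = replace(listwise, loss="mse")
    rows = [
        evaluate_system(corpus, listwise, eval_cfg, "A-NDCG", folds),
        evaluate_system(corpus, pointwise, eval_cfg, "MSE", folds),
    ]
    return EvaluationReport(rows=rows, k=eval_cfg.k, folds=folds)
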