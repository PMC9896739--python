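"""Scoring network and training losses for listwise diagnosis ranking.

The scorer is deliberately small: a single hidden layer mapping a multi-hot
symptom vector to one real score per disease. Two loss functions train the
identical network:

* ``approx_ndcg`` — the listwise surrogate. NDCG itself is not differentiable
  because an item's rank is a step function of the scores; the surrogate
  replaces the 1-based rank of item i with the smooth estimate

      pi_hat_i = 1 + sum_{j != i} sigmoid(alpha * (s_j - s_i)),

  plugs it into the DCG discount, normalizes by the exact ideal DCG and
  minimizes the negative:  loss = -ApproxNDCG.  As alpha -> infinity each
  sigmoid becomes a step and -loss converges to the exact ndcg.
* ``mse`` — the pointwise baseline: mean squared error between the score
  vector and the graded relevance labels, disease by disease.

Gradients for both losses and the network are analytic (numpy); they are
verified against central finite differences in the test suite. Training is
mini-batch Adam (or plain SGD) with per-list losses averaged over the batch,
fully reproducible from the seed.

The public surface follows the statsmodels idiom: build a
:class:`DiseaseRanker` from a corpus, call :meth:`DiseaseRanker.fit`, get a
:class:`RankerResults` carrying the trained network, per-epoch learning
curves and a ``summary()``. The module-level :func:`train` wraps this for
callers that prefer functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.special import expit

from .casedata import CaseCorpus, ScoredList, Vocabulary, densify_corpus
from .metrics import MetricConfig, ideal_dcg, ndcg

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# Configs


@dataclass(frozen=True)
class LossConfig:
    """Which loss trains the network, and the surrogate's steepness.

    alpha is the logistic steepness (inverse temperature) of the rank
    approximation; larger alpha tracks the true ranks more closely but yields
    sparser gradients. The default 10 corresponds to the conventional
    temperature 0.1 of published ApproxNDCG implementations.

    standardize (ApproxNDCG only) evaluates the surrogate on per-list
    standardized scores, (s - mean(s)) / std(s). The surrogate otherwise
    rewards inflating score gaps until every sigmoid comparison saturates and
    gradients vanish, freezing whatever misorderings remain; standardization
    makes the training objective scale-invariant so ordering pressure never
    dies. It changes no ranking (the transform is monotone per list).
    """

    loss: Literal["approx_ndcg", "mse"] = "approx_ndcg"
    alpha: float = 10.0
    standardize: bool = True
    metric: MetricConfig = field(default_factory=MetricConfig)

    def __post_init__(self) -> None:
        if self.loss not in ("approx_ndcg", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters; every knob the training loop reads."""

    epochs: int = 30
    learning_rate: float = 0.01
    batch_size: int = 32
    optimizer: Literal["adam", "sgd"] = "adam"
    hidden_dim: int = 64
    weight_decay: float = 0.0
    seed: int = 0
    early_stopping_patience: int | None = None
    validation_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# Network


class RankingModel:
    """One-hidden-layer scorer: symptom multi-hot -> one score per disease.

    Weights are He-initialized from ``seed``; the forward pass is
    deterministic given the weights.
    """

    def __init__(
        self,
        n_symptoms: int,
        n_diseases: int,
        hidden_dim: int = 64,
        seed: int = 0,
        activation: Literal["relu"] = "relu",
    ) -> None:
        if activation != "relu":
            raise ValueError(f"unsupported activation {activation!r}")
        self.n_symptoms = int(n_symptoms)
        self.n_diseases = int(n_diseases)
        self.hidden_dim = int(hidden_dim)
        self.seed = int(seed)
        self.activation = activation
        rng = np.random.default_rng(seed)
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / n_symptoms), (n_symptoms, hidden_dim))
        self.b1 = np.zeros(hidden_dim)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / hidden_dim), (hidden_dim, n_diseases))
        self.b2 = np.zeros(n_diseases)
        # checksums of the vocabularies the model was trained against
        self.symptom_checksum: str | None = None
        self.disease_checksum: str | None = None

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Score vector over diseases for one multi-hot symptom vector."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_symptoms,):
            raise ValueError(
                f"input has shape {x.shape}, expected ({self.n_symptoms},)"
            )
        return self.forward_batch(x[None, :])[0]

    def forward_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_symptoms:
            raise ValueError(
                f"input has shape {X.shape}, expected (batch, {self.n_symptoms})"
            )
        H = np.maximum(X @ self.W1 + self.b1, 0.0)
        return H @ self.W2 + self.b2

    # -- parameter plumbing ---------------------------------------------------

    @property
    def parameters(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2]

    def _backward(
        self, X: np.ndarray, dS: np.ndarray
    ) -> list[np.ndarray]:
        """Gradients of a scalar loss w.r.t. parameters, given dLoss/dScores."""
        Hpre = X @ self.W1 + self.b1
        H = np.maximum(Hpre, 0.0)
        dW2 = H.T @ dS
        db2 = dS.sum(axis=0)
        dH = dS @ self.W2.T
        dHpre = dH * (Hpre > 0.0)
        dW1 = X.T @ dHpre
        db1 = dHpre.sum(axis=0)
        return [dW1, db1, dW2, db2]

    def copy(self) -> "RankingModel":
        clone = RankingModel.__new__(RankingModel)
        clone.__dict__.update(
            {
                k: (v.copy() if isinstance(v, np.ndarray) else v)
                for k, v in self.__dict__.items()
            }
        )
        return clone

    # -- serialization --------------------------------------------------------

    def bind_vocabularies(
        self, symptom_vocab: Vocabulary, disease_vocab: Vocabulary
    ) -> None:
        self.symptom_checksum = symptom_vocab.checksum()
        self.disease_checksum = disease_vocab.checksum()

    def to_dict(self) -> dict:
        return {
            "format": "ddxrank-model",
            "version": 1,
            "n_symptoms": self.n_symptoms,
            "n_diseases": self.n_diseases,
            "hidden_dim": self.hidden_dim,
            "seed": self.seed,
            "activation": self.activation,
            "symptom_checksum": self.symptom_checksum,
            "disease_checksum": self.disease_checksum,
            "weights": {
                "W1": {"shape": list(self.W1.shape), "data": self.W1.ravel().tolist()},
                "b1": {"shape": list(self.b1.shape), "data": self.b1.tolist()},
                "W2": {"shape": list(self.W2.shape), "data": self.W2.ravel().tolist()},
                "b2": {"shape": list(self.b2.shape), "data": self.b2.tolist()},
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def from_dict(cls, d: dict) -> "RankingModel":
        if d.get("format") != "ddxrank-model":
            raise ValueError("not a ddxrank model archive")
        model = cls(
            n_symptoms=d["n_symptoms"],
            n_diseases=d["n_diseases"],
            hidden_dim=d["hidden_dim"],
            seed=d["seed"],
            activation=d["activation"],
        )
        for name in ("W1", "b1", "W2", "b2"):
            w = d["weights"][name]
            arr = np.asarray(w["data"], dtype=float).reshape(w["shape"])
            if arr.shape != getattr(model, name).shape:
                raise ValueError(f"weight {name} has wrong shape {arr.shape}")
            setattr(model, name, arr)
        model.symptom_checksum = d.get("symptom_checksum")
        model.disease_checksum = d.get("disease_checksum")
        return model

    @classmethod
    def load(
        cls,
        path: str | Path,
        symptom_vocab: Vocabulary | None = None,
        disease_vocab: Vocabulary | None = None,
    ) -> "RankingModel":
        """Load a model; refuses to pair with mismatched vocabularies."""
        model = cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))
        if symptom_vocab is not None and model.symptom_checksum is not None:
            if symptom_vocab.checksum() != model.symptom_checksum:
                raise ValueError("symptom vocabulary does not match the model archive")
        if disease_vocab is not None and model.disease_checksum is not None:
            if disease_vocab.checksum() != model.disease_checksum:
                raise ValueError("disease vocabulary does not match the model archive")
        return model


# ---------------------------------------------------------------------------
# Losses (scalar API over ScoredList + vectorized batch internals)


def approx_positions(scores: np.ndarray, alpha: float) -> np.ndarray:
    """Smooth 1-based rank estimates pi_hat_i = 1 + sum_{j!=i} sigmoid(alpha (s_j - s_i)).

    Each entry lies in [1, n] and the vector sums to n(n+1)/2 exactly, because
    sigmoid(x) + sigmoid(-x) = 1 pairs off every (i, j) comparison.
    """
    s = np.asarray(scores, dtype=float)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    diff = s[None, :] - s[:, None]  # diff[i, j] = s_j - s_i
    sig = expit(alpha * diff)
    np.fill_diagonal(sig, 0.0)
    return 1.0 + sig.sum(axis=1)


def _approx_ndcg_batch(
    S: np.ndarray, Y: np.ndarray, loss_cfg: LossConfig, want_grad: bool
) -> tuple[np.ndarray, np.ndarray | None]:
    """ApproxNDCG losses/gradients, honoring ``loss_cfg.standardize``."""
    if not loss_cfg.standardize:
        return _approx_ndcg_batch_raw(S, Y, loss_cfg, want_grad)
    mu = S.mean(axis=1, keepdims=True)
    sd = S.std(axis=1, keepdims=True) + 1e-12
    Z = (S - mu) / sd
    losses, dZ = _approx_ndcg_batch_raw(Z, Y, loss_cfg, want_grad)
    if not want_grad:
        return losses, None
    assert dZ is not None
    # chain rule through z = (s - mean) / std
    dS = (
        dZ
        - dZ.mean(axis=1, keepdims=True)
        - Z * np.mean(dZ * Z, axis=1, keepdims=True)
    ) / sd
    return losses, dS


def _approx_ndcg_batch_raw(
    S: np.ndarray, Y: np.ndarray, loss_cfg: LossConfig, want_grad: bool
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-case ApproxNDCG losses (and optionally dLoss/dScores) for a batch.

    Only items with positive gain contribute to the DCG sum, so the pairwise
    sigmoid tensor is built between those items and the full list: shape
    (batch, max positives, n) instead of (batch, n, n).
    """
    B, n = S.shape
    alpha = loss_cfg.alpha
    G = loss_cfg.metric.gain_of(Y)
    idcg = np.array([ideal_dcg(Y[b], loss_cfg.metric) for b in range(B)])

    pos_lists = [np.flatnonzero(G[b] > 0) for b in range(B)]
    P = max((len(p) for p in pos_lists), default=0)
    losses = np.zeros(B)
    grad = np.zeros_like(S) if want_grad else None
    if P == 0:
        return losses, grad  # all-zero labels: loss 0 by policy

    pos_idx = np.zeros((B, P), dtype=int)
    mask = np.zeros((B, P))
    for b, p in enumerate(pos_lists):
        pos_idx[b, : len(p)] = p
        mask[b, : len(p)] = 1.0

    s_pos = np.take_along_axis(S, pos_idx, axis=1)  # (B, P)
    g_pos = np.take_along_axis(G, pos_idx, axis=1)
    diff = S[:, None, :] - s_pos[:, :, None]  # diff[b,p,k] = s_k - s_pos
    sig = expit(alpha * diff)
    # sum over j != i: the k == pos entry contributes sigmoid(0) = 0.5
    pi = 1.0 + sig.sum(axis=2) - 0.5  # (B, P)

    safe_idcg = np.where(idcg > 0, idcg, 1.0)
    log1pi = np.log(1.0 + pi)
    contrib = mask * g_pos * LN2 / log1pi  # g / log2(1 + pi)
    approx_dcg = contrib.sum(axis=1)
    losses = np.where(idcg > 0, -approx_dcg / safe_idcg, 0.0)

    if want_grad:
        # c_p = -g_p f'(pi_p) / idcg with f(pi) = 1/log2(1+pi)  (c_p >= 0)
        c = mask * g_pos * LN2 / ((1.0 + pi) * log1pi**2)
        c = np.where(idcg[:, None] > 0, c / safe_idcg[:, None], 0.0)
        A = alpha * sig * (1.0 - sig)  # A[b,p,k] = alpha * sigmoid'(alpha (s_k - s_p))
        grad = np.einsum("bp,bpk->bk", c, A)
        # remove the k == pos self entry (sigmoid'(0) = 1/4) and add the
        # diagonal term dpi_p/ds_p = -sum_{j != p} A[p, j]
        rowsum = A.sum(axis=2) - 0.25 * alpha
        b_idx = np.repeat(np.arange(B), P)
        np.add.at(
            grad,
            (b_idx, pos_idx.ravel()),
            (-c * (0.25 * alpha + rowsum)).ravel(),
        )
    return losses, grad


def _mse_batch(
    S: np.ndarray, Y: np.ndarray, want_grad: bool
) -> tuple[np.ndarray, np.ndarray | None]:
    resid = S - Y
    losses = np.mean(resid**2, axis=1)
    grad = (2.0 / S.shape[1]) * resid if want_grad else None
    return losses, grad


def _loss_batch(
    S: np.ndarray, Y: np.ndarray, loss_cfg: LossConfig, want_grad: bool
) -> tuple[np.ndarray, np.ndarray | None]:
    if loss_cfg.loss == "approx_ndcg":
        return _approx_ndcg_batch(S, Y, loss_cfg, want_grad)
    return _mse_batch(S, Y, want_grad)


def approx_ndcg_loss(scored: ScoredList, config: LossConfig | None = None) -> float:
    """Listwise surrogate loss, in [-1, 0]; 0 when all labels are zero."""
    config = config or LossConfig()
    losses, _ = _approx_ndcg_batch(
        scored.scores[None, :], scored.labels[None, :], config, want_grad=False
    )
    return float(losses[0])


def mse_loss(scored: ScoredList) -> float:
    """Pointwise baseline loss: mean over diseases of (s_i - rel_i)^2."""
    losses, _ = _mse_batch(
        scored.scores[None, :], scored.labels[None, :], want_grad=False
    )
    return float(losses[0])


def gradient(scored: ScoredList, config: LossConfig | None = None) -> np.ndarray:
    """dLoss/dScores for the configured loss on one scored list."""
    config = config or LossConfig()
    _, grad = _loss_batch(
        scored.scores[None, :], scored.labels[None, :], config, want_grad=True
    )
    assert grad is not None
    return grad[0]


# ---------------------------------------------------------------------------
# Optimizers


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for p, g in zip(params, grads):
            p -= self.lr * g


# ---------------------------------------------------------------------------
# Model + Results (statsmodels-style)


@dataclass
class LearningCurves:
    """Per-epoch evaluation-function values on the train / validation splits."""

    epochs: list[int] = field(default_factory=list)
    train_ndcg: list[float] = field(default_factory=list)
    train_mse: list[float] = field(default_factory=list)
    val_ndcg: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, e in enumerate(self.epochs):
            rows.append(("train", e, self.train_ndcg[i], self.train_mse[i]))
            if self.val_ndcg:
                rows.append(("validation", e, self.val_ndcg[i], self.val_mse[i]))
        return pd.DataFrame(rows, columns=["split", "epoch", "ndcg", "mse"])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _split_eval(
    model: RankingModel, X: np.ndarray, Y: np.ndarray, metric: MetricConfig
) -> tuple[float, float]:
    S = model.forward_batch(X)
    vals = [ndcg(ScoredList(S[i], Y[i]), metric) for i in range(len(X))]
    return float(np.mean(vals)), float(np.mean((S - Y) ** 2))


class DiseaseRanker:
    """Listwise (or pointwise-baseline) diagnosis ranking model.

    Parameters
    ----------
    corpus
        Validated case corpus; its vocabularies fix the network dimensions.
    loss_config
        Training loss: the listwise ApproxNDCG surrogate (default) or the
        pointwise MSE baseline. Everything else about the two systems —
        network, data, optimizer — is identical, so a comparison isolates the
        loss function.
    train_config
        Optimizer and schedule; the seed controls initialization, the
        train/validation split and batch shuffling, so a fit is exactly
        reproducible.
    """

    def __init__(
        self,
        corpus: CaseCorpus,
        loss_config: LossConfig | None = None,
        train_config: TrainConfig | None = None,
    ) -> None:
        if len(corpus) == 0:
            raise ValueError("cannot build a model from an empty corpus")
        self.corpus = corpus
        self.loss_config = loss_config or LossConfig()
        self.train_config = train_config or TrainConfig()
        self.X, self.Y = densify_corpus(corpus)

    @classmethod
    def from_files(
        cls,
        corpus_path: str | Path,
        symptom_vocab_path: str | Path,
        disease_vocab_path: str | Path,
        loss_config: LossConfig | None = None,
        train_config: TrainConfig | None = None,
    ) -> "DiseaseRanker":
        from .casedata import read_corpus

        corpus = read_corpus(corpus_path, symptom_vocab_path, disease_vocab_path)
        return cls(corpus, loss_config, train_config)

    def fit(self) -> "RankerResults":
        cfg = self.train_config
        rng = np.random.default_rng(cfg.seed)
        n_cases = len(self.X)

        perm = rng.permutation(n_cases)
        n_val = int(round(cfg.validation_fraction * n_cases))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        if len(train_idx) == 0:
            raise ValueError("validation fraction leaves no training cases")
        Xtr, Ytr = self.X[train_idx], self.Y[train_idx]
        Xval, Yval = self.X[val_idx], self.Y[val_idx]

        model = RankingModel(
            n_symptoms=self.X.shape[1],
            n_diseases=self.Y.shape[1],
            hidden_dim=cfg.hidden_dim,
            seed=cfg.seed,
        )
        model.bind_vocabularies(self.corpus.symptom_vocab, self.corpus.disease_vocab)
        opt = (
            _Adam(model.parameters, cfg.learning_rate)
            if cfg.optimizer == "adam"
            else _SGD(model.parameters, cfg.learning_rate)
        )

        curves = LearningCurves()
        metric = self.loss_config.metric
        best: tuple[float, RankingModel] | None = None
        stale = 0
        for epoch in range(1, cfg.epochs + 1):
            order = rng.permutation(len(Xtr))
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                Xb, Yb = Xtr[idx], Ytr[idx]
                Sb = model.forward_batch(Xb)
                losses, dS = _loss_batch(Sb, Yb, self.loss_config, want_grad=True)
                if not np.all(np.isfinite(losses)):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}"
                    )
                assert dS is not None
                grads = model._backward(Xb, dS / len(idx))
                if cfg.weight_decay > 0:
                    # L2 decay on the weight matrices (not the biases) keeps
                    # the score scale bounded so the sigmoid comparisons in
                    # the listwise surrogate never saturate permanently
                    grads[0] += cfg.weight_decay * model.W1
                    grads[2] += cfg.weight_decay * model.W2
                opt.step(model.parameters, grads)

            tr_ndcg, tr_mse = _split_eval(model, Xtr, Ytr, metric)
            curves.epochs.append(epoch)
            curves.train_ndcg.append(tr_ndcg)
            curves.train_mse.append(tr_mse)
            if len(val_idx):
                va_ndcg, va_mse = _split_eval(model, Xval, Yval, metric)
                curves.val_ndcg.append(va_ndcg)
                curves.val_mse.append(va_mse)
                if cfg.early_stopping_patience is not None:
                    if best is None or va_ndcg > best[0]:
                        best, stale = (va_ndcg, model.copy()), 0
                    else:
                        stale += 1
                        if stale >= cfg.early_stopping_patience:
                            break

        if best is not None:
            model = best[1]
        return RankerResults(self, model, curves, train_idx, val_idx)


class RankerResults:
    """Fit results: trained network, learning curves, evaluation helpers."""

    def __init__(
        self,
        ranker: DiseaseRanker,
        model: RankingModel,
        curves: LearningCurves,
        train_idx: np.ndarray,
        val_idx: np.ndarray,
    ) -> None:
        self.ranker = ranker
        self.model = model
        self.curves = curves
        self.train_indices = train_idx
        self.val_indices = val_idx

    @property
    def loss_config(self) -> LossConfig:
        return self.ranker.loss_config

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return self.model.forward_batch(np.atleast_2d(X))

    def evaluate(
        self, X: np.ndarray, Y: np.ndarray, cutoffs: tuple[int, ...] = (5, 10, 20)
    ) -> dict[str, float]:
        """Evaluation functions (ndcg family + mse) averaged over the cases."""
        S = self.model.forward_batch(X)
        out: dict[str, float] = {}
        base = self.loss_config.metric
        for name, k in [("ndcg", None)] + [(f"ndcg@{k}", k) for k in cutoffs]:
            cfg = replace(base, k=k)
            out[name] = float(
                np.mean([ndcg(ScoredList(S[i], Y[i]), cfg) for i in range(len(X))])
            )
        out["mse"] = float(np.mean((S - Y) ** 2))
        return out

    def summary(self) -> str:
        cfg_t, cfg_l = self.ranker.train_config, self.loss_config
        tr = self.evaluate(
            self.ranker.X[self.train_indices], self.ranker.Y[self.train_indices]
        )
        lines = [
            "DiseaseRanker fit summary",
            "=" * 55,
            f"loss function:        {cfg_l.loss}"
            + (f" (alpha={cfg_l.alpha:g})" if cfg_l.loss == "approx_ndcg" else ""),
            f"network:              {self.model.n_symptoms} -> "
            f"{self.model.hidden_dim} (relu) -> {self.model.n_diseases}",
            f"cases (train / val):  {len(self.train_indices)} / {len(self.val_indices)}",
            f"optimizer:            {cfg_t.optimizer}, lr={cfg_t.learning_rate:g}, "
            f"batch={cfg_t.batch_size}, epochs trained={len(self.curves.epochs)}",
            f"seed:                 {cfg_t.seed}",
            "-" * 55,
            "training-split evaluation functions:",
        ]
        for k, v in tr.items():
            lines.append(f"  {k:<10} {v:.4f}")
        if self.curves.val_ndcg:
            lines.append(
                f"final validation:     ndcg={self.curves.val_ndcg[-1]:.4f}, "
                f"mse={self.curves.val_mse[-1]:.4f}"
            )
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        self.model.save(path)


def train(
    corpus: CaseCorpus,
    loss_cfg: LossConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> tuple[RankingModel, LearningCurves]:
    """Functional wrapper: fit a :class:`DiseaseRanker` on the corpus."""
    res = DiseaseRanker(corpus, loss_cfg, train_cfg).fit()
    return res.model, res.curves
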