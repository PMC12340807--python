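"""Per-position codon speed classification head.

A small fully connected network maps the protein-embedding vector at one
position to the probability that the codon used there is FAST.  The default
architecture is four hidden layers (128, 128, 64, 64) with ReLU activations
and 50% dropout after each hidden layer, a single sigmoid output, binary
cross entropy loss, and the Adam optimizer at learning rate 1e-4 with batch
size 128.  With 1280 input features this head has exactly 192,961 trainable
parameters.

Training is deterministic given the config seed: the input table is
canonically sorted before the seeded shuffling stream is applied, and
initialisation, shuffling and dropout all draw from seeded generators.

Cross-validation heads are trained per fold; at evaluation time each test
protein is scored by the head whose training folds exclude the fold of the
protein's 70%-identity homology cluster, so no head ever scores a sequence
homologous to its training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from codonspeed.corpus import TEST_FOLD
from codonspeed.io import EmbeddingStore


@dataclass
class HeadConfig:
    input_dim: int = 1280
    hidden_sizes: tuple[int, ...] = (128, 128, 64, 64)
    dropout: float = 0.5
    learning_rate: float = 1e-4
    batch_size: int = 128
    epochs: int = 60
    patience: int | None = None  # early stopping on validation loss, if given
    seed: int = 0

    def __post_init__(self):
        if not self.hidden_sizes:
            raise ValueError("hidden_sizes must be nonempty")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def count_parameters(config: HeadConfig) -> int:
    """Total trainable scalars: weights + biases over all consecutive layers."""
    dims = [config.input_dim, *config.hidden_sizes, 1]
    return sum(d_in * d_out + d_out for d_in, d_out in zip(dims[:-1], dims[1:]))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class FeedForwardHead:
    """Minimal fully connected binary classifier (ReLU + dropout + Adam)."""

    def __init__(self, config: HeadConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        dims = [config.input_dim, *config.hidden_sizes, 1]
        # He-normal initialisation, zero biases
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)).astype(np.float64)
            for d_in, d_out in zip(dims[:-1], dims[1:])
        ]
        self.b = [np.zeros(d_out) for d_out in dims[1:]]
        self._adam_t = 0
        self._m = [np.zeros_like(w) for w in self.W] + [np.zeros_like(b) for b in self.b]
        self._v = [np.zeros_like(w) for w in self.W] + [np.zeros_like(b) for b in self.b]
        # per-feature z-score normalisation, fitted on the training inputs
        self.x_mean: np.ndarray | None = None
        self.x_std: np.ndarray | None = None

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        if self.x_mean is None:
            return X
        return (X - self.x_mean) / self.x_std

    def _forward(self, X, dropout_rng=None):
        """Returns logits and the per-layer activations/masks for backprop."""
        a = X
        acts, masks = [X], []
        p = self.config.dropout
        for i in range(len(self.W) - 1):
            a = np.maximum(a @ self.W[i] + self.b[i], 0.0)
            if dropout_rng is not None and p > 0:
                mask = (dropout_rng.random(a.shape) >= p) / (1.0 - p)
                a = a * mask
            else:
                mask = None
            masks.append(mask)
            acts.append(a)
        logits = (a @ self.W[-1] + self.b[-1]).ravel()
        return logits, acts, masks

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._normalize(np.asarray(X, dtype=np.float64))
        logits, _, _ = self._forward(X)
        return _sigmoid(logits)

    @staticmethod
    def _bce(logits: np.ndarray, y: np.ndarray) -> float:
        # numerically stable mean BCE-with-logits
        return float(np.mean(np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))))

    def _adam_step(self, grads_W, grads_b):
        cfg = self.config
        self._adam_t += 1
        params = self.W + self.b
        grads = grads_W + grads_b
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            self._m[i] = beta1 * self._m[i] + (1 - beta1) * g
            self._v[i] = beta2 * self._v[i] + (1 - beta2) * g * g
            m_hat = self._m[i] / (1 - beta1**self._adam_t)
            v_hat = self._v[i] / (1 - beta2**self._adam_t)
            p -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

    def _train_batch(self, X, y, dropout_rng) -> float:
        logits, acts, masks = self._forward(X, dropout_rng)
        loss = self._bce(logits, y)
        n = len(y)
        delta = (_sigmoid(logits) - y)[:, None] / n  # dL/dlogits
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        grads_W[-1] = acts[-1].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        d = delta @ self.W[-1].T
        for i in range(len(self.W) - 2, -1, -1):
            if masks[i] is not None:
                d = d * masks[i]
            d = d * (acts[i + 1] > 0)
            grads_W[i] = acts[i].T @ d
            grads_b[i] = d.sum(axis=0)
            if i > 0:
                d = d @ self.W[i].T
        self._adam_step(grads_W, grads_b)
        return loss

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> list[float]:
        """Train; returns the per-epoch mean training loss trace."""
        cfg = self.config
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        self.x_mean = X.mean(axis=0)
        self.x_std = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        X = self._normalize(X)
        shuffle_rng = np.random.default_rng(cfg.seed + 1)
        dropout_rng = np.random.default_rng(cfg.seed + 2)
        trace: list[float] = []
        best_val, stall = np.inf, 0
        for _ in range(cfg.epochs):
            order = shuffle_rng.permutation(len(y))
            losses = []
            for start in range(0, len(y), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                losses.append(self._train_batch(X[idx], y[idx], dropout_rng))
            trace.append(float(np.mean(losses)))
            if cfg.patience is not None and X_val is not None:
                logits, _, _ = self._forward(self._normalize(np.asarray(X_val, dtype=np.float64)))
                val = self._bce(logits, np.asarray(y_val, dtype=np.float64))
                if val < best_val - 1e-6:
                    best_val, stall = val, 0
                else:
                    stall += 1
                    if stall >= cfg.patience:
                        break
        return trace


@dataclass
class TrainedHead:
    model: FeedForwardHead
    trained_folds: frozenset[int]
    loss_trace: list[float] = field(default_factory=list)


def save_head(head: TrainedHead, path) -> None:
    """Serialise a trained head (weights, normalisation, config) to .npz."""
    model = head.model
    arrays = {f"W{i}": w for i, w in enumerate(model.W)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.b)})
    arrays["x_mean"] = model.x_mean if model.x_mean is not None else np.zeros(0)
    arrays["x_std"] = model.x_std if model.x_std is not None else np.zeros(0)
    arrays["trained_folds"] = np.array(sorted(head.trained_folds), dtype=int)
    arrays["loss_trace"] = np.array(head.loss_trace)
    cfg = model.config
    arrays["config"] = np.array(
        [cfg.input_dim, *cfg.hidden_sizes, -1, cfg.seed], dtype=np.int64
    )
    arrays["config_f"] = np.array([cfg.dropout, cfg.learning_rate, cfg.batch_size, cfg.epochs])
    np.savez(path, **arrays)


def load_head(path) -> TrainedHead:
    data = np.load(path)
    cfg_i = data["config"]
    sep = int(np.flatnonzero(cfg_i == -1)[0])
    cfg = HeadConfig(
        input_dim=int(cfg_i[0]),
        hidden_sizes=tuple(int(h) for h in cfg_i[1:sep]),
        dropout=float(data["config_f"][0]),
        learning_rate=float(data["config_f"][1]),
        batch_size=int(data["config_f"][2]),
        epochs=int(data["config_f"][3]),
        seed=int(cfg_i[sep + 1]),
    )
    model = FeedForwardHead(cfg)
    model.W = [data[f"W{i}"] for i in range(len(model.W))]
    model.b = [data[f"b{i}"] for i in range(len(model.b))]
    if data["x_mean"].size:
        model.x_mean, model.x_std = data["x_mean"], data["x_std"]
    return TrainedHead(
        model=model,
        trained_folds=frozenset(int(f) for f in data["trained_folds"]),
        loss_trace=[float(x) for x in data["loss_trace"]],
    )


def _gather(table: pd.DataFrame, store: EmbeddingStore) -> tuple[np.ndarray, np.ndarray]:
    """Embedding matrix + FAST indicator, rows in canonical order."""
    table = table.sort_values(["protein_id", "position"], kind="mergesort")
    X = np.empty((len(table), store.dim), dtype=np.float64)
    offset = 0
    for pid, grp in table.groupby("protein_id", sort=True):
        try:
            X[offset : offset + len(grp)] = store.rows(pid, grp["position"].to_numpy())
        except KeyError as err:
            raise KeyError(f"missing embedding while gathering rows: {err}") from err
        offset += len(grp)
    y = (table["label"] == "FAST").to_numpy(float)
    return X, y


def train_head(
    balanced: pd.DataFrame,
    store: EmbeddingStore,
    config: HeadConfig,
    folds_to_use: set[int] | None = None,
) -> TrainedHead:
    """Train one head on the balanced rows of the given training folds."""
    rows = balanced[balanced["fold"] != TEST_FOLD]
    if folds_to_use is not None:
        rows = rows[rows["fold"].isin(folds_to_use)]
    if rows.empty:
        raise ValueError("no training rows for the requested folds")
    rows = rows.sort_values(["protein_id", "position"], kind="mergesort").reset_index(drop=True)
    X, y = _gather(rows, store)
    cfg = HeadConfig(**{**config.__dict__, "input_dim": store.dim})
    model = FeedForwardHead(cfg)
    trace = model.fit(X, y)
    used = folds_to_use if folds_to_use is not None else set(int(f) for f in rows["fold"].unique())
    return TrainedHead(model=model, trained_folds=frozenset(used), loss_trace=trace)


def train_cv_heads(
    balanced: pd.DataFrame,
    store: EmbeddingStore,
    config: HeadConfig,
    k_folds: int = 5,
) -> dict[int, TrainedHead]:
    """One head per held-out fold f, trained on all folds except f."""
    heads = {}
    for f in range(k_folds):
        folds = set(range(k_folds)) - {f}
        heads[f] = train_head(balanced, store, config, folds_to_use=folds)
    return heads


def predict_out_of_fold(
    table: pd.DataFrame,
    store: EmbeddingStore,
    heads: dict[int, TrainedHead],
    cluster_fold: dict[str, int],
) -> pd.DataFrame:
    """Score TEST positions with the head blind to each protein's cluster.

    ``cluster_fold`` maps protein id -> the fold its 70%-identity cluster
    was assigned to; the protein is scored by ``heads[that fold]``, whose
    training folds exclude it.  Returns a table with columns protein_id,
    position, score, fold_used.
    """
    test = table[table["fold"] == TEST_FOLD]
    out = []
    for pid, grp in test.groupby("protein_id", sort=True):
        if pid not in cluster_fold:
            raise KeyError(f"no cluster fold recorded for test protein {pid!r}")
        f = cluster_fold[pid]
        if f not in heads:
            raise KeyError(f"no head available for fold {f} (protein {pid!r})")
        if f in heads[f].trained_folds:
            raise ValueError(f"head for fold {f} was trained on its own fold")
        X = store.rows(pid, grp["position"].to_numpy())
        scores = heads[f].model.predict_proba(X)
        for (_, row), s in zip(grp.iterrows(), scores):
            out.append((pid, int(row["position"]), float(s), f))
    return pd.DataFrame(out, columns=["protein_id", "position", "score", "fold_used"])
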