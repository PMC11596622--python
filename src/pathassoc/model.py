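"""MLP binary classifier over concatenated compound (+) pathway features.

The model is a multi-layer perceptron with ReLU hidden layers, inverted
dropout, a single sigmoid output, and binary cross-entropy loss, trained
with Adam on raw (unscaled) count features.  Batches are assembled by a
block-gather: a batch of entry indices is mapped to compound rows and
pathway rows, the two sub-matrices are gathered in one slicing operation
each, densified, and concatenated -- equivalent, row for row, to
concatenating each entry's pair of vectors one at a time.

Follows the model/results idiom: :class:`AssociationMLP` is constructed
from a :class:`~pathassoc.dataset.PairDataset` plus an :class:`MLPConfig`;
``fit`` returns a :class:`FitResult` carrying the parameters, the
training-loss trace and prediction methods; ``fit_cv`` runs the repeated
stratified cross-validation analysis and returns a
:class:`~pathassoc.evaluation.CVResult`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import PairDataset, SplitPlan


class TrainingError(RuntimeError):
    """Training cannot proceed (single-class data, non-finite loss, ...)."""


@dataclass(frozen=True)
class MLPConfig:
    """Hyperparameters of the MLP classifier.

    Defaults are declared, desk-scale choices; all are configurable.
    ``threshold`` is the probability cutoff for the positive call, with the
    boundary counted as positive (``p >= threshold``).
    """

    hidden_sizes: tuple[int, ...] = (512, 128)
    dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 4096
    max_epochs: int = 20
    patience: int = 3
    min_loss_delta: float = 1e-4
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate and batch_size must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


def assemble_batch(ds: PairDataset, entry_indices: Sequence[int]) -> np.ndarray:
    """Dense ``len(indices) x (d_c + d_p)`` matrix of concatenated features.

    Row ``j`` is ``[compound_matrix[i_c(k_j)], pathway_matrix[i_p(k_j)]]``
    for entry index ``k_j``; identical to per-entry concatenation.
    Raises ``IndexError`` on an out-of-range entry index.
    """
    k = np.asarray(entry_indices, dtype=np.int64)
    i_c, i_p = ds.entry_pairs(k)
    left = np.asarray(ds.compound_matrix[i_c, :].todense(), dtype=np.float64)
    right = np.asarray(ds.pathway_matrix[i_p, :].todense(), dtype=np.float64)
    return np.hstack([left, right])


def _sigmoid(logits: np.ndarray) -> np.ndarray:
    out = np.empty_like(logits)
    pos = logits >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-logits[pos]))
    ez = np.exp(logits[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _init_params(
    dims: Sequence[int], rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        scale = np.sqrt(2.0 / fan_in)
        weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _forward(
    x: np.ndarray,
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    dropout: float,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, list]:
    """Logits plus the cache needed for backprop.

    ``rng`` enables inverted dropout on hidden activations (training mode);
    ``None`` disables it (inference).
    """
    cache = []
    h = x
    for layer, (w, b) in enumerate(zip(weights, biases)):
        z = h @ w + b
        if layer < len(weights) - 1:
            a = np.maximum(z, 0.0)
            if rng is not None and dropout > 0.0:
                mask = (rng.random(a.shape) >= dropout) / (1.0 - dropout)
                a = a * mask
            else:
                mask = None
            cache.append((h, z, mask))
            h = a
        else:
            cache.append((h, z, None))
    return z.ravel(), cache


def _backward(
    logits: np.ndarray,
    y: np.ndarray,
    weights: list[np.ndarray],
    cache: list,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    n = len(y)
    p = _sigmoid(logits)
    delta = ((p - y) / n)[:, None]  # d(mean BCE)/d(logits)
    grads_w = [np.empty(0)] * len(weights)
    grads_b = [np.empty(0)] * len(weights)
    for layer in range(len(weights) - 1, -1, -1):
        h_in, z, mask = cache[layer]
        grads_w[layer] = h_in.T @ delta
        grads_b[layer] = delta.sum(axis=0)
        if layer > 0:
            # gate by the previous hidden layer's ReLU derivative and dropout mask
            delta = delta @ weights[layer].T
            prev_z = cache[layer - 1][1]
            prev_mask = cache[layer - 1][2]
            delta = delta * (prev_z > 0.0)
            if prev_mask is not None:
                delta = delta * prev_mask
    return grads_w, grads_b


@dataclass
class FitResult:
    """A trained MLP: parameters, config echo, and the training-loss trace.

    ``predict`` is deterministic given the stored parameters.  A model
    trained for zero epochs keeps its zero-logit output head disabled and
    predicts probability 0.5 everywhere (the null model).
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    input_dim: int
    config: MLPConfig
    loss_trace: list[float] = field(default_factory=list)
    is_null: bool = False

    def predict_proba(
        self, ds: PairDataset, entry_indices: Sequence[int]
    ) -> np.ndarray:
        if ds.input_dim != self.input_dim:
            raise ValueError(
                f"dataset input dim {ds.input_dim} != model input dim "
                f"{self.input_dim}"
            )
        if self.is_null:
            return np.full(len(np.asarray(entry_indices)), 0.5)
        k = np.asarray(entry_indices, dtype=np.int64)
        out = np.empty(len(k))
        step = self.config.batch_size
        for start in range(0, len(k), step):
            x = assemble_batch(ds, k[start : start + step])
            logits, _ = _forward(x, self.weights, self.biases, 0.0, None)
            out[start : start + step] = _sigmoid(logits)
        return out

    def predict(
        self,
        ds: PairDataset,
        entry_indices: Sequence[int],
        threshold: float | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Probabilities and binary calls (``p >= threshold`` is positive)."""
        thr = self.config.threshold if threshold is None else threshold
        proba = self.predict_proba(ds, entry_indices)
        return proba, (proba >= thr).astype(np.uint8)

    def save(self, path: str | Path) -> None:
        """Checkpoint: one ``.npz`` of parameters + a JSON config sidecar."""
        path = Path(path)
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(path, n_layers=len(self.weights), **arrays)
        sidecar = {
            "input_dim": self.input_dim,
            "config": asdict(self.config),
            "loss_trace": self.loss_trace,
            "is_null": self.is_null,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FitResult":
        path = Path(path)
        with np.load(path if path.suffix else path.with_suffix(".npz")) as data:
            n = int(data["n_layers"])
            weights = [data[f"w{i}"] for i in range(n)]
            biases = [data[f"b{i}"] for i in range(n)]
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = dict(meta["config"])
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        return cls(
            weights=weights,
            biases=biases,
            input_dim=meta["input_dim"],
            config=MLPConfig(**cfg),
            loss_trace=meta["loss_trace"],
            is_null=meta["is_null"],
        )

    def summary(self) -> str:
        n_params = sum(w.size for w in self.weights) + sum(b.size for b in self.biases)
        lines = [
            "AssociationMLP fit",
            f"  input dim:        {self.input_dim}",
            f"  hidden layers:    {list(self.config.hidden_sizes)}",
            f"  parameters:       {n_params}",
            f"  epochs run:       {len(self.loss_trace)}",
        ]
        if self.loss_trace:
            lines.append(f"  final train loss: {self.loss_trace[-1]:.6f}")
        if self.is_null:
            lines.append("  (null model: trained for zero epochs)")
        return "\n".join(lines)


class AssociationMLP:
    """Compound-pathway association classifier bound to a pair dataset.

    Parameters
    ----------
    dataset : PairDataset
        The cross-join dataset supplying features and labels.
    config : MLPConfig, optional
        Hyperparameters; defaults are used when omitted.
    """

    def __init__(self, dataset: PairDataset, config: MLPConfig | None = None):
        self.dataset = dataset
        self.config = config or MLPConfig()

    def fit(self, plan: SplitPlan | None = None) -> FitResult:
        """Train on ``plan.train_indices`` (or on every entry if no plan).

        Mini-batch Adam on mean binary cross-entropy; the epoch order is
        shuffled by a generator seeded from ``config.seed``, so a rerun
        with the same config reproduces the same parameters.  Stops early
        when the epoch loss has not improved by ``min_loss_delta`` for
        ``patience`` consecutive epochs.

        Raises
        ------
        TrainingError
            Single-class training labels, or a non-finite loss.
        """
        ds, cfg = self.dataset, self.config
        if plan is None:
            train_idx = np.arange(ds.n_entries)
        else:
            train_idx = np.asarray(plan.train_indices, dtype=np.int64)
        if train_idx.size == 0:
            raise TrainingError("empty training index set")
        y = ds.entry_labels(train_idx).astype(np.float64)
        if y.min() == y.max():
            raise TrainingError(
                "training labels are single-class; both classes are required"
            )

        dims = [ds.input_dim, *cfg.hidden_sizes, 1]
        rng = np.random.default_rng(cfg.seed)
        weights, biases = _init_params(dims, rng)
        if cfg.max_epochs == 0:
            return FitResult(
                weights=weights,
                biases=biases,
                input_dim=ds.input_dim,
                config=cfg,
                loss_trace=[],
                is_null=True,
            )

        m_w = [np.zeros_like(w) for w in weights]
        v_w = [np.zeros_like(w) for w in weights]
        m_b = [np.zeros_like(b) for b in biases]
        v_b = [np.zeros_like(b) for b in biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        loss_trace: list[float] = []
        best_loss = np.inf
        stale = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(train_idx.size)
            epoch_loss = 0.0
            for start in range(0, train_idx.size, cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                x = assemble_batch(ds, train_idx[sel])
                yb = y[sel]
                logits, cache = _forward(x, weights, biases, cfg.dropout, rng)
                # numerically stable BCE-with-logits
                loss = float(
                    np.mean(
                        np.maximum(logits, 0.0)
                        - logits * yb
                        + np.log1p(np.exp(-np.abs(logits)))
                    )
                )
                if not np.isfinite(loss):
                    raise TrainingError(
                        f"non-finite training loss at epoch {epoch}; "
                        "lower the learning rate"
                    )
                epoch_loss += loss * len(sel)
                grads_w, grads_b = _backward(logits, yb, weights, cache)
                t += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
                for layer in range(len(weights)):
                    m_w[layer] = beta1 * m_w[layer] + (1 - beta1) * grads_w[layer]
                    v_w[layer] = beta2 * v_w[layer] + (1 - beta2) * grads_w[layer] ** 2
                    weights[layer] -= lr_t * m_w[layer] / (np.sqrt(v_w[layer]) + eps)
                    m_b[layer] = beta1 * m_b[layer] + (1 - beta1) * grads_b[layer]
                    v_b[layer] = beta2 * v_b[layer] + (1 - beta2) * grads_b[layer] ** 2
                    biases[layer] -= lr_t * m_b[layer] / (np.sqrt(v_b[layer]) + eps)
            epoch_loss /= train_idx.size
            loss_trace.append(epoch_loss)
            if epoch_loss < best_loss - cfg.min_loss_delta:
                best_loss = epoch_loss
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        return FitResult(
            weights=weights,
            biases=biases,
            input_dim=ds.input_dim,
            config=cfg,
            loss_trace=loss_trace,
        )

    def fit_cv(
        self,
        n_iterations: int = 200,
        test_fraction: float = 0.1,
        base_seed: int = 0,
    ):
        """Repeated stratified CV; see :func:`pathassoc.evaluation.run_cv`."""
        from .evaluation import run_cv

        return run_cv(
            self.dataset,
            self.config,
            n_iterations=n_iterations,
            test_fraction=test_fraction,
            base_seed=base_seed,
        )


def train(ds: PairDataset, plan: SplitPlan | None, cfg: MLPConfig) -> FitResult:
    """Functional wrapper over :meth:`AssociationMLP.fit`."""
    return AssociationMLP(ds, cfg).fit(plan)


def predict(
    model: FitResult,
    ds: PairDataset,
    entry_indices: Sequence[int],
    threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper over :meth:`FitResult.predict`."""
    return model.predict(ds, entry_indices, threshold)
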