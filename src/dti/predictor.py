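"""The interaction classifier shared by both pipelines.

One architecture serves both models: the direct pipeline (DEDTI) scores
the concatenation [d ‖ t] of raw feature vectors (length m+n) and the
embedding pipeline (IEDTI) scores concatenated embeddings (length
f1+f2 = 512).  The network treats the input as a 1-channel sequence:

    4 × [Conv1D → ReLU → batch norm → dropout]
    → flatten → dense (ReLU) → dropout → dense(1, sigmoid)

trained with Adam on binary cross-entropy.  The output neuron's bias is
preset to ln(positives/negatives) so the untrained classifier predicts
the class prior — the initial-bias trick for imbalanced data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, DimensionError, ValidationError

__all__ = [
    "PredictorConfig",
    "PairSample",
    "PredictorModel",
    "initial_bias",
    "build_predictor",
    "train_predictor",
    "predict_scores",
    "score_matrix",
]


def initial_bias(positive_count: int, negative_count: int) -> float:
    """ln(positives/negatives); the untrained sigmoid then outputs the prior."""
    if positive_count <= 0 or negative_count <= 0:
        raise ValidationError("both class counts must be positive")
    return float(np.log(positive_count / negative_count))


@dataclass
class PredictorConfig:
    """Hyperparameters of the Conv1D interaction classifier.

    Defaults are full-scale (batch 1024 for the direct model; pass 64
    for the embedding model).  Filter counts, kernel and stride are this
    package's own defaults — stride 2 keeps the flattened width
    tractable for both the 2220-long and 512-long inputs.
    """

    input_length: int
    conv_filters: tuple = (32, 64, 128, 256)
    conv_kernel: int = 5
    conv_stride: int = 2
    dropout: float = 0.5
    dense_width: int = 512
    batch_size: int = 1024
    epochs: int = 100
    learning_rate: float = 1e-3
    initial_bias: float = 0.0
    seed: int = 0
    early_stopping: bool = False
    val_fraction: float = 0.1
    patience: int = 10

    def conv_lengths(self):
        """Sequence length after each convolution stage."""
        lengths, L = [], self.input_length
        for _ in self.conv_filters:
            L = nn.Conv1D.out_length(L, self.conv_kernel, self.conv_stride)
            lengths.append(L)
        return lengths

    def validate(self) -> "PredictorConfig":
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must lie in [0, 1)")
        if len(self.conv_filters) != 4:
            raise ConfigurationError("the classifier has exactly four conv stages")
        if self.input_length < 2:
            raise ConfigurationError("input_length must be >= 2")
        if self.conv_lengths()[-1] < 1:
            raise ConfigurationError(
                f"input_length {self.input_length} too short for four "
                f"kernel-{self.conv_kernel} stride-{self.conv_stride} stages"
            )
        return self


@dataclass
class PairSample:
    """One (drug, target) training pair with its concatenated feature."""

    drug_index: int
    target_index: int
    label: int
    feature: np.ndarray


class PredictorModel:
    """Conv1D classifier wrapper holding the network and its config."""

    def __init__(self, net: nn.Sequential, config: PredictorConfig):
        self.net = net
        self.config = config
        self.loss_history: list = []

    @property
    def input_length(self) -> int:
        return self.config.input_length

    def logits(self, X, train=False):
        X = np.asarray(X, dtype=nn.F32)
        if X.ndim != 2 or X.shape[1] != self.input_length:
            raise DimensionError(
                f"input width {X.shape[-1]} != configured {self.input_length}"
            )
        z = self.net.forward(X[:, :, None], train=train)
        return z[:, 0]

    def predict(self, X, batch_size=4096):
        """Probabilities in (0,1); inference mode (dropout off, BN frozen)."""
        X = np.asarray(X, dtype=nn.F32)
        out = np.empty(X.shape[0], dtype=np.float64)
        for start in range(0, X.shape[0], batch_size):
            z = self.logits(X[start:start + batch_size], train=False)
            out[start:start + batch_size] = nn.sigmoid(z.astype(np.float64))
        return np.clip(out, 1e-12, 1.0 - 1e-12)

    def save(self, path) -> None:
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in asdict(self.config).items()}
        np.savez(path, config_json=np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8),
            **{f"arr_{i}": a for i, a in enumerate(self.net.get_state())})

    @classmethod
    def load(cls, path) -> "PredictorModel":
        data = np.load(path, allow_pickle=False)
        cfg = json.loads(bytes(data["config_json"]).decode())
        cfg["conv_filters"] = tuple(cfg["conv_filters"])
        model = build_predictor(PredictorConfig(**cfg))
        n = len(model.net.get_state())
        model.net.set_state([data[f"arr_{i}"] for i in range(n)])
        return model


def build_predictor(config: PredictorConfig) -> PredictorModel:
    """Construct the (untrained) classifier described in the module docs.

    The output layer's weights are initialized at small scale (std 0.01)
    so the preset bias alone determines the initial mean prediction —
    the calibration the initial-bias trick exists to provide.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    drop_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    layers, in_ch = [], 1
    for filters in config.conv_filters:
        layers += [
            nn.Conv1D(in_ch, filters, config.conv_kernel, config.conv_stride, rng),
            nn.ReLU(),
            nn.BatchNorm(filters),
            nn.Dropout(config.dropout, drop_rng),
        ]
        in_ch = filters
    flat_width = config.conv_lengths()[-1] * config.conv_filters[-1]
    layers += [
        nn.Flatten(),
        nn.Dense(flat_width, config.dense_width, rng),
        nn.ReLU(),
        nn.Dropout(config.dropout, drop_rng),
        nn.Dense(config.dense_width, 1, rng, w_std=0.01,
                 bias_init=config.initial_bias),
    ]
    return PredictorModel(nn.Sequential(layers), config)


def _unpack_samples(samples):
    if isinstance(samples, tuple) and len(samples) == 2:
        X, y = samples
    else:
        samples = list(samples)
        X = np.stack([s.feature for s in samples])
        y = np.array([s.label for s in samples], dtype=float)
    X = np.asarray(X, dtype=nn.F32)
    y = np.asarray(y, dtype=np.float64)
    return X, y


def train_predictor(model: PredictorModel, samples, config: PredictorConfig = None):
    """Minimize binary cross-entropy with Adam; returns (model, loss history).

    ``samples`` is either a list of :class:`PairSample` or a tuple
    (features 2-D array, binary labels).  Shuffling, dropout and the
    optional early stopping (10% validation split, configurable
    patience, best weights restored) are all seeded, so fixed inputs and
    seed give a bit-identical loss history.
    """
    config = config or model.config
    X, y = _unpack_samples(samples)
    if np.unique(y).size < 2:
        raise ValidationError("training set must contain both classes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    idx = np.arange(X.shape[0])
    val_idx = np.array([], dtype=int)
    if config.early_stopping:
        perm = rng.permutation(idx)
        n_val = max(1, int(round(config.val_fraction * idx.size)))
        val_idx, idx = perm[:n_val], perm[n_val:]

    if not hasattr(model, "_opt"):
        model._opt = nn.Adam(model.net.params(), model.net.grads(),
                             lr=config.learning_rate)
    best_val, best_state, since_best = np.inf, None, 0
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(idx)
        epoch_losses = []
        for start in range(0, order.size, config.batch_size):
            batch = order[start:start + config.batch_size]
            if batch.size < 2:
                continue
            z = model.logits(X[batch], train=True)
            loss, gz = nn.bce_with_logits(z, y[batch])
            model.net.backward(gz[:, None])
            model._opt.step()
            epoch_losses.append(loss)
        history.append(float(np.mean(epoch_losses)))
        if config.early_stopping:
            zv = model.logits(X[val_idx], train=False)
            val_loss, _ = nn.bce_with_logits(zv, y[val_idx])
            if val_loss < best_val - 1e-12:
                best_val, best_state, since_best = val_loss, model.net.get_state(), 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    if config.early_stopping and best_state is not None:
        model.net.set_state(best_state)
    model.loss_history = history
    return model, history


def predict_scores(model: PredictorModel, pairs, drug_vectors, target_vectors):
    """Score (drug_index, target_index) pairs; concatenation is drug-first."""
    D = np.asarray(drug_vectors, dtype=nn.F32)
    T = np.asarray(target_vectors, dtype=nn.F32)
    if D.shape[1] + T.shape[1] != model.input_length:
        raise DimensionError(
            f"drug width {D.shape[1]} + target width {T.shape[1]} != "
            f"model input {model.input_length}"
        )
    pairs = np.asarray(list(pairs), dtype=int).reshape(-1, 2)
    X = np.concatenate([D[pairs[:, 0]], T[pairs[:, 1]]], axis=1)
    return model.predict(X)


def score_matrix(model: PredictorModel, drug_vectors, target_vectors,
                 batch_rows=64):
    """Score every (drug, target) pair; returns an m×n matrix in (0,1)."""
    D = np.asarray(drug_vectors, dtype=nn.F32)
    T = np.asarray(target_vectors, dtype=nn.F32)
    m, n = D.shape[0], T.shape[0]
    out = np.empty((m, n), dtype=np.float64)
    cols = np.arange(n)
    for start in range(0, m, batch_rows):
        rows = np.arange(start, min(start + batch_rows, m))
        pairs = np.stack(np.meshgrid(rows, cols, indexing="ij"), axis=-1).reshape(-1, 2)
        out[rows[0]:rows[-1] + 1] = predict_scores(
            model, pairs, D, T).reshape(rows.size, n)
    return out
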