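"""Triplet-loss embedding of feature vectors (the IEDTI embedders).

A feed-forward network maps each entity's accumulated-similarity feature
vector (width m for drugs, n for targets) to a compact embedding
(default 256-d) such that entities sharing a k-means pseudo-label end up
close in squared-Euclidean distance and members of other clusters end up
at least a margin γ farther away.

Embeddings are L2-normalized by default (the usual head for semi-hard
triplet training); the margin then lives on the unit sphere.

Mining is batch-wise semi-hard: for every (anchor, positive) pair all
negatives farther than the positive but within the margin are mined; if
none exists, the hardest (closest) negative stands in.  The loss is the
mean hinge max(0, γ + d(a,p) − d(a,n)) over the mined triplets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import DimensionError, MiningError, ValidationError
from .labeling import ClusterAssignment
from .preprocess import FeatureMatrix

__all__ = [
    "TripletConfig",
    "EmbeddingMatrix",
    "Embedder",
    "triplet_loss",
    "train_embedder",
    "embed_features",
]


@dataclass
class TripletConfig:
    margin: float = 1.0
    embedding_dim: int = 256
    hidden_widths: tuple = (512, 256)
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-3
    normalize: bool = True
    seed: int = 0

    def validate(self) -> "TripletConfig":
        if self.margin < 0:
            raise ValidationError("margin must be non-negative")
        if self.embedding_dim < 1:
            raise ValidationError("embedding_dim must be >= 1")
        return self


@dataclass
class EmbeddingMatrix:
    values: np.ndarray
    entity_kind: str = ""


def _as_array(x):
    if isinstance(x, FeatureMatrix):
        return np.asarray(x.values, dtype=np.float64)
    return np.asarray(x, dtype=np.float64)


def _squared_distances(E):
    sq = np.sum(E * E, axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (E @ E.T)
    np.fill_diagonal(D2, 0.0)
    return np.maximum(D2, 0.0)


def _mine(E, labels, margin):
    """Semi-hard mining over one batch.

    Returns (loss, coefficient matrix C, triplet count).  C accumulates
    +1 at (a, p) and −1 at (a, n) for every active mined triplet, so the
    gradient of the mean hinge w.r.t. the embeddings is
    (2/N) * (diag(S·1) − S) E with S = C + Cᵀ.
    """
    B = E.shape[0]
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    neg_mask = ~same
    if not neg_mask.any():
        raise MiningError("triplet mining needs at least two classes in the batch")
    pos_mask = same & ~np.eye(B, dtype=bool)
    D2 = _squared_distances(E)

    dap = D2[:, :, None]
    dan = D2[:, None, :]
    semi = (pos_mask[:, :, None] & neg_mask[:, None, :]
            & (dan > dap) & (dan < dap + margin))
    hinge = margin + dap - dan

    C = np.zeros((B, B))
    loss_sum = float(hinge[semi].sum())
    n_triplets = int(semi.sum())
    C += semi.sum(axis=2)          # (a, p) appearances, all active
    C -= semi.sum(axis=1)          # (a, n) appearances

    # fallback: (a, p) pairs without any semi-hard negative take the
    # hardest (closest) negative of the anchor
    fb_a, fb_p = np.nonzero(pos_mask & ~semi.any(axis=2))
    if fb_a.size:
        d2neg = np.where(neg_mask, D2, np.inf)
        hard_n = d2neg.argmin(axis=1)
        fb_n = hard_n[fb_a]
        fb_hinge = margin + D2[fb_a, fb_p] - D2[fb_a, fb_n]
        loss_sum += float(np.maximum(fb_hinge, 0.0).sum())
        n_triplets += fb_a.size
        act = fb_hinge > 0
        np.add.at(C, (fb_a[act], fb_p[act]), 1.0)
        np.add.at(C, (fb_a[act], fb_n[act]), -1.0)

    if n_triplets == 0:
        return 0.0, C, 0
    return loss_sum / n_triplets, C, n_triplets


def triplet_loss(embeddings, labels, margin: float) -> float:
    """Mean semi-hard triplet hinge loss over one batch of embeddings."""
    E = np.asarray(embeddings, dtype=np.float64)
    loss, _, _ = _mine(E, labels, margin)
    return loss


def _triplet_grad(E, labels, margin):
    loss, C, n = _mine(E, labels, margin)
    if n == 0:
        return loss, np.zeros_like(E)
    S = C + C.T
    grad = (2.0 / n) * (S.sum(axis=1)[:, None] * E - S @ E)
    return loss, grad


class Embedder:
    """A trained feature→embedding transform (one of the IEDTI DNNs)."""

    def __init__(self, model: nn.Sequential, input_dim: int, config: TripletConfig,
                 entity_kind: str = ""):
        self.model = model
        self.input_dim = input_dim
        self.config = config
        self.entity_kind = entity_kind
        self.final_loss = float("nan")

    def transform(self, features) -> EmbeddingMatrix:
        F = _as_array(features)
        if F.ndim != 2 or F.shape[1] != self.input_dim:
            raise DimensionError(
                f"feature width {F.shape[-1]} != embedder input {self.input_dim}"
            )
        E = self.model.forward(F.astype(nn.F32), train=False)
        return EmbeddingMatrix(values=np.asarray(E, dtype=np.float64),
                               entity_kind=self.entity_kind)

    def save(self, path) -> None:
        cfg = self.config
        np.savez(
            path,
            input_dim=self.input_dim,
            entity_kind=self.entity_kind,
            final_loss=self.final_loss,
            margin=cfg.margin, embedding_dim=cfg.embedding_dim,
            hidden_widths=np.asarray(cfg.hidden_widths), epochs=cfg.epochs,
            batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
            normalize=cfg.normalize, seed=cfg.seed,
            **{f"arr_{i}": a for i, a in enumerate(self.model.get_state())},
        )

    @classmethod
    def load(cls, path) -> "Embedder":
        data = np.load(path, allow_pickle=False)
        cfg = TripletConfig(
            margin=float(data["margin"]),
            embedding_dim=int(data["embedding_dim"]),
            hidden_widths=tuple(int(w) for w in data["hidden_widths"]),
            epochs=int(data["epochs"]), batch_size=int(data["batch_size"]),
            learning_rate=float(data["learning_rate"]),
            normalize=bool(data["normalize"]), seed=int(data["seed"]),
        )
        emb = cls(_build_mlp(int(data["input_dim"]), cfg),
                  int(data["input_dim"]), cfg, str(data["entity_kind"]))
        n = len(emb.model.get_state())
        emb.model.set_state([data[f"arr_{i}"] for i in range(n)])
        emb.final_loss = float(data["final_loss"])
        return emb


def _build_mlp(input_dim: int, config: TripletConfig) -> nn.Sequential:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    layers, fan_in = [], input_dim
    for width in config.hidden_widths:
        layers += [nn.Dense(fan_in, width, rng), nn.ReLU()]
        fan_in = width
    layers.append(nn.Dense(fan_in, config.embedding_dim, rng))
    if config.normalize:
        layers.append(nn.L2Normalize())
    return nn.Sequential(layers)


def _balanced_batches(labels, batch_size, rng):
    """Class-balanced batch index sampler (PK-style).

    Each batch draws up to batch_size // n_classes members per cluster
    (with replacement inside small clusters) so mining never starves.
    """
    classes = np.unique(labels)
    per_class = max(2, batch_size // classes.size)
    n_batches = max(1, int(np.ceil(labels.size / (per_class * classes.size))))
    members = {c: np.flatnonzero(labels == c) for c in classes}
    for _ in range(n_batches):
        idx = np.concatenate([
            rng.choice(members[c], size=min(per_class, members[c].size),
                       replace=False)
            if members[c].size >= 2 else members[c]
            for c in classes
        ])
        yield idx


def train_embedder(features, labels, config: TripletConfig,
                   entity_kind: str = "") -> Embedder:
    """Train an embedding MLP by minimizing the semi-hard triplet loss.

    ``labels`` may be a :class:`ClusterAssignment` or a plain label
    array with at least two clusters.  Training is fully seeded; the
    final-epoch mean loss is stored on the returned :class:`Embedder`.
    """
    config.validate()
    F = _as_array(features)
    lab = labels.labels if isinstance(labels, ClusterAssignment) else np.asarray(labels)
    if lab.size != F.shape[0]:
        raise DimensionError("labels length must match feature rows")
    if np.unique(lab).size < 2:
        raise MiningError("triplet training needs at least two clusters")

    model = _build_mlp(F.shape[1], config)
    opt = nn.Adam(model.params(), model.grads(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    Ff = F.astype(nn.F32)

    embedder = Embedder(model, F.shape[1], config, entity_kind)
    for _ in range(config.epochs):
        losses = []
        for idx in _balanced_batches(lab, config.batch_size, rng):
            E = model.forward(Ff[idx], train=True)
            loss, gradE = _triplet_grad(np.asarray(E, dtype=np.float64), lab[idx],
                                        config.margin)
            model.backward(gradE.astype(nn.F32))
            opt.step()
            losses.append(loss)
        embedder.final_loss = float(np.mean(losses))
    return embedder


def embed_features(model: Embedder, features) -> EmbeddingMatrix:
    """Row-wise application of a trained embedder."""
    return model.transform(features)
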