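"""Synthetic heterogeneous DTI bundles with planted structure.

The generator emulates the statistical shape of a real bundle under the
guilt-by-association premise: drugs (targets) fall into latent clusters,
entities of one cluster share a signature block of attributes (diseases,
side effects), native similarity matrices reflect the same clusters, and
interactions are enriched inside favored (drug-cluster, target-cluster)
blocks.  Ground truth (cluster labels, favored blocks) is returned so
every downstream stage is testable without any download.

All randomness flows from the single spec seed through named substreams
(attributes, similarities, interactions), so fixing the seed fixes the
bundle bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .matrixio import MatrixBundle

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_bundle",
    "generate_cluster_features",
]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    Defaults mirror the fixture regime used throughout the test suite:
    cluster counts 4 (drugs) and 5 (targets), two drug-association and
    one target-association matrix as in the DTINet inventory, and an
    interaction density a couple of orders denser than DTINet's 0.18%
    so the signal is learnable at desk scale.
    """

    m: int = 150
    n: int = 300
    n_attributes: int = 400
    k_drug: int = 4
    k_target: int = 5
    attribute_sharing: float = 0.6
    background_rate: float = 0.02
    interaction_block_prob: float = 0.35
    interaction_noise: float = 0.01
    similarity_jitter: float = 0.01
    n_drug_association: int = 2
    n_target_association: int = 1
    n_drug_similarity: int = 2
    n_target_similarity: int = 2
    seed: int = 0

    def validate(self) -> "SyntheticSpec":
        for name in ("attribute_sharing", "background_rate",
                     "interaction_block_prob", "interaction_noise"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")
        if not (1 <= self.k_drug <= self.m):
            raise ValidationError("k_drug must be in 1..m")
        if not (1 <= self.k_target <= self.n):
            raise ValidationError("k_target must be in 1..n")
        if self.n_attributes < max(self.k_drug, self.k_target):
            raise ValidationError(
                "n_attributes too small for disjoint signature blocks"
            )
        return self


@dataclass
class GroundTruth:
    """Planted structure: cluster labels and favored interaction blocks."""

    drug_labels: np.ndarray
    target_labels: np.ndarray
    favored_blocks: list = field(default_factory=list)


def _cluster_labels(count: int, k: int) -> np.ndarray:
    """Contiguous labels with sizes as equal as divisibility allows."""
    base, extra = divmod(count, k)
    sizes = [base + (1 if c < extra else 0) for c in range(k)]
    return np.repeat(np.arange(k), sizes)


def _association_matrix(labels, k, n_attributes, sharing, background, rng):
    """Bernoulli attribute matrix: each cluster owns a disjoint signature
    attribute block carried with prob `sharing`; everything else appears
    with prob `background`."""
    width = n_attributes // k
    P = np.full((labels.size, n_attributes), background)
    for c in range(k):
        block = slice(c * width, (c + 1) * width)
        P[labels == c, block] = sharing
    return (rng.random(P.shape) < P).astype(float)


def _similarity_matrix(labels, jitter, rng):
    """Cosine similarity of cluster-signature profiles plus symmetric
    jitter: 1 within clusters, 0 across, clipped to [0, 1], diagonal 1."""
    base = (labels[:, None] == labels[None, :]).astype(float)
    E = rng.normal(0.0, jitter, size=base.shape)
    S = np.clip(base + (E + E.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def generate_bundle(spec: SyntheticSpec):
    """Generate a bundle plus its ground truth from a :class:`SyntheticSpec`.

    Returns
    -------
    (MatrixBundle, GroundTruth)
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_attr, rng_sim, rng_int = (np.random.default_rng(s) for s in ss.spawn(3))

    drug_labels = _cluster_labels(spec.m, spec.k_drug)
    target_labels = _cluster_labels(spec.n, spec.k_target)
    favored = [(c, c) for c in range(min(spec.k_drug, spec.k_target))]

    drug_assoc = [
        _association_matrix(drug_labels, spec.k_drug, spec.n_attributes,
                            spec.attribute_sharing, spec.background_rate, rng_attr)
        for _ in range(spec.n_drug_association)
    ]
    target_assoc = [
        _association_matrix(target_labels, spec.k_target, spec.n_attributes,
                            spec.attribute_sharing, spec.background_rate, rng_attr)
        for _ in range(spec.n_target_association)
    ]
    drug_sim = [_similarity_matrix(drug_labels, spec.similarity_jitter, rng_sim)
                for _ in range(spec.n_drug_similarity)]
    target_sim = [_similarity_matrix(target_labels, spec.similarity_jitter, rng_sim)
                  for _ in range(spec.n_target_similarity)]

    P = np.full((spec.m, spec.n), spec.interaction_noise)
    for cd, ct in favored:
        P[np.ix_(drug_labels == cd, target_labels == ct)] = spec.interaction_block_prob
    X = (rng_int.random(P.shape) < P).astype(float)

    bundle = MatrixBundle(
        X=X,
        drug_similarity_inputs=drug_sim,
        drug_association_inputs=drug_assoc,
        target_similarity_inputs=target_sim,
        target_association_inputs=target_assoc,
    ).validate()
    truth = GroundTruth(drug_labels=drug_labels, target_labels=target_labels,
                        favored_blocks=favored)
    return bundle, truth


def generate_cluster_features(n_entities=120, k=4, n_features=16,
                              radii=(10.0, 20.0, 40.0, 80.0), spread=1.0,
                              seed=0):
    """Gaussian clusters with irregular, pairwise-distinct separations.

    Cluster c sits at radius ``radii[c]`` along its own orthogonal axis,
    so no two inter-cluster distances coincide and no balanced merge of
    clusters is as tight as the planted partition — the geometry under
    which a cluster-size balance criterion identifies the true k.
    Returns (features, labels) with equal cluster sizes (up to
    divisibility).
    """
    if k > len(radii):
        raise ValidationError("need one radius per cluster")
    if n_features < k:
        raise ValidationError("n_features must be at least k")
    rng = np.random.default_rng(seed)
    labels = _cluster_labels(n_entities, k)
    centers = np.zeros((k, n_features))
    for c in range(k):
        centers[c, c] = radii[c]
    features = centers[labels] + rng.normal(0.0, spread, (n_entities, n_features))
    return features, labels
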