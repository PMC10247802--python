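"""Similarity conversion and accumulation.

Association matrices (drug-disease, drug-side-effect, target-disease) are
converted to entity-by-entity cosine-similarity matrices; each side's
similarity matrices are then summed element-wise into one feature matrix
per side (D for drugs, T for targets).  Row i of D is the feature vector
of drug i; likewise for targets.  Summation rather than concatenation
keeps the feature space dense and of fixed width m (or n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, ValidationError
from .matrixio import MatrixBundle

__all__ = [
    "SimilarityMatrix",
    "FeatureMatrix",
    "cosine_similarity_matrix",
    "accumulate_features",
    "build_feature_matrices",
]


@dataclass
class SimilarityMatrix:
    """A square pairwise-similarity matrix with its originating role."""

    values: np.ndarray
    source_role: str = ""


@dataclass
class FeatureMatrix:
    """Element-wise sum of per-side similarity matrices.

    ``values`` is m×m for drugs or n×n for targets; row i is the feature
    vector of entity i.  Entries lie in [0, n_summands] when every
    summand lies in [0, 1].
    """

    values: np.ndarray
    n_summands: int = 1

    @property
    def shape(self):
        return self.values.shape


def cosine_similarity_matrix(O, source_role: str = "") -> SimilarityMatrix:
    """Pairwise cosine similarity of the rows of an entity×attribute matrix.

    Entry (k, l) is dot(row_k, row_l) / (||row_k|| ||row_l||).  Rows of
    zero norm get off-diagonal similarity 0; the diagonal is set to 1 for
    every row so self-similarity is maximal and downstream sums stay
    finite.
    """
    O = np.asarray(O, dtype=float)
    if O.ndim != 2 or O.shape[0] < 1:
        raise ValidationError("input must be a 2-D matrix with at least one row")
    if not np.all(np.isfinite(O)):
        raise ValidationError("input contains non-finite entries")
    norms = np.linalg.norm(O, axis=1)
    denom = np.outer(norms, norms)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(denom > 0, (O @ O.T) / denom, 0.0)
    R = (R + R.T) / 2.0  # remove floating-point asymmetry
    np.fill_diagonal(R, 1.0)
    return SimilarityMatrix(values=R, source_role=source_role)


def accumulate_features(similarities) -> FeatureMatrix:
    """Element-wise sum of a non-empty list of same-shape square matrices."""
    mats = [s.values if isinstance(s, SimilarityMatrix) else np.asarray(s, dtype=float)
            for s in similarities]
    if not mats:
        raise ValidationError("cannot accumulate an empty list of matrices")
    shape = mats[0].shape
    if len(shape) != 2 or shape[0] != shape[1]:
        raise DimensionError(f"similarity matrices must be square, got {shape}")
    for i, M in enumerate(mats[1:], start=1):
        if M.shape != shape:
            raise DimensionError(
                f"summand {i} has shape {M.shape}, expected {shape}"
            )
    total = np.zeros(shape, dtype=float)
    for M in mats:
        total += M
    return FeatureMatrix(values=total, n_summands=len(mats))


def build_feature_matrices(bundle: MatrixBundle):
    """Build the drug (m×m) and target (n×n) feature matrices of a bundle.

    Every association input is converted with
    :func:`cosine_similarity_matrix`; the results plus the native
    similarity inputs are summed per side.  The interaction matrix X is
    never part of the feature space (it is the label).
    """
    drug_sims = [SimilarityMatrix(values=S, source_role=f"drug_similarity_{i}")
                 for i, S in enumerate(bundle.drug_similarity_inputs)]
    drug_sims += [cosine_similarity_matrix(A, source_role=f"drug_association_{i}")
                  for i, A in enumerate(bundle.drug_association_inputs)]
    target_sims = [SimilarityMatrix(values=S, source_role=f"target_similarity_{i}")
                   for i, S in enumerate(bundle.target_similarity_inputs)]
    target_sims += [cosine_similarity_matrix(A, source_role=f"target_association_{i}")
                    for i, A in enumerate(bundle.target_association_inputs)]
    if not drug_sims or not target_sims:
        raise ValidationError("bundle must supply at least one matrix per side")
    D = accumulate_features(drug_sims)
    T = accumulate_features(target_sims)
    if D.shape != (bundle.m, bundle.m) or T.shape != (bundle.n, bundle.n):
        raise DimensionError("feature matrices disagree with bundle dimensions")
    return D, T
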