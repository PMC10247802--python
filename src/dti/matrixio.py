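"""Reading and writing the dense plain-text matrix dialect.

Heterogeneous DTI bundles (the DTINet distribution and the Yamanishi
gold-standard sets) ship as whitespace-separated dense numeric matrices,
one row per line, no header.  This module parses and writes that dialect,
assembles a validated :class:`MatrixBundle` from a manifest, and emits
prediction tables.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    DimensionError,
    MatrixFormatError,
    ValidationError,
)

__all__ = [
    "MatrixBundle",
    "read_dense_matrix",
    "write_dense_matrix",
    "load_bundle",
    "write_predictions",
    "read_predictions",
]

#: symmetry tolerance for native similarity inputs (catches transposed files)
SYMMETRY_TOL = 1e-6
#: entries of X within this distance of 0/1 are snapped to the integer
BINARY_SNAP_TOL = 1e-9


def read_dense_matrix(path, expected_shape=None) -> np.ndarray:
    """Read a whitespace-separated dense numeric matrix.

    Parameters
    ----------
    path : str or Path
        File with one matrix row per line; scientific notation accepted.
    expected_shape : tuple of int, optional
        If given, the parsed matrix must have exactly this shape.

    Raises
    ------
    MatrixFormatError
        Empty file, ragged rows (the offending line is named) or
        non-numeric tokens.
    DimensionError
        Parsed shape disagrees with ``expected_shape``.
    """
    with open(path, "r") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MatrixFormatError(f"{path}: empty matrix file")
    width = len(lines[0].split())
    for i, ln in enumerate(lines):
        w = len(ln.split())
        if w != width:
            raise MatrixFormatError(
                f"{path}: line {i + 1} has {w} values, expected {width}"
            )
    try:
        mat = np.loadtxt(io.StringIO("\n".join(lines)), ndmin=2, dtype=float)
    except ValueError as exc:
        raise MatrixFormatError(f"{path}: non-numeric token ({exc})") from exc
    if expected_shape is not None and tuple(mat.shape) != tuple(expected_shape):
        raise DimensionError(
            f"{path}: shape {mat.shape} found, expected {tuple(expected_shape)}"
        )
    return mat


def write_dense_matrix(path, matrix) -> None:
    """Write a matrix in the dense text dialect with ``%.10g`` precision."""
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.10g")


@dataclass
class MatrixBundle:
    """The raw heterogeneous matrices of one dataset.

    ``X`` is the binary drug-target interaction matrix (m×n) used as the
    prediction label.  Similarity inputs are already pairwise similarity
    matrices; association inputs (entity × attribute, e.g. drug-disease,
    drug-side-effect, target-disease) are converted to similarities
    downstream.
    """

    X: np.ndarray
    drug_similarity_inputs: list = field(default_factory=list)
    drug_association_inputs: list = field(default_factory=list)
    target_similarity_inputs: list = field(default_factory=list)
    target_association_inputs: list = field(default_factory=list)
    drug_ids: list | None = None
    target_ids: list | None = None

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    def validate(self) -> "MatrixBundle":
        """Check (and snap) all bundle invariants; return self."""
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise DimensionError("interaction matrix X must be 2-D")
        near0 = np.abs(X) <= BINARY_SNAP_TOL
        near1 = np.abs(X - 1.0) <= BINARY_SNAP_TOL
        if not np.all(near0 | near1):
            bad = X[~(near0 | near1)].flat[0]
            raise ValidationError(f"X contains non-binary entry {bad!r}")
        self.X = np.where(near1, 1.0, 0.0)
        m, n = self.X.shape
        for side, count, sims, assocs in (
            ("drug", m, self.drug_similarity_inputs, self.drug_association_inputs),
            ("target", n, self.target_similarity_inputs, self.target_association_inputs),
        ):
            for i, S in enumerate(sims):
                S = np.asarray(S, dtype=float)
                if S.shape != (count, count):
                    raise DimensionError(
                        f"{side} similarity input {i}: shape {S.shape}, "
                        f"expected ({count}, {count})"
                    )
                if np.min(S) < 0:
                    raise ValidationError(
                        f"{side} similarity input {i} has negative entries"
                    )
                if np.max(np.abs(S - S.T)) > SYMMETRY_TOL:
                    raise ValidationError(
                        f"{side} similarity input {i} is asymmetric beyond "
                        f"{SYMMETRY_TOL} (transposed file?)"
                    )
                sims[i] = S
            for i, A in enumerate(assocs):
                A = np.asarray(A, dtype=float)
                if A.ndim != 2 or A.shape[0] != count:
                    raise DimensionError(
                        f"{side} association input {i}: {A.shape[0]} rows, "
                        f"expected {count}"
                    )
                assocs[i] = A
        if self.drug_ids is not None and len(self.drug_ids) != m:
            raise DimensionError("drug_ids length does not match X rows")
        if self.target_ids is not None and len(self.target_ids) != n:
            raise DimensionError("target_ids length does not match X columns")
        return self


_MANIFEST_KEYS = {
    "interactions",
    "drug_similarity",
    "drug_association",
    "target_similarity",
    "target_association",
    "drug_ids",
    "target_ids",
}


def _read_id_file(path) -> list:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def load_bundle(manifest) -> MatrixBundle:
    """Assemble a :class:`MatrixBundle` from a manifest.

    The manifest is a YAML file (or an equivalent dict) mapping roles to
    file paths::

        interactions: X.txt
        drug_similarity: [drug_struct_sim.txt, drug_drug_int.txt]
        drug_association: [drug_disease.txt, drug_se.txt]
        target_similarity: [target_seq_sim.txt, target_target_int.txt]
        target_association: [target_disease.txt]
        drug_ids: drugs.txt        # optional, one identifier per line
        target_ids: targets.txt    # optional

    Relative paths resolve against the manifest's directory.  The number
    of matrices per side is free: gold-standard bundles supply fewer
    matrices than DTINet.
    """
    if isinstance(manifest, (str, os.PathLike)):
        base = os.path.dirname(os.fspath(manifest))
        with open(manifest) as fh:
            spec = yaml.safe_load(fh)
    else:
        base = "."
        spec = dict(manifest)
    if not isinstance(spec, dict):
        raise ConfigurationError("manifest must be a mapping of role -> path")
    unknown = set(spec) - _MANIFEST_KEYS
    if unknown:
        raise ConfigurationError(f"unknown manifest keys: {sorted(unknown)}")
    if "interactions" not in spec:
        raise ConfigurationError("manifest omits the interaction matrix role")

    def resolve(p):
        return p if os.path.isabs(p) else os.path.join(base, p)

    def read_list(key):
        return [read_dense_matrix(resolve(p)) for p in spec.get(key) or []]

    bundle = MatrixBundle(
        X=read_dense_matrix(resolve(spec["interactions"])),
        drug_similarity_inputs=read_list("drug_similarity"),
        drug_association_inputs=read_list("drug_association"),
        target_similarity_inputs=read_list("target_similarity"),
        target_association_inputs=read_list("target_association"),
        drug_ids=_read_id_file(resolve(spec["drug_ids"])) if spec.get("drug_ids") else None,
        target_ids=_read_id_file(resolve(spec["target_ids"])) if spec.get("target_ids") else None,
    )
    return bundle.validate()


def write_predictions(scores, path) -> None:
    """Write (drug_id, target_id, score) rows as a sorted TSV table.

    Rows are ordered by descending score; ties break on the
    (drug_id, target_id) pair in ascending order so output is
    deterministic.  Scores must lie in [0, 1].
    """
    rows = list(scores)
    for d, t, s in rows:
        if not (0.0 <= s <= 1.0):
            raise ValidationError(f"score {s!r} for pair ({d}, {t}) outside [0, 1]")
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("drug_id\ttarget_id\tscore\n")
        for d, t, s in rows:
            fh.write(f"{d}\t{t}\t{s:.8g}\n")


def read_predictions(path) -> pd.DataFrame:
    """Read a prediction table written by :func:`write_predictions`."""
    return pd.read_csv(path, sep="\t")
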