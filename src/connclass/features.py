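"""Edge-feature construction for connectome classification.

A symmetric N-node matrix contributes its Ne = N(N-1)/2 upper-triangle
entries as features. Structural modalities are sparsified group-wise with
proportional thresholding (keep an edge only if it is nonzero in at least a
given fraction of subjects); functional and structural feature blocks can be
stacked per subject into one long vector; all features are z-normalised with
statistics estimated on training subjects only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EdgeSpace",
    "FeatureMatrix",
    "ZNormStats",
    "ValidationError",
    "AlignmentError",
    "vectorize_upper",
    "reconstruct_symmetric",
    "proportional_threshold",
    "stack_modalities",
    "fit_znorm",
    "apply_znorm",
]


class ValidationError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class EdgeSpace:
    """Bijection between unordered node pairs {i<j} and edge indices.

    Edge k runs over the upper triangle in row-major order, 0-based:
    (0,1), (0,2), ..., (0,N-1), (1,2), ...
    """

    n_nodes: int

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def triu(self) -> tuple[np.ndarray, np.ndarray]:
        return np.triu_indices(self.n_nodes, 1)

    def index(self, i: int, j: int) -> int:
        if not 0 <= i < j < self.n_nodes:
            raise ValidationError(f"need 0 <= i < j < {self.n_nodes}, got ({i}, {j})")
        return i * self.n_nodes - i * (i + 1) // 2 + (j - i - 1)

    def pair(self, k: int) -> tuple[int, int]:
        if not 0 <= k < self.n_edges:
            raise ValidationError(f"edge index {k} outside [0, {self.n_edges})")
        rows, cols = self.triu()
        return int(rows[k]), int(cols[k])

    def pairs(self, ks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = self.triu()
        ks = np.asarray(ks)
        return rows[ks], cols[ks]


def vectorize_upper(matrix: np.ndarray, space: EdgeSpace | None = None,
                    atol: float = 1e-8) -> np.ndarray:
    """Upper-triangle edge vector of a symmetric square matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValidationError(f"expected a square matrix, got shape {matrix.shape}")
    if space is not None and space.n_nodes != matrix.shape[0]:
        raise ValidationError(
            f"matrix has {matrix.shape[0]} nodes, EdgeSpace expects {space.n_nodes}")
    if not np.allclose(matrix, matrix.T, atol=atol, rtol=0.0):
        raise ValidationError("matrix is not symmetric within tolerance")
    return matrix[np.triu_indices(matrix.shape[0], 1)]


def reconstruct_symmetric(vector: np.ndarray, space: EdgeSpace) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` (zero diagonal)."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (space.n_edges,):
        raise ValidationError(f"expected {space.n_edges} edges, got {vector.shape}")
    out = np.zeros((space.n_nodes, space.n_nodes))
    out[space.triu()] = vector
    return out + out.T


@dataclass
class FeatureMatrix:
    """Subjects x kept-features table for one (possibly stacked) modality.

    ``col_modality`` / ``col_edge`` record, for every column, which modality
    it came from and its edge index in that modality's :class:`EdgeSpace`.
    """

    subject_ids: tuple[str, ...]
    values: np.ndarray                       # (n_subjects, n_features)
    col_modality: np.ndarray                 # (n_features,) str
    col_edge: np.ndarray                     # (n_features,) int
    spaces: dict = field(default_factory=dict)  # modality -> EdgeSpace

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.col_edge)):
            raise ValidationError("values shape does not match ids/columns")
        if not np.isfinite(self.values).all():
            raise ValidationError("feature matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def provenance(self, column: int) -> tuple[str, int]:
        return str(self.col_modality[column]), int(self.col_edge[column])

    def rows_for(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise AlignmentError(f"subjects missing from feature matrix: {missing[:5]}")
        return np.array([lookup[s] for s in ids])

    @classmethod
    def from_matrices(
        cls,
        subject_ids: Sequence[str],
        matrices: Sequence[np.ndarray],
        modality: str,
        mask: np.ndarray | None = None,
    ) -> "FeatureMatrix":
        """Vectorise per-subject symmetric matrices, optionally masked."""
        if len(matrices) == 0:
            raise ValidationError("no matrices supplied")
        if len(matrices) != len(subject_ids):
            raise AlignmentError("subject_ids and matrices lengths differ")
        space = EdgeSpace(np.asarray(matrices[0]).shape[0])
        vecs = np.stack([vectorize_upper(m, space) for m in matrices])
        edges = np.arange(space.n_edges) if mask is None else np.asarray(mask, dtype=int)
        return cls(
            subject_ids=tuple(subject_ids),
            values=vecs[:, edges],
            col_modality=np.array([modality] * len(edges), dtype=object),
            col_edge=edges.copy(),
            spaces={modality: space},
        )


def proportional_threshold(matrices: Sequence[np.ndarray], fraction: float) -> np.ndarray:
    """Group-level edge mask: keep edges nonzero in >= ceil(fraction * n) subjects.

    Returns the kept edge indices into the shared :class:`EdgeSpace`. The
    boundary is inclusive ("present in at least" the fraction), and presence
    means strictly nonzero.
    """
    if len(matrices) == 0:
        raise ValidationError("empty subject list")
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("fraction must lie in (0, 1]")
    space = EdgeSpace(np.asarray(matrices[0]).shape[0])
    vecs = np.stack([vectorize_upper(m, space) for m in matrices])
    n_required = math.ceil(fraction * len(matrices) - 1e-9)
    counts = np.count_nonzero(vecs, axis=0)
    return np.flatnonzero(counts >= n_required)


def stack_modalities(functional: FeatureMatrix, structural: FeatureMatrix) -> FeatureMatrix:
    """Concatenate structural kept-features after functional kept-features."""
    if functional.subject_ids != structural.subject_ids:
        a, b = set(functional.subject_ids), set(structural.subject_ids)
        raise AlignmentError(
            f"subject id mismatch; only in functional: {sorted(a - b)[:5]}, "
            f"only in structural: {sorted(b - a)[:5]}"
        )
    overlap = set(functional.spaces) & set(structural.spaces)
    if overlap:
        raise ValidationError(f"modalities stacked twice: {sorted(overlap)}")
    return FeatureMatrix(
        subject_ids=functional.subject_ids,
        values=np.hstack([functional.values, structural.values]),
        col_modality=np.concatenate([functional.col_modality, structural.col_modality]),
        col_edge=np.concatenate([functional.col_edge, structural.col_edge]),
        spaces={**functional.spaces, **structural.spaces},
    )


@dataclass
class ZNormStats:
    """Per-feature mean and SD (denominator n-1) from a training subset."""

    mean: np.ndarray
    sd: np.ndarray
    zero_variance: np.ndarray


def fit_znorm(train: FeatureMatrix | np.ndarray) -> ZNormStats:
    x = train.values if isinstance(train, FeatureMatrix) else np.asarray(train, float)
    if x.shape[0] < 2:
        raise ValidationError("z-normalisation needs at least two training subjects")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    # constant columns up to rounding error count as zero-variance
    dead = sd <= 1e-12 * (np.abs(mean) + 1.0)
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance training column(s); "
            "they will map to all-zeros",
            stacklevel=2,
        )
    return ZNormStats(mean=mean, sd=sd, zero_variance=dead)


def apply_znorm(fm: FeatureMatrix | np.ndarray, stats: ZNormStats) -> np.ndarray:
    """Transform features with training statistics; dead columns become zero."""
    x = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, float)
    if x.shape[1] != stats.mean.shape[0]:
        raise ValidationError("feature count does not match z-norm statistics")
    sd = np.where(stats.zero_variance, 1.0, stats.sd)
    out = (x - stats.mean) / sd
    out[:, stats.zero_variance] = 0.0
    return out
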