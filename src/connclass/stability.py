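"""Coefficient-stability feature selection and feature-set comparison.

An edge counts as a robust "important feature" only if, across all 30
cross-validation models, (a) its coefficient magnitude ranks in the top half
of all features in every single model, and (b) its coefficient sign is the
same (and nonzero) in every single model. Feature sets from different
analysis settings are compared with the Jaccard index, and mean coefficients
are aggregated per subnetwork block as a signed, normalised mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import EdgeSpace, ValidationError

__all__ = [
    "ImportantFeatureSet",
    "BlockCoefficients",
    "select_important",
    "jaccard",
    "round_half_up",
    "mean_coefficients",
    "normalized_block_coefficients",
    "important_edge_table",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal rounding with ties away from zero, the printed-table convention
    (e.g. 0.15625 -> 0.1563 at 4 digits, where banker's rounding gives 0.1562)."""
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class ImportantFeatureSet:
    """Feature indices surviving both stability criteria, with their signs."""

    indices: np.ndarray             # ascending feature indices
    signs: np.ndarray               # +1 / -1 per index
    n_features: int                 # size p of the underlying feature space
    phenotype: str = ""
    modality: str = ""
    ctq_threshold: float | None = None

    @property
    def k(self) -> int:
        return len(self.indices)

    def as_set(self) -> set[int]:
        return set(int(i) for i in self.indices)


def _top_half_mask(coef: np.ndarray) -> np.ndarray:
    """Boolean mask of features in the top floor(p/2) by |coef|.

    Ties break toward the smaller feature index (stable sort on descending
    magnitude).
    """
    p = len(coef)
    order = np.argsort(-np.abs(coef), kind="stable")
    mask = np.zeros(p, dtype=bool)
    mask[order[: p // 2]] = True
    return mask


def select_important(models, **metadata) -> ImportantFeatureSet:
    """Apply the two 30-model stability criteria.

    ``models`` is a sequence of fitted models (or bare coefficient vectors)
    sharing one feature space. A feature is kept iff it is in the top half by
    magnitude in *every* model and its sign is identical and nonzero in
    *every* model.
    """
    coefs = np.stack([np.asarray(getattr(m, "coef", m), dtype=float) for m in models])
    if coefs.ndim != 2:
        raise ValidationError("models must share a single coefficient vector each")
    p = coefs.shape[1]
    in_top = np.ones(p, dtype=bool)
    for c in coefs:
        if len(c) != p:
            raise ValidationError("models have differing feature counts")
        in_top &= _top_half_mask(c)
    signs = np.sign(coefs)
    consistent = (signs == signs[0]).all(axis=0) & (signs[0] != 0)
    keep = np.flatnonzero(in_top & consistent)
    return ImportantFeatureSet(
        indices=keep, signs=signs[0][keep].astype(int), n_features=p, **metadata
    )


def jaccard(a, b) -> float:
    """|a & b| / |a | b|; two empty sets are identical, so 1.0."""
    sa = a.as_set() if isinstance(a, ImportantFeatureSet) else set(a)
    sb = b.as_set() if isinstance(b, ImportantFeatureSet) else set(b)
    union = sa | sb
    if not union:
        return 1.0
    return len(sa & sb) / len(union)


def mean_coefficients(models) -> np.ndarray:
    """Arithmetic mean coefficient vector over the cross-validation models."""
    coefs = np.stack([np.asarray(getattr(m, "coef", m), dtype=float) for m in models])
    return coefs.mean(axis=0)


@dataclass
class BlockCoefficients:
    """Signed normalised coefficient mass per subnetwork block.

    ``matrix[i, j]`` is the sum of mean coefficients of the important edges
    in block (i, j), divided by the total absolute mean-coefficient mass of
    *all* edges. The matrix is stored symmetrically; the upper triangle
    (including the diagonal) is canonical. A positive entry means the
    block's important edges push predictions toward the case class.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def normalized_block_coefficients(
    beta_mean: np.ndarray,
    important: ImportantFeatureSet,
    node_labels: np.ndarray,
    space: EdgeSpace,
    labels: tuple[str, ...] | None = None,
) -> BlockCoefficients:
    """Aggregate signed important-edge mass per subnetwork block.

    ``node_labels`` assigns each node of ``space`` to a subnetwork label.
    The denominator is the sum of |mean coefficient| over all edges; when it
    is zero (all-null coefficients) an all-zero matrix is returned with a
    warning.
    """
    beta_mean = np.asarray(beta_mean, dtype=float)
    if len(beta_mean) != space.n_edges:
        raise ValidationError("beta_mean length does not match the edge space")
    node_labels = np.asarray(node_labels)
    if labels is None:
        labels = tuple(dict.fromkeys(node_labels))
    label_index = {lab: i for i, lab in enumerate(labels)}
    out = np.zeros((len(labels), len(labels)))
    denom = np.abs(beta_mean).sum()
    if denom == 0.0:
        warnings.warn("all mean coefficients are zero; block coefficients set to 0",
                      stacklevel=2)
        return BlockCoefficients(labels=labels, matrix=out)
    rows, cols = space.pairs(important.indices)
    for k, i, j in zip(important.indices, rows, cols):
        a, b = sorted((label_index[node_labels[i]], label_index[node_labels[j]]))
        out[a, b] += beta_mean[k]
    out = out / denom
    out = out + np.triu(out, 1).T  # mirror for symmetric storage
    return BlockCoefficients(labels=labels, matrix=out)


def important_edge_table(
    important: ImportantFeatureSet,
    node_labels: np.ndarray,
    space: EdgeSpace,
    beta_mean: np.ndarray | None = None,
) -> pd.DataFrame:
    """Edge list of the important features, suitable for circular-plot tools."""
    rows, cols = space.pairs(important.indices)
    node_labels = np.asarray(node_labels)
    table = pd.DataFrame(
        {
            "node_i": rows,
            "node_j": cols,
            "subnetwork_i": node_labels[rows],
            "subnetwork_j": node_labels[cols],
            "sign": important.signs,
        }
    )
    if beta_mean is not None:
        table["beta_mean"] = np.asarray(beta_mean)[important.indices]
    return table
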