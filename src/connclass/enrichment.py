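"""Hypergeometric enrichment of important edges in subnetwork blocks.

With K important edges among the Ne possible edges of an N-node connectome,
and a six-way node partition, the number of important edges falling in block
(i, j) under the null of uniform selection without replacement is
hypergeometric with population Ne, S_ij marked items and K draws, where

    S_ij = n_i * n_j           (i != j)
    S_ii = n_i (n_i - 1) / 2.

Each block is tested in the direction of its deviation from the expected
count K * S_ij / Ne: the lower tail P[X <= O_ij] when the observed count is
at or below expectation ("fewer"), the upper tail P[X >= O_ij] otherwise
("more"). Tail probabilities are evaluated in log space, and the 21 block
tests of one model are corrected with the Benjamini-Hochberg step-up
procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .features import EdgeSpace, ValidationError
from .stability import BlockCoefficients, ImportantFeatureSet

__all__ = [
    "Partition",
    "BlockCounts",
    "EnrichmentResult",
    "block_capacity",
    "observed_block_counts",
    "hypergeom_block_pvalues",
    "bh_adjust",
    "enrich",
]


@dataclass(frozen=True)
class Partition:
    """Assignment of connectome nodes to named subnetworks."""

    labels: tuple[str, ...]          # subnetwork names, in canonical order
    node_labels: tuple[str, ...]     # one label per node

    def __post_init__(self) -> None:
        extra = set(self.node_labels) - set(self.labels)
        if extra:
            raise ValidationError(f"node labels not in the partition: {sorted(extra)}")

    @classmethod
    def from_sizes(cls, sizes, labels) -> "Partition":
        node_labels = tuple(np.repeat(list(labels), list(sizes)))
        return cls(labels=tuple(labels), node_labels=node_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def sizes(self) -> np.ndarray:
        arr = np.asarray(self.node_labels)
        return np.array([int((arr == lab).sum()) for lab in self.labels])

    def node_index(self) -> np.ndarray:
        """Subnetwork index of each node."""
        lookup = {lab: i for i, lab in enumerate(self.labels)}
        return np.array([lookup[lab] for lab in self.node_labels])


def block_capacity(partition: Partition) -> np.ndarray:
    """S matrix: number of possible edges within/between subnetworks."""
    n = partition.sizes
    s = np.outer(n, n)
    np.fill_diagonal(s, n * (n - 1) // 2)
    return s


def observed_block_counts(
    important: ImportantFeatureSet, partition: Partition, space: EdgeSpace
) -> np.ndarray:
    """O matrix: important-edge count per unordered subnetwork block."""
    if partition.n_nodes != space.n_nodes:
        raise ValidationError("partition and edge space disagree on node count")
    if important.k and int(important.indices.max()) >= space.n_edges:
        raise ValidationError("important feature index outside the edge space")
    idx = partition.node_index()
    k = len(partition.labels)
    out = np.zeros((k, k), dtype=int)
    rows, cols = space.pairs(important.indices)
    for i, j in zip(idx[rows], idx[cols]):
        a, b = sorted((int(i), int(j)))
        out[a, b] += 1
    return out + np.triu(out, 1).T


@dataclass
class BlockCounts:
    """Capacity and observed counts for the hypergeometric block tests."""

    s: np.ndarray    # capacity matrix
    o: np.ndarray    # observed important-edge counts
    k: int           # total important edges
    ne: int          # total possible edges

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=int)
        self.o = np.asarray(self.o, dtype=int)
        iu = np.triu_indices(self.s.shape[0])
        if int(self.s[iu].sum()) != self.ne:
            raise ValidationError("block capacities do not sum to Ne")
        if int(self.o[iu].sum()) != self.k:
            raise ValidationError("observed block counts do not sum to K")
        if self.k > self.ne or (self.s > self.ne).any():
            raise ValidationError("K and S must not exceed Ne")
        if (self.o > np.minimum(self.s, self.k)).any() or (self.o < 0).any():
            raise ValidationError("observed counts outside [0, min(S, K)]")

    @classmethod
    def from_partition(
        cls, important: ImportantFeatureSet, partition: Partition, space: EdgeSpace
    ) -> "BlockCounts":
        return cls(
            s=block_capacity(partition),
            o=observed_block_counts(important, partition, space),
            k=important.k,
            ne=space.n_edges,
        )


@dataclass
class EnrichmentResult:
    labels: tuple[str, ...]
    counts: BlockCounts
    p: np.ndarray                    # tail p-values; NaN for empty blocks
    tail: np.ndarray                 # "more" / "fewer" / "" per block
    q: np.ndarray                    # BH-adjusted over the testable blocks
    beta_norm: BlockCoefficients | None = None

    def tidy(self) -> pd.DataFrame:
        """Long-format table over the upper-triangle blocks."""
        rows = []
        k = len(self.labels)
        for i in range(k):
            for j in range(i, k):
                rows.append(
                    {
                        "block": f"{self.labels[i]}-{self.labels[j]}",
                        "O": int(self.counts.o[i, j]),
                        "S": int(self.counts.s[i, j]),
                        "p": self.p[i, j],
                        "q": self.q[i, j],
                        "tail": self.tail[i, j],
                        "beta_norm": (
                            self.beta_norm.matrix[i, j] if self.beta_norm else np.nan
                        ),
                    }
                )
        return pd.DataFrame(rows)


def hypergeom_tail(o: int, ne: int, s: int, k: int) -> tuple[float, str]:
    """Directional hypergeometric tail probability for one block.

    Lower tail P[X <= o] when o is at or below the expectation k*s/ne
    (comparison done in exact integer arithmetic), upper tail P[X >= o]
    otherwise.
    """
    if o * ne <= k * s:
        logp = hypergeom.logcdf(o, ne, s, k)
        tail = "fewer"
    else:
        logp = hypergeom.logsf(o - 1, ne, s, k)
        tail = "more"
    return float(min(np.exp(logp), 1.0)), tail


def hypergeom_block_pvalues(counts: BlockCounts) -> tuple[np.ndarray, np.ndarray]:
    """Directional p-values and tail flags for every block with capacity > 0."""
    n = counts.s.shape[0]
    p = np.full((n, n), np.nan)
    tail = np.full((n, n), "", dtype=object)
    for i in range(n):
        for j in range(i, n):
            if counts.s[i, j] == 0:
                continue  # untestable (e.g. the diagonal of a size-1 subnetwork)
            p[i, j], tail[i, j] = hypergeom_tail(
                int(counts.o[i, j]), counts.ne, int(counts.s[i, j]), counts.k
            )
            p[j, i], tail[j, i] = p[i, j], tail[i, j]
    return p, tail


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    pvalues = np.asarray(pvalues, dtype=float)
    if len(pvalues) == 0:
        return pvalues.copy()
    if (pvalues <= 0).any() or (pvalues > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


def enrich(
    important: ImportantFeatureSet,
    partition: Partition,
    space: EdgeSpace,
    beta_mean: np.ndarray | None = None,
) -> EnrichmentResult:
    """Full block-enrichment analysis for one model's important-feature set.

    The BH family is the set of testable (capacity > 0) upper-triangle
    blocks of this one model.
    """
    counts = BlockCounts.from_partition(important, partition, space)
    p, tail = hypergeom_block_pvalues(counts)
    n = len(partition.labels)
    iu = np.triu_indices(n)
    testable = np.isfinite(p[iu])
    q = np.full((n, n), np.nan)
    flat_q = np.full(testable.sum(), np.nan)
    flat_q[:] = bh_adjust(p[iu][testable])
    qu = np.full(len(iu[0]), np.nan)
    qu[testable] = flat_q
    q[iu] = qu
    q_low = q.T.copy()
    mask = np.isnan(q)
    q[mask] = q_low[mask]

    beta = None
    if beta_mean is not None:
        from .stability import normalized_block_coefficients

        beta = normalized_block_coefficients(
            beta_mean, important, np.asarray(partition.node_labels), space,
            labels=partition.labels,
        )
    return EnrichmentResult(
        labels=partition.labels, counts=counts, p=p, tail=tail, q=q, beta_norm=beta
    )
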