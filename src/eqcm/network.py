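"""Weighted gene co-expression networks and the primitives built on them.

A co-expression network here is the complete weighted graph over genes whose
edge weights are the absolute Pearson correlation (|PCC|) between the two
genes' expression profiles across samples.  Weights therefore live in
``[0, 1]`` and the graph is stored as a dense symmetric matrix, which is
comfortable up to a few thousand genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "WeightedNetwork",
    "SubNetwork",
    "build_wgcn",
    "density",
    "overlap_ratio",
]


def _check_unique(ids: Sequence[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValueError(f"duplicate {kind} identifiers: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized expression values.

    Parameters
    ----------
    gene_ids : ordered unique gene identifiers (rows).
    sample_ids : ordered unique sample identifiers (columns).
    values : real matrix of shape ``(len(gene_ids), len(sample_ids))``;
        must be finite (missing values are rejected, not imputed).
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no NaN/inf)")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_indices(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices for ``genes``; raises on unknown identifiers."""
        try:
            return np.array([self._gene_index[g] for g in genes], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"gene {exc.args[0]!r} not in expression matrix") from None

    def submatrix(self, genes: Sequence[str]) -> np.ndarray:
        return self.values[self.gene_indices(genes), :]


@dataclass
class WeightedNetwork:
    """Complete weighted graph over genes; weights symmetric in ``[0, 1]``.

    ``weights`` is dense with a zero diagonal (no self-loops).
    """

    vertices: list
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = list(self.vertices)
        _check_unique(self.vertices, "vertex")
        W = np.asarray(self.weights, dtype=float)
        n = len(self.vertices)
        if W.shape != (n, n):
            raise ValueError(f"weight matrix shape {W.shape} != ({n}, {n})")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if W.size and (np.nanmin(W) < -1e-12 or np.nanmax(W) > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")
        np.fill_diagonal(W, 0.0)
        self.weights = np.clip(W, 0.0, 1.0)
        self._index = {v: i for i, v in enumerate(self.vertices)}

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def index(self, vertex: str) -> int:
        try:
            return self._index[vertex]
        except KeyError:
            raise KeyError(f"vertex {vertex!r} not in network") from None

    def indices(self, vertices: Iterable[str]) -> np.ndarray:
        return np.array([self.index(v) for v in vertices], dtype=int)

    def weight(self, a: str, b: str) -> float:
        return float(self.weights[self.index(a), self.index(b)])

    def max_weight(self) -> float:
        return float(self.weights.max()) if self.n_vertices > 1 else 0.0


@dataclass
class SubNetwork:
    """A mined vertex set with its induced density and provenance.

    ``density`` is the mean pairwise weight over all unordered member pairs.
    ``seed_edge`` records which heavy edge started the greedy expansion, and
    ``addition_order`` the vertices appended after the seed, in order.
    ``pvalue`` is filled in later by the survival screen.
    """

    members: frozenset
    density: float
    seed_edge: Optional[tuple] = None
    pvalue: Optional[float] = None
    id: str = ""
    addition_order: tuple = ()

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if len(self.members) < 2:
            raise ValueError("a sub-network needs at least 2 members")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def sorted_members(self) -> list:
        return sorted(self.members)


def build_wgcn(expr: ExpressionMatrix, weight_floor: float = 0.0) -> WeightedNetwork:
    """Build the |PCC| co-expression network from an expression matrix.

    Genes with zero variance across samples are dropped (their correlation is
    undefined; any imputed weight would be arbitrary) with a logged warning.

    Parameters
    ----------
    expr : expression matrix, >= 2 genes and >= 3 samples.
    weight_floor : optional memory optimization — weights strictly below the
        floor are zeroed.  The default 0.0 keeps the exact complete graph;
        any positive floor makes downstream mining approximate and is opt-in.
    """
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples; correlation is ill-defined")
    if expr.n_genes < 2:
        raise ValueError("need at least 2 genes")
    var = expr.values.var(axis=1)
    keep = var > 0.0
    n_dropped = int((~keep).sum())
    if n_dropped:
        dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
        msg = f"dropping {n_dropped} zero-variance gene(s): {dropped[:5]}..."
        log.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 genes with non-zero variance")
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    W = np.abs(np.corrcoef(expr.values[keep, :]))
    np.fill_diagonal(W, 0.0)
    W = np.clip(W, 0.0, 1.0)
    if weight_floor > 0.0:
        W[W < weight_floor] = 0.0
    return WeightedNetwork(genes, W)


def density(members: Iterable[str], net: WeightedNetwork) -> float:
    """Weighted density of the induced sub-network.

    ``d = sum_{i<j} w_ij / (N (N-1) / 2)`` — the mean pairwise edge weight
    over all unordered pairs of the ``N`` member vertices.
    """
    idx = net.indices(members)
    n = len(idx)
    if n < 2:
        raise ValueError("density requires at least 2 members")
    sub = net.weights[np.ix_(idx, idx)]
    # sub sums each unordered pair twice; normalize accordingly
    return float(sub.sum() / (n * (n - 1)))


def overlap_ratio(v1: Iterable[str], v2: Iterable[str]) -> float:
    """Overlap between two gene sets: ``|V1 ∩ V2| / min(|V1|, |V2|)``."""
    s1, s2 = set(v1), set(v2)
    if not s1 or not s2:
        raise ValueError("overlap_ratio requires non-empty sets")
    return len(s1 & s2) / min(len(s1), len(s2))
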