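"""Randomized significance thresholds, selection, and overlap clustering.

Because mined sub-networks overlap heavily, their log-rank tests are far
from independent and a Bonferroni-style correction would be badly
conservative.  Instead, an empirical null is built per size bin: random
gene lists with a given expected size are pushed through the identical
bipartition-plus-log-rank screen many times, and the lower 5th percentile
of the resulting p-values becomes the significance cutoff for real
sub-networks whose size falls in that bin.  Significant sub-networks are
then merged into clusters wherever their overlap ratio exceeds 50%, and
each cluster is represented by its lowest-p member.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import networkx as nx
import numpy as np

from .network import ExpressionMatrix, SubNetwork, overlap_ratio
from .survival import ClinicalTable, derive_seed, genes_survival_test

__all__ = [
    "ThresholdTable",
    "ClusterGroup",
    "size_bin",
    "random_gene_list",
    "empirical_threshold",
    "build_threshold_table",
    "select_significant",
    "merge_into_clusters",
    "pick_representative",
]


def size_bin(n: int) -> int:
    """Leading-digit size bin: 10,...,90,100,200,...,900,1000,...

    A sub-network of size ``n`` consults the threshold of the bin obtained by
    zeroing all but the leading decimal digit of ``n`` (e.g. 28 -> 20,
    250 -> 200).  Requires ``n >= 10`` — smaller sets are below the minimum
    sub-network size.  Idempotent and monotone non-decreasing.
    """
    n = int(n)
    if n < 10:
        raise ValueError(f"size {n} below the minimum sub-network size (10)")
    base = 10 ** (len(str(n)) - 1)
    return (n // base) * base


def random_gene_list(
    universe: Sequence[str], n_expected: int, rng: np.random.Generator
) -> List[str]:
    """Bernoulli gene sample with expected size ``n_expected``.

    Each gene of the universe is included independently with probability
    ``n_expected / |universe|``, so the list length is Binomial with the
    requested expectation (it is *not* a fixed-size draw).
    """
    universe = list(universe)
    if not 0 <= n_expected <= len(universe):
        raise ValueError(
            f"n_expected={n_expected} outside [0, {len(universe)}]"
        )
    p = n_expected / len(universe)
    mask = rng.random(len(universe)) < p
    return [g for g, m in zip(universe, mask) if m]


def empirical_threshold(pvalues: Sequence[float], percentile: float = 0.05) -> float:
    """Lower-tail empirical percentile of a p-value sample.

    Uses the ``ceil(percentile * n)``-th smallest value (for 1000 values at
    the default 5%, the 50th order statistic) — no interpolation.  Intended
    for samples of at least ~20 values; the estimate is meaningless below
    that.
    """
    arr = np.asarray(list(pvalues), dtype=float)
    if arr.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must be in (0, 1)")
    k = math.ceil(percentile * arr.size)
    return float(np.sort(arr)[k - 1])


@dataclass
class ThresholdTable:
    """Per-size-bin empirical p-value cutoffs.

    ``thresholds`` maps a bin (10, 20, ..., 100, 200, ...) to the cutoff
    derived from ``n_random`` random-list survival tests; ``pvalues`` keeps
    the raw null p-value vectors for audit.
    """

    thresholds: Dict[int, float]
    n_random: int
    seed: int
    percentile: float = 0.05
    pvalues: Dict[int, tuple] = field(default_factory=dict)

    @property
    def bins(self) -> List[int]:
        return sorted(self.thresholds)

    def threshold(self, bin_value: int) -> float:
        try:
            return self.thresholds[int(bin_value)]
        except KeyError:
            raise ValueError(
                f"no empirical threshold computed for size bin {bin_value}"
            ) from None

    def threshold_for_size(self, n: int) -> float:
        return self.threshold(size_bin(n))


def build_threshold_table(
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    bins: Iterable[int],
    n_random: int = 1000,
    rng_seed: int = 0,
    replicates: int = 100,
    percentile: float = 0.05,
) -> ThresholdTable:
    """Estimate the null p-value cutoff for each requested size bin.

    For each bin ``N``: draw ``n_random`` random gene lists with expected
    size ``N`` from the expression matrix's gene universe, run each through
    the same bipartition + log-rank screen used for real sub-networks, and
    take the lower ``percentile`` of the null p-values.  Lists that come out
    with fewer than 2 genes (possible for small ``N``) are redrawn, since
    correlation-distance features need at least two genes.

    Seeding is fully reproducible: list draws and per-test K-means restarts
    all derive from ``rng_seed``.
    """
    bins = sorted(set(int(b) for b in bins))
    for b in bins:
        if b < 10 or size_bin(b) != b:
            raise ValueError(f"{b} is not a canonical size bin")
    if n_random < 20:
        raise ValueError("n_random must be >= 20 for a stable 5th percentile")
    universe = list(expr.gene_ids)
    thresholds: Dict[int, float] = {}
    raw: Dict[int, tuple] = {}
    for b in bins:
        rng = np.random.default_rng(derive_seed(rng_seed, f"random-lists-bin{b}"))
        ps = []
        for i in range(n_random):
            genes = random_gene_list(universe, b, rng)
            while len(genes) < 2:
                genes = random_gene_list(universe, b, rng)
            res = genes_survival_test(
                genes,
                expr,
                clin,
                rng_seed=derive_seed(rng_seed, f"random-test-bin{b}-{i}"),
                replicates=replicates,
                test_id=f"rand{b}_{i:04d}",
            )
            ps.append(res.pvalue)
        thresholds[b] = empirical_threshold(ps, percentile)
        raw[b] = tuple(ps)
    return ThresholdTable(
        thresholds=thresholds,
        n_random=n_random,
        seed=int(rng_seed),
        percentile=percentile,
        pvalues=raw,
    )


def select_significant(
    subs: Sequence[SubNetwork], table: ThresholdTable
) -> List[SubNetwork]:
    """Keep sub-networks whose p-value is strictly below their bin's cutoff.

    Each sub-network of size ``n`` is compared against the threshold of
    ``size_bin(n)``; boundary values are excluded ("less than").  A missing
    bin raises an error naming the bin rather than extrapolating.
    """
    out = []
    for s in subs:
        if s.pvalue is None:
            raise ValueError(f"sub-network {s.id or s.sorted_members[:3]} has no p-value")
        if s.pvalue < table.threshold_for_size(s.size):
            out.append(s)
    return out


@dataclass
class ClusterGroup:
    """A set of significant sub-networks merged by overlap, with its representative."""

    members: List[SubNetwork]
    representative: SubNetwork = field(init=False)
    union_genes: frozenset = field(init=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must be non-empty")
        self.representative = pick_representative(self.members)
        self.union_genes = frozenset().union(*(s.members for s in self.members))

    @property
    def size(self) -> int:
        return len(self.members)


def pick_representative(members: Sequence[SubNetwork]) -> SubNetwork:
    """Lowest-p member; ties broken by smaller gene set, then lexicographic id."""
    if not members:
        raise ValueError("cluster must be non-empty")
    return min(
        members,
        key=lambda s: (
            s.pvalue if s.pvalue is not None else np.inf,
            s.size,
            s.id,
        ),
    )


def merge_into_clusters(
    subs: Sequence[SubNetwork], r_cutoff: float = 0.5
) -> List[ClusterGroup]:
    """Cluster sub-networks whose pairwise overlap ratio exceeds ``r_cutoff``.

    Clusters are the connected components of the graph joining sub-network
    pairs with overlap ratio strictly greater than the cutoff (transitive
    chains merge; the partition does not depend on input order).  Output
    clusters are ordered by their smallest member id, members by id.
    """
    ids = [s.id for s in subs]
    if len(set(ids)) != len(ids):
        raise ValueError("sub-networks must carry distinct ids")
    g = nx.Graph()
    g.add_nodes_from(range(len(subs)))
    for i in range(len(subs)):
        for j in range(i + 1, len(subs)):
            if overlap_ratio(subs[i].members, subs[j].members) > r_cutoff:
                g.add_edge(i, j)
    clusters = []
    for comp in nx.connected_components(g):
        members = sorted((subs[i] for i in comp), key=lambda s: s.id)
        clusters.append(ClusterGroup(members=members))
    clusters.sort(key=lambda c: c.members[0].id)
    return clusters
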