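"""eQCM: edge-covering quasi-clique mining on weighted networks.

The miner seeds a greedy expansion at every sufficiently heavy edge (weight
at least ``gamma`` times the maximum edge weight) that is not already covered
by an earlier sub-network, grows the seed by repeatedly adding the vertex
with the largest *contribute* score while that score clears a density-linked
threshold, then merges near-identical results (overlap >= ``beta``) and
drops everything smaller than ``min_size`` genes.

Every heavy edge is guaranteed to end up inside at least one pre-filter
sub-network — the "edge-covering" property that distinguishes this variant
from the hierarchical quasi-clique merger it descends from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .network import SubNetwork, WeightedNetwork, density, overlap_ratio

__all__ = [
    "MinerConfig",
    "sorted_seed_edges",
    "contribute",
    "expansion_threshold",
    "expand_seed",
    "expand_all_seeds",
    "beta_merge",
    "mine",
]


@dataclass(frozen=True)
class MinerConfig:
    """Mining parameters.

    gamma : seed-edge cutoff as a fraction of the maximum edge weight.
    lam : lambda in the expansion threshold; larger values make the
        threshold hug the current density more tightly (stricter growth).
    t : additive size offset in the expansion threshold.
    beta : overlap ratio at or above which two mined sets are unioned;
        the near-1 default only de-duplicates (near-)identical sets.
    min_size : minimum number of genes a reported sub-network may have.
    """

    gamma: float = 0.7
    lam: float = 1.0
    t: float = 1.0
    beta: float = 0.99999
    min_size: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")
        if self.lam <= 0.0:
            raise ValueError("lam must be positive")
        if self.t < 0.0:
            raise ValueError("t must be non-negative")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must be in (0, 1]")
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")


def sorted_seed_edges(net: WeightedNetwork, gamma: float) -> List[Tuple[str, str]]:
    """Seed edges in descending weight order.

    Keeps edges whose weight is at least ``gamma`` times the maximum edge
    weight (and positive).  Ties are broken lexicographically on the
    (gene_a, gene_b) pair, endpoints ordered within each edge, so the result
    is fully deterministic.  Returns an empty list when the network has no
    positive-weight edge.
    """
    n = net.n_vertices
    if n < 2:
        return []
    iu, ju = np.triu_indices(n, 1)
    w = net.weights[iu, ju]
    wmax = float(w.max()) if w.size else 0.0
    if wmax <= 0.0:
        return []
    cutoff = gamma * wmax
    keep = w >= cutoff
    verts = net.vertices
    edges = []
    for i, j, wij in zip(iu[keep], ju[keep], w[keep]):
        a, b = verts[i], verts[j]
        if b < a:
            a, b = b, a
        edges.append((-wij, a, b))
    edges.sort()
    return [(a, b) for _, a, b in edges]


def contribute(v: str, C: Iterable[str], net: WeightedNetwork) -> float:
    """Average edge weight from candidate ``v`` into the current set ``C``.

    Equals the total edge-weight increase of the induced sub-network on
    adding ``v``, divided by ``|C|``.
    """
    members = set(C)
    if v in members:
        raise ValueError(f"candidate {v!r} already in the sub-network")
    if len(members) < 2:
        raise ValueError("C must have at least 2 members")
    iv = net.index(v)
    idx = net.indices(members)
    return float(net.weights[iv, idx].sum() / len(members))


def _threshold_factor(size: int, lam: float, t: float) -> float:
    # the single place the expansion-threshold parenthesization lives
    denom = 2.0 * lam * (size + t)
    if denom <= 1.0:
        raise ValueError(
            f"degenerate threshold parameters: 2*lam*(|C|+t) = {denom} <= 1"
        )
    return 1.0 - 1.0 / denom


def expansion_threshold(C: Iterable[str], cfg: MinerConfig, net: WeightedNetwork) -> float:
    """Greedy-growth threshold: ``(1 - 1/(2 lam (|C| + t))) * density(C)``.

    A candidate joins ``C`` only while the best contribute score is at least
    this value; the factor rises toward 1 as the set grows, so additions must
    keep pace with the current density.
    """
    members = list(C)
    return _threshold_factor(len(members), cfg.lam, cfg.t) * density(members, net)


def expand_seed(
    edge: Tuple[str, str], net: WeightedNetwork, cfg: Optional[MinerConfig] = None
) -> SubNetwork:
    """Greedily grow a sub-network from a seed edge.

    Starts from the two endpoints and repeatedly adds the vertex with the
    largest contribute score while that score is >= the expansion threshold,
    recomputed against the current set after every accepted vertex.  Ties in
    the contribute score are broken toward the earliest vertex in the
    network's vertex order, making the expansion deterministic.
    """
    cfg = cfg or MinerConfig()
    a, b = edge
    ia, ib = net.index(a), net.index(b)
    if ia == ib:
        raise ValueError("seed edge endpoints must differ")
    W = net.weights
    n = net.n_vertices
    in_c = np.zeros(n, dtype=bool)
    in_c[[ia, ib]] = True
    contrib_sum = W[:, ia] + W[:, ib]
    wsum = float(W[ia, ib])  # sum over unordered member pairs
    size = 2
    order: List[str] = []
    while size < n:
        dens = wsum / (size * (size - 1) / 2.0)
        thr = _threshold_factor(size, cfg.lam, cfg.t) * dens
        scores = np.where(in_c, -1.0, contrib_sum / size)
        best = int(np.argmax(scores))  # argmax -> first max = lowest index
        if scores[best] < thr:
            break
        in_c[best] = True
        wsum += float(contrib_sum[best])
        contrib_sum = contrib_sum + W[:, best]
        size += 1
        order.append(net.vertices[best])
    members = frozenset(v for v, flag in zip(net.vertices, in_c) if flag)
    dens = wsum / (size * (size - 1) / 2.0)
    seed = (a, b) if a <= b else (b, a)
    return SubNetwork(
        members=members, density=dens, seed_edge=seed, addition_order=tuple(order)
    )


def expand_all_seeds(net: WeightedNetwork, cfg: Optional[MinerConfig] = None) -> List[SubNetwork]:
    """The seed-expansion pass: one expansion per uncovered heavy edge.

    Iterates the sorted seed edges, skipping any edge whose two endpoints
    already lie together inside a previously expanded sub-network, so every
    heavy edge is covered by at least one returned set.  This is the raw,
    pre-merge, pre-size-filter output.
    """
    cfg = cfg or MinerConfig()
    found: List[SubNetwork] = []
    for a, b in sorted_seed_edges(net, cfg.gamma):
        if any(a in s.members and b in s.members for s in found):
            continue
        found.append(expand_seed((a, b), net, cfg))
    return found


def beta_merge(
    subs: Sequence[SubNetwork], beta: float, net: WeightedNetwork
) -> List[SubNetwork]:
    """Union any pair of sub-networks whose overlap ratio is >= ``beta``.

    Scans pairs in list order, merges the first qualifying pair (recomputing
    the union's density on ``net``), and restarts until no pair qualifies.
    With ``beta`` close to 1 this only collapses (near-)identical sets and
    the result does not depend on the scan order.  Idempotent.
    """
    if not 0.0 < beta <= 1.0:
        raise ValueError("beta must be in (0, 1]")
    work = list(subs)
    merged = True
    while merged:
        merged = False
        for i in range(len(work)):
            for j in range(i + 1, len(work)):
                if overlap_ratio(work[i].members, work[j].members) >= beta:
                    union = work[i].members | work[j].members
                    work[i] = SubNetwork(
                        members=union,
                        density=density(union, net),
                        seed_edge=work[i].seed_edge,
                        addition_order=work[i].addition_order,
                    )
                    del work[j]
                    merged = True
                    break
            if merged:
                break
    return work


def mine(
    net: WeightedNetwork, cfg: Optional[MinerConfig] = None, raw: bool = False
) -> List[SubNetwork]:
    """Run the full miner: seed expansions, beta-merge, size filter.

    With ``raw=True`` returns the pre-merge, pre-filter expansions (the list
    that carries the edge-cover guarantee).  Output order and identifiers
    ("M0001", ...) are deterministic for a given network and config.
    """
    cfg = cfg or MinerConfig()
    found = expand_all_seeds(net, cfg)
    if raw:
        subs = found
    else:
        subs = [
            s for s in beta_merge(found, cfg.beta, net) if s.size >= cfg.min_size
        ]
    for k, s in enumerate(subs):
        s.id = f"M{k + 1:04d}"
    return subs
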