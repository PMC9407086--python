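"""Weighted median-joining networks over Y-STR haplotypes.

A haplotype network connects observed haplotypes (and inferred
intermediate "median vectors") under the weighted Manhattan metric

.. math:: d(u, v) = \\sum_l w_l\\,|u_l - v_l|

where the locus weight :math:`w_l \\in \\{1..5\\}` is derived from the
locus mutation rate — the slower the locus, the higher the weight, so a
step at a stable locus costs more than a step at a rapidly mutating one.

The median-joining construction iterates two phases: build the
ε-relaxed minimum-spanning network (the union of all minimum spanning
trees, plus links within ε of the minimax connection level), then
propose the component-wise median of connected triplets of nodes and
keep medians that strictly reduce the spanning cost.  Obsolete medians
(degree ≤ 2 nodes whose removal does not raise the spanning cost) are
pruned at the end.

The default locus set is the classic 15-locus network panel, with
DYS389b = DYS389II − DYS389I replacing the raw DYS389II so the two
DYS389 amplicons contribute independent repeat blocks.  Samples with a
fractional (microvariant) allele at a network locus are excluded: the
integer step metric is undefined across a partial-repeat offset.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree as _sparse_mst
from scipy.spatial.distance import cdist

from .io import derive_dys389b
from .profiles import STRProfile

logger = logging.getLogger(__name__)

__all__ = [
    "NET_LOCI",
    "NetHaplotype",
    "LocusWeight",
    "HaploNetwork",
    "weights_from_rates",
    "collect_net_haplotypes",
    "build_network",
    "ancestral_node",
    "network_composition_summary",
]

# 15-locus network panel: 13 single-copy Yfiler loci (DYS385a/b excluded)
# plus DYS389I and the derived DYS389b in place of raw DYS389II.
NET_LOCI: tuple[str, ...] = (
    "DYS19", "DYS389I", "DYS389b", "DYS390", "DYS391", "DYS392", "DYS393",
    "DYS437", "DYS438", "DYS439", "DYS448", "DYS456", "DYS458", "DYS635",
    "YGATAH4",
)


@dataclass
class NetHaplotype:
    """One distinct haplotype over the network loci."""

    vector: tuple[int, ...]
    counts: dict[str, int] = field(default_factory=dict)
    samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.vector = tuple(int(v) for v in self.vector)
        if any(v < 0 for v in self.vector):
            raise ValueError(f"negative repeat entries: {self.vector}")

    @property
    def count(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class LocusWeight:
    """Integer network weight (1–5) for one locus."""

    locus: str
    weight: int

    def __post_init__(self) -> None:
        if not (1 <= self.weight <= 5):
            raise ValueError(f"weight must be in [1, 5], got {self.weight}")


def weights_from_rates(rates: dict[str, float],
                       loci: tuple[str, ...] = NET_LOCI) -> list[LocusWeight]:
    """Derive integer locus weights from mutation rates.

    log10 rates are quintile-binned: the slowest quintile maps to weight
    5, the fastest to 1, so weights are anti-monotone in mutation rate.
    All-equal rates fall in the middle bin (weight 3).
    """
    missing = [l for l in loci if l not in rates]
    if missing:
        raise KeyError(f"no mutation rate for network loci: {missing}")
    values = np.array([rates[l] for l in loci], dtype=float)
    if (values <= 0).any():
        raise ValueError("mutation rates must be positive")
    log_r = np.log10(values)
    if np.ptp(log_r) == 0:
        return [LocusWeight(l, 3) for l in loci]
    edges = np.quantile(log_r, [0.2, 0.4, 0.6, 0.8])
    bins = np.searchsorted(edges, log_r, side="right")
    return [LocusWeight(l, int(5 - b)) for l, b in zip(loci, bins)]


def collect_net_haplotypes(
    profiles: list[STRProfile],
    loci: tuple[str, ...] = NET_LOCI,
    keep_samples: set[str] | None = None,
) -> list[NetHaplotype]:
    """Group profiles into distinct network haplotypes.

    Applies the DYS389b derivation when the locus set asks for it, then
    excludes (with a log entry) samples that are flagged by the
    derivation, have a null or multi-allele call, or carry a fractional
    allele at a network locus.  ``keep_samples`` optionally restricts to a
    sample-id subset (e.g. the members of one haplogroup).
    """
    grouped: dict[tuple[int, ...], NetHaplotype] = {}
    for p in profiles:
        if keep_samples is not None and p.sample_id not in keep_samples:
            continue
        if "DYS389b" in loci and "DYS389b" not in p.calls:
            p, flag = derive_dys389b(p)
            if flag is not None:
                logger.info("sample %s excluded from network (%s)", p.sample_id, flag)
                continue
        vec = []
        usable = True
        for locus in loci:
            calls = p.get(locus)
            if len(calls) != 1:
                reason = "null" if not calls else "multi-allele"
                logger.info(
                    "sample %s excluded from network (%s call at %s)",
                    p.sample_id, reason, locus,
                )
                usable = False
                break
            if calls[0].is_microvariant:
                logger.info(
                    "sample %s excluded from network (fractional allele at %s)",
                    p.sample_id, locus,
                )
                usable = False
                break
            vec.append(int(round(float(calls[0]))))
        if not usable:
            continue
        key = tuple(vec)
        h = grouped.get(key)
        if h is None:
            h = grouped[key] = NetHaplotype(vector=key)
        h.counts[p.population] = h.counts.get(p.population, 0) + 1
        h.samples = (*h.samples, p.sample_id)
    return list(grouped.values())


def _weight_vector(weights: list[LocusWeight],
                   n_loci: int) -> np.ndarray:
    if len(weights) != n_loci:
        raise ValueError("one weight per network locus required")
    return np.array([w.weight for w in weights], dtype=float)


def _dist(u: tuple[int, ...], v: tuple[int, ...], w: np.ndarray) -> float:
    return float(np.abs(np.subtract(u, v)) @ w)


def _pairwise(nodes: list[tuple[int, ...]], w: np.ndarray) -> np.ndarray:
    arr = np.asarray(nodes, dtype=float)
    return cdist(arr, arr, metric="minkowski", p=1, w=w)


def _mst_from_matrix(d: np.ndarray) -> tuple[float, list[tuple[int, int, float]]]:
    # duplicate vectors (distance 0) are excluded upstream, so a zero in
    # the off-diagonal cannot occur and the dense sparse-MST form is safe
    mst = _sparse_mst(d).tocoo()
    edges = [
        (int(i), int(j), float(v))
        for i, j, v in zip(mst.row, mst.col, mst.data)
    ]
    return float(mst.sum()), edges


def _mst_cost_and_edges(nodes: list[tuple[int, ...]], w: np.ndarray
                        ) -> tuple[float, list[tuple[int, int, float]]]:
    return _mst_from_matrix(_pairwise(nodes, w))


def _msn_edges(nodes: list[tuple[int, ...]], w: np.ndarray, epsilon: float
               ) -> list[tuple[int, int, float]]:
    """ε-relaxed minimum spanning network.

    An edge (u, v) belongs to the MSN iff d(u, v) ≤ minimax(u, v) + ε,
    where minimax(u, v) is the largest edge on the MST path between u and
    v (the level at which the components of u and v merge in Kruskal's
    algorithm).  With ε = 0 this is exactly the union of all MSTs.
    """
    n = len(nodes)
    if n == 1:
        return []
    d = _pairwise(nodes, w)
    _, mst_edges = _mst_from_matrix(d)
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    for i, j, v in mst_edges:
        adj[i].append((j, v))
        adj[j].append((i, v))
    # all-pairs minimax distance via DFS from each node over the MST
    minimax = np.zeros((n, n))
    for src in range(n):
        stack = [(src, 0.0)]
        seen = {src}
        while stack:
            cur, level = stack.pop()
            for nbr, weight in adj[cur]:
                if nbr not in seen:
                    seen.add(nbr)
                    lvl = max(level, weight)
                    minimax[src, nbr] = lvl
                    stack.append((nbr, lvl))
    out = []
    for i, j in itertools.combinations(range(n), 2):
        if d[i, j] <= minimax[i, j] + epsilon + 1e-9:
            out.append((i, j, float(d[i, j])))
    return out


def _triple_medians(nodes: list[tuple[int, ...]]) -> set[tuple[int, ...]]:
    node_set = set(nodes)
    out: set[tuple[int, ...]] = set()
    for a, b, c in itertools.combinations(nodes, 3):
        med = tuple(sorted(t)[1] for t in zip(a, b, c))
        if med not in node_set:
            out.add(med)
    return out


def _exact_median_steiner(
    vectors: list[tuple[int, ...]], w: np.ndarray,
    max_vectors: int = 8, budget: int = 20000,
) -> list[tuple[int, ...]] | None:
    """Bounded exhaustive search over the median closure.

    Explores every way of augmenting the observed vectors with
    component-wise medians of triples (up to n−2 additions, the most a
    Steiner tree on n terminals can use), returning the smallest node set
    achieving the minimal spanning cost.  Gives up (returns ``None``) on
    more than ``max_vectors`` observed haplotypes or once ``budget``
    spanning-cost evaluations are spent, in which case the caller falls
    back to the greedy median-joining pass.
    """
    n = len(vectors)
    if n > max_vectors:
        return None
    evals = 0
    best: list = [None, None]  # cost, node list
    seen: set[frozenset] = set()

    def rec(nodes: list[tuple[int, ...]], depth: int) -> bool:
        nonlocal evals
        if evals >= budget:
            return False
        evals += 1
        cost, _ = _mst_cost_and_edges(nodes, w)
        if (
            best[0] is None or cost < best[0] - 1e-9
            or (abs(cost - best[0]) <= 1e-9 and len(nodes) < len(best[1]))
        ):
            best[0], best[1] = cost, list(nodes)
        if depth == 0:
            return True
        for med in sorted(_triple_medians(nodes)):
            key = frozenset([*nodes, med])
            if key in seen:
                continue
            seen.add(key)
            if not rec([*nodes, med], depth - 1):
                return False
        return True

    completed = rec(list(vectors), max(0, n - 2))
    return best[1] if completed else None


def _greedy_medians(nodes: list[tuple[int, ...]], w: np.ndarray,
                    epsilon: float, n_loci: int) -> list[tuple[int, ...]]:
    """Iteratively add the best cost-reducing median of a connected triplet."""
    nodes = list(nodes)
    while True:
        cost, _ = _mst_cost_and_edges(nodes, w)
        edges = _msn_edges(nodes, w, epsilon)
        node_set = set(nodes)
        candidates: set[tuple[int, ...]] = set()
        for i, j, _d in edges:
            for k in range(len(nodes)):
                if k in (i, j):
                    continue
                med = tuple(
                    sorted(t)[1]
                    for t in zip(nodes[i], nodes[j], nodes[k])
                )
                if med not in node_set:
                    candidates.add(med)
        best = None
        for med in sorted(candidates):
            new_cost, _ = _mst_cost_and_edges([*nodes, med], w)
            if new_cost < cost - 1e-9 and (best is None or new_cost < best[0]):
                best = (new_cost, med)
        if best is None:
            return nodes
        nodes.append(best[1])


@dataclass
class HaploNetwork:
    """A median-joining network: observed haplotypes plus median vectors."""

    graph: nx.Graph
    loci: tuple[str, ...]
    weights: list[LocusWeight]
    spanning_cost: float

    def nodes(self, medians: bool | None = None):
        for node, data in self.graph.nodes(data=True):
            if medians is None or data["is_median"] == medians:
                yield node, data

    @property
    def median_vectors(self) -> list[tuple[int, ...]]:
        return [n for n, d in self.nodes(medians=True)]


def build_network(haplotypes: list[NetHaplotype],
                  weights: list[LocusWeight],
                  epsilon: float = 0.0) -> HaploNetwork:
    """Median-joining network construction.

    Small instances (≤ 8 observed haplotypes) are solved to a provably
    minimal spanning cost by a bounded exhaustive search over the median
    closure.  Larger inputs use the iterative heuristic: build the
    ε-relaxed minimum spanning network over the current node set; for
    every triplet of nodes connected in it, form the component-wise
    median vector; among medians that strictly reduce the spanning (MST)
    cost, add the best one; repeat until no median helps.  Either way,
    obsolete medians — inferred nodes of degree ≤ 2 whose removal does
    not increase the spanning cost — are pruned, and the MSN over the
    surviving nodes is returned.

    Observed haplotypes must be pre-merged (duplicate vectors are an
    error); median vectors carry zero counts.
    """
    if len(haplotypes) < 2:
        raise ValueError("need at least 2 haplotypes")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    seen: set[tuple[int, ...]] = set()
    for h in haplotypes:
        if h.vector in seen:
            raise ValueError(f"duplicate observed vector {h.vector}; pre-merge them")
        seen.add(h.vector)
    n_loci = len(haplotypes[0].vector)
    w = _weight_vector(weights, n_loci)

    observed = {h.vector: h for h in haplotypes}
    nodes: list[tuple[int, ...]] = [h.vector for h in haplotypes]

    exact = _exact_median_steiner(nodes, w)
    if exact is not None:
        nodes = exact
    else:
        nodes = _greedy_medians(nodes, w, epsilon, n_loci)

    # prune obsolete medians
    changed = True
    while changed:
        changed = False
        cost, _ = _mst_cost_and_edges(nodes, w)
        edges = _msn_edges(nodes, w, epsilon)
        degree: dict[int, int] = {i: 0 for i in range(len(nodes))}
        for i, j, _d in edges:
            degree[i] += 1
            degree[j] += 1
        for idx in range(len(nodes) - 1, -1, -1):
            if nodes[idx] in observed or degree[idx] > 2:
                continue
            reduced = nodes[:idx] + nodes[idx + 1:]
            new_cost, _ = _mst_cost_and_edges(reduced, w)
            if new_cost <= cost + 1e-9:
                nodes = reduced
                changed = True
                break

    cost, _ = _mst_cost_and_edges(nodes, w)
    edges = _msn_edges(nodes, w, epsilon)
    g = nx.Graph()
    for vec in nodes:
        h = observed.get(vec)
        g.add_node(
            vec,
            is_median=h is None,
            counts=dict(h.counts) if h else {},
            samples=list(h.samples) if h else [],
        )
    for i, j, d in edges:
        steps = tuple(abs(a - b) for a, b in zip(nodes[i], nodes[j]))
        g.add_edge(nodes[i], nodes[j], length=d, steps=steps)
    if len(nodes) > 1 and not nx.is_connected(g):
        raise AssertionError("median-joining network must be connected")
    return HaploNetwork(
        graph=g, loci=NET_LOCI[:n_loci] if n_loci == len(NET_LOCI) else tuple(
            f"L{i}" for i in range(n_loci)
        ),
        weights=list(weights), spanning_cost=cost,
    )


def ancestral_node(haplotypes: list[NetHaplotype],
                   weights: list[LocusWeight]) -> tuple[int, ...]:
    """Frequency-weighted medoid: the observed haplotype minimizing the
    count-weighted distance to all observed haplotypes.

    Ties break toward the higher own count, then the lexicographically
    smallest vector, so the choice is deterministic.
    """
    if not haplotypes:
        raise ValueError("need at least one haplotype")
    w = _weight_vector(weights, len(haplotypes[0].vector))
    best = None
    for h in haplotypes:
        total = sum(
            other.count * _dist(h.vector, other.vector, w)
            for other in haplotypes
        )
        key = (total, -h.count, h.vector)
        if best is None or key < best[0]:
            best = (key, h.vector)
    return best[1]


def network_composition_summary(net: HaploNetwork,
                                ancestor: tuple[int, ...]) -> dict[str, dict]:
    """Per-population summary of the network relative to the ancestral node.

    For each population: number of sampled chromosomes, number of distinct
    haplotypes, and the count-weighted mean and median of the shortest
    weighted path length from its haplotypes to the ancestral node.
    Populations present in node annotations but without any usable
    haplotype are omitted with a log entry.
    """
    if ancestor not in net.graph:
        raise KeyError("ancestral node not in network")
    lengths = nx.single_source_dijkstra_path_length(
        net.graph, ancestor, weight="length"
    )
    per_pop: dict[str, list[tuple[float, int]]] = {}
    for node, data in net.nodes(medians=False):
        for pop, count in data["counts"].items():
            if count > 0:
                per_pop.setdefault(pop, []).append((lengths[node], count))
    out = {}
    for pop, pairs in sorted(per_pop.items()):
        expanded = np.repeat(
            [d for d, _c in pairs], [c for _d, c in pairs]
        ).astype(float)
        out[pop] = {
            "n_samples": int(expanded.size),
            "n_haplotypes": len(pairs),
            "mean_distance_to_ancestor": float(expanded.mean()),
            "median_distance_to_ancestor": float(np.median(expanded)),
        }
    return out
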