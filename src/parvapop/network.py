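"""Weighted median-joining haplotype networks and neighbour-joining trees.

The median-joining network starts from the minimum-spanning network over
sampled haplotypes (keeping all ties), then augments it with quasi-median
(consensus) vectors of feasible triplets until closure, and finally prunes
unsampled vectors of degree <= 2 — the epsilon = 0 variant of Bandelt's
algorithm.  Distances are weighted per site (homoplastic positions can be
down-weighted) with transversions up-weighted relative to transitions, which
penalises the changes most likely to be homoplastic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from parvapop.errors import InputError, ParameterError
from parvapop.popio import AlignedSequenceSet, HaplotypeTable

PURINES = frozenset("AG")


@dataclass(frozen=True)
class SiteWeightScheme:
    """Per-site weights for network distances.

    ``homoplastic_sites`` are 1-based positions (on the trimmed alignment)
    down-weighted to ``homoplastic_weight``; every other site carries
    ``default_weight``.  Transversions are multiplied by ``tv_multiplier``.
    """

    default_weight: float = 50.0
    homoplastic_sites: frozenset[int] = frozenset()
    homoplastic_weight: float = 1.0
    tv_multiplier: float = 3.0
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.default_weight <= 0 or self.homoplastic_weight <= 0:
            raise ParameterError("site weights must be positive")
        if self.epsilon < 0:
            raise ParameterError("epsilon must be >= 0")

    def site_weight(self, pos0: int) -> float:
        """Weight of the 0-based site ``pos0``."""
        return self.homoplastic_weight if (pos0 + 1) in self.homoplastic_sites else self.default_weight


def weighted_distance(a: str, b: str, scheme: SiteWeightScheme) -> float:
    """Sum of site weights (x tv multiplier) over differing sites."""
    total = 0.0
    for i, (x, y) in enumerate(zip(a, b)):
        if x == y:
            continue
        w = scheme.site_weight(i)
        if (x in PURINES) != (y in PURINES):
            w *= scheme.tv_multiplier
        total += w
    return total


def _msn_edges(seqs: list[str], scheme: SiteWeightScheme) -> list[tuple[int, int, float]]:
    """Minimum-spanning network: Kruskal by weight level, keeping all ties.

    An edge at weight level w is kept iff its endpoints lie in different
    components *before* any edge of weight w is added.
    """
    n = len(seqs)
    dist = {}
    for i, j in itertools.combinations(range(n), 2):
        dist[(i, j)] = weighted_distance(seqs[i], seqs[j], scheme)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = []
    by_weight: dict[float, list[tuple[int, int]]] = {}
    for (i, j), w in dist.items():
        by_weight.setdefault(w, []).append((i, j))
    for w in sorted(by_weight):
        level = [(i, j) for i, j in by_weight[w] if find(i) != find(j)]
        for i, j in level:
            edges.append((i, j, w))
        for i, j in level:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return edges


def _quasi_median(u: str, v: str, w: str) -> str:
    """Per-site majority consensus of a triplet; ties keep the hub state."""
    out = []
    for a, b, c in zip(u, v, w):
        if b == c:
            out.append(b)
        else:
            out.append(a)
    return "".join(out)


@dataclass
class HaplotypeNetwork:
    """Median-joining network: sampled haplotypes plus median vectors."""

    graph: nx.Graph
    sampled: list[str]
    median_vectors: list[str]

    def edge_table(self) -> list[tuple[str, str, float, tuple[int, ...]]]:
        """(node, node, weighted steps, 1-based mutated sites) per edge."""
        rows = []
        for u, v, data in self.graph.edges(data=True):
            rows.append((u, v, data["weight"], data["sites"]))
        return rows


def build_mj_network(
    hap: HaplotypeTable,
    scheme: SiteWeightScheme | None = None,
    exclusions=(),
    max_rounds: int = 20,
) -> HaplotypeNetwork:
    """Build the epsilon = 0 median-joining network of a haplotype table.

    Median (consensus) vectors of triplets ``(v, hub, w)`` where both ``v``
    and ``w`` are minimum-spanning-network neighbours of the hub are added
    whenever connecting the triplet through the median is strictly cheaper
    than the two spanning edges; the augmentation iterates to closure, then
    unsampled vectors of degree <= 2 are pruned.
    """
    if scheme is None:
        scheme = SiteWeightScheme()
    keep = [i for i, h in enumerate(hap.hap_ids) if h not in set(exclusions)]
    if len(keep) < 1:
        raise InputError("no haplotypes left after exclusions")
    names = {hap.representatives[i]: hap.hap_ids[i] for i in keep}
    counts_total = hap.counts.sum(axis=1)
    sampled_seqs = sorted(names)  # canonical order: input order must not matter
    nodes = list(sampled_seqs)
    node_set = set(nodes)

    for _ in range(max_rounds):
        edges = _msn_edges(nodes, scheme)
        adj: dict[int, list[int]] = {i: [] for i in range(len(nodes))}
        for i, j, _w in edges:
            adj[i].append(j)
            adj[j].append(i)
        dist_cache: dict[tuple[int, int], float] = {}

        def d(i: int, j: int) -> float:
            key = (i, j) if i < j else (j, i)
            if key not in dist_cache:
                dist_cache[key] = weighted_distance(nodes[key[0]], nodes[key[1]], scheme)
            return dist_cache[key]

        new: set[str] = set()
        for hub in range(len(nodes)):
            for a, b in itertools.combinations(sorted(adj[hub]), 2):
                m = _quasi_median(nodes[hub], nodes[a], nodes[b])
                if m in node_set or m in new:
                    continue
                star = (
                    weighted_distance(m, nodes[hub], scheme)
                    + weighted_distance(m, nodes[a], scheme)
                    + weighted_distance(m, nodes[b], scheme)
                )
                if star < d(hub, a) + d(hub, b) - 1e-9:
                    new.add(m)
        if not new:
            break
        for m in sorted(new):
            nodes.append(m)
            node_set.add(m)

    # Prune obsolete median vectors (unsampled, degree <= 2), iterating to a
    # fixed point since pruning can reduce other medians' degrees.
    while True:
        edges = _msn_edges(nodes, scheme)
        degree = {i: 0 for i in range(len(nodes))}
        for i, j, _w in edges:
            degree[i] += 1
            degree[j] += 1
        drop = [
            i
            for i in range(len(nodes))
            if nodes[i] not in names and degree[i] <= 2
        ]
        if not drop:
            break
        nodes = [nodes[i] for i in range(len(nodes)) if i not in set(drop)]

    g = nx.Graph()
    medians = []
    mv = 0
    label = {}
    for seq in nodes:
        if seq in names:
            label[seq] = names[seq]
            g.add_node(
                names[seq],
                sequence=seq,
                sampled=True,
                count=int(counts_total.get(names[seq], 0)),
            )
        else:
            mv += 1
            label[seq] = f"mv{mv}"
            medians.append(seq)
            g.add_node(label[seq], sequence=seq, sampled=False, count=0)
    for i, j, w in _msn_edges(nodes, scheme):
        sites = tuple(
            k + 1 for k, (x, y) in enumerate(zip(nodes[i], nodes[j])) if x != y
        )
        g.add_edge(label[nodes[i]], label[nodes[j]], weight=w, sites=sites)
    return HaplotypeNetwork(
        graph=g,
        sampled=[names[s] for s in nodes if s in names],
        median_vectors=medians,
    )


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------


@dataclass
class PhyloTree:
    """Unrooted tree as a graph with branch lengths and optional supports."""

    graph: nx.Graph
    leaves: list[str]
    supports: dict[frozenset, float] = field(default_factory=dict)

    def bipartitions(self) -> dict[frozenset, tuple]:
        """Non-trivial bipartitions, keyed by the frozenset pair of leaf sets."""
        out = {}
        for u, v in self.graph.edges():
            g = self.graph.copy()
            g.remove_edge(u, v)
            comp = nx.node_connected_component(g, u)
            side_a = frozenset(l for l in self.leaves if l in comp)
            side_b = frozenset(self.leaves) - side_a
            if len(side_a) >= 2 and len(side_b) >= 2:
                out[frozenset({side_a, side_b})] = (u, v)
        return out

    def newick(self) -> str:
        """Newick string rooted at an arbitrary internal node.

        Internal node labels carry bootstrap supports (percent) when
        available.
        """
        internal = [n for n in self.graph.nodes if n not in self.leaves]
        root = internal[-1] if internal else self.leaves[0]

        def rec(node, parent):
            children = [n for n in self.graph.neighbors(node) if n != parent]
            if not children:
                bl = self.graph.edges[(parent, node)]["length"]
                return f"{node}:{bl:.6g}"
            inner = ",".join(rec(c, node) for c in children)
            lab = ""
            if parent is not None:
                edge = frozenset(self._split_of_edge(parent, node))
                sup = self.supports.get(edge)
                lab = f"{sup:.0f}" if sup is not None else ""
                bl = self.graph.edges[(parent, node)]["length"]
                return f"({inner}){lab}:{bl:.6g}"
            return f"({inner});"

        return rec(root, None)

    def _split_of_edge(self, parent, node):
        g = self.graph.copy()
        g.remove_edge(parent, node)
        comp = nx.node_connected_component(g, node)
        side = frozenset(l for l in self.leaves if l in comp)
        return side, frozenset(self.leaves) - side

    def leaf_distance(self, a: str, b: str) -> float:
        """Path length between two leaves."""
        return nx.shortest_path_length(self.graph, a, b, weight="length")


def nj_tree(d: np.ndarray | "object", labels: list[str] | None = None) -> PhyloTree:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    ``d`` may be a square numpy array (with ``labels``) or a pandas
    DataFrame.  Ties in the Q criterion resolve to the lowest index pair.
    Negative branch-length estimates are clamped to zero.
    """
    if hasattr(d, "to_numpy"):
        labels = list(d.index)
        d = d.to_numpy(dtype=float)
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if labels is None:
        labels = [f"T{i}" for i in range(n)]
    if n < 3:
        raise ParameterError("NJ needs >= 3 taxa")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise InputError("distance matrix must be symmetric with zero diagonal")
    if np.isnan(d).any():
        raise InputError("distance matrix contains NaN")

    g = nx.Graph()
    active = list(range(n))
    names = {i: labels[i] for i in range(n)}
    D = d.copy()
    next_id = n
    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i, j) pair on ties: argmin scans row-major
        k = int(np.argmin(Q))
        ai, aj = divmod(k, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = idx[ai], idx[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = next_id
        next_id += 1
        names[u] = f"I{u}"
        g.add_edge(names[i], names[u], length=float(li))
        g.add_edge(names[j], names[u], length=float(lj))
        D = np.pad(D, ((0, 1), (0, 1)))
        for k2 in active:
            if k2 in (i, j):
                continue
            D[u, k2] = D[k2, u] = 0.5 * (D[i, k2] + D[j, k2] - dij)
        active = [a for a in active if a not in (i, j)] + [u]
    # final three taxa join at a central node
    a, b, c = active
    centre = f"I{next_id}"
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for node, l in ((a, la), (b, lb), (c, lc)):
        g.add_edge(names[node], centre, length=float(max(l, 0.0)))
    return PhyloTree(graph=g, leaves=list(labels))


def bootstrap_support(
    aln: AlignedSequenceSet,
    B: int = 1000,
    seed: int = 0,
    distance=None,
) -> PhyloTree:
    """NJ tree with non-parametric bootstrap supports (percent of B).

    Columns are resampled with replacement; each replicate rebuilds the
    distance matrix (K2P by default) and the NJ tree, and every original
    non-trivial bipartition is scored by the percentage of replicates that
    contain it.
    """
    from parvapop.diversity import k2p_distance

    if B < 1:
        raise ParameterError("B must be >= 1")
    if distance is None:
        distance = k2p_distance
    if len(aln) < 3:
        raise ParameterError("bootstrap needs >= 3 sequences")

    def matrix(seqs):
        m = len(seqs)
        out = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                out[i, j] = out[j, i] = distance(seqs[i], seqs[j])
        return out

    tree = nj_tree(matrix(list(aln.seqs)), labels=list(aln.ids))
    original = tree.bipartitions()
    hits = {k: 0 for k in original}
    rng = np.random.default_rng(seed)
    arr = np.array([list(s) for s in aln.seqs])
    for _ in range(B):
        cols = rng.integers(aln.L, size=aln.L)
        seqs = ["".join(row) for row in arr[:, cols]]
        rep = nj_tree(matrix(seqs), labels=list(aln.ids))
        for k in rep.bipartitions():
            if k in hits:
                hits[k] += 1
    tree.supports = {k: 100.0 * v / B for k, v in hits.items()}
    return tree
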