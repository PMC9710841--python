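"""Independent brute-force reference implementations used as oracles.

Everything here works on a plain adjacency dict built from an explicit
edge list, enumerates paths/triplets/partitions exhaustively, and keeps
distances as exact :class:`fractions.Fraction` values so shortest-path
ties are decided exactly.  Intended for graphs of at most ~8 nodes.
Nothing in this module calls the package under test or networkx.
"""

from __future__ import annotations

import itertools
import random
from fractions import Fraction


class BruteGraph:
    def __init__(self, nodes, edges):
        self.nodes = list(nodes)
        self.adj: dict = {u: {} for u in self.nodes}
        for u, v, w in edges:
            self.adj[u][v] = w
            self.adj[v][u] = w

    @property
    def n(self) -> int:
        return len(self.nodes)

    def edges(self):
        seen = set()
        for u in self.nodes:
            for v, w in self.adj[u].items():
                if (v, u) not in seen:
                    seen.add((u, v))
                    yield u, v, w

    def degree(self, u) -> int:
        return len(self.adj[u])

    def has_edge(self, u, v) -> bool:
        return v in self.adj[u]


def _edge_length(w, scheme: str):
    return Fraction(1, w) if scheme == "inverse-weight" else 1


def all_simple_paths(g: BruteGraph, s, t):
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            yield path
            continue
        for nbr in g.adj[node]:
            if nbr not in path:
                stack.append((nbr, path + [nbr]))


def path_length(g: BruteGraph, path, scheme: str):
    return sum(_edge_length(g.adj[u][v], scheme) for u, v in zip(path, path[1:]))


def sp_distance(g: BruteGraph, s, t, scheme: str = "inverse-weight"):
    """Exact shortest-path length by exhaustive simple-path enumeration,
    or None when unreachable (shortest paths are simple for positive
    lengths)."""
    if s == t:
        return Fraction(0)
    best = None
    for path in all_simple_paths(g, s, t):
        length = path_length(g, path, scheme)
        if best is None or length < best:
            best = length
    return best


def shortest_path_set(g: BruteGraph, s, t, scheme: str = "inverse-weight"):
    """All geodesics between s and t (ties resolved exactly)."""
    best, paths = None, []
    for path in all_simple_paths(g, s, t):
        length = path_length(g, path, scheme)
        if best is None or length < best:
            best, paths = length, [path]
        elif length == best:
            paths.append(path)
    return paths


def betweenness(g: BruteGraph, node, scheme: str = "inverse-weight") -> float:
    """Normalized fractional betweenness: over pairs of other nodes, the
    share of geodesics with ``node`` in the interior, divided by the
    number of such pairs."""
    if g.n < 3:
        return 0.0
    total = Fraction(0)
    others = [v for v in g.nodes if v != node]
    for s, t in itertools.combinations(others, 2):
        geos = shortest_path_set(g, s, t, scheme)
        if not geos:
            continue
        through = sum(1 for p in geos if node in p[1:-1])
        total += Fraction(through, len(geos))
    n_pairs = (g.n - 1) * (g.n - 2) // 2
    return float(total / n_pairs)


def closeness(g: BruteGraph, node) -> float:
    dists = [sp_distance(g, node, v) for v in g.nodes if v != node]
    total = sum(d for d in dists if d is not None)
    return float(Fraction(g.n - 1) / total) if total > 0 else float("nan")


def geodesic_mean(g: BruteGraph) -> float:
    dists = [
        sp_distance(g, s, t)
        for s, t in itertools.combinations(g.nodes, 2)
    ]
    finite = [d for d in dists if d is not None]
    return float(sum(finite) / len(finite)) if finite else float("nan")


def components(g: BruteGraph):
    left = set(g.nodes)
    while left:
        comp, stack = set(), [next(iter(left))]
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(v for v in g.adj[u] if v not in comp)
        left -= comp
        yield comp


def diameter_hops(g: BruteGraph) -> float:
    giant = max(components(g), key=len)
    best = 0
    for s, t in itertools.combinations(sorted(giant, key=repr), 2):
        d = sp_distance(g, s, t, scheme="hop")
        best = max(best, int(d))
    return float(best)


def transitivity(g: BruteGraph) -> float:
    closed = total = 0
    for center in g.nodes:
        for a, b in itertools.combinations(sorted(g.adj[center], key=repr), 2):
            total += 1
            if g.has_edge(a, b):
                closed += 1
    return closed / total if total else 0.0


def density(g: BruteGraph) -> float:
    return sum(1 for _ in g.edges()) / (g.n * (g.n - 1) / 2)


def degree_centralization(g: BruteGraph) -> float:
    degs = [g.degree(u) for u in g.nodes]
    return sum(max(degs) - d for d in degs) / (g.n - 1)


# -- modularity by exhaustive partition search ------------------------------


def _partitions_rgs(items: list):
    """Set partitions via restricted-growth strings."""
    n = len(items)
    if n == 0:
        yield []
        return
    rgs = [0] * n
    maxes = [0] * n
    while True:
        n_blocks = max(rgs) + 1
        blocks = [[] for _ in range(n_blocks)]
        for item, b in zip(items, rgs):
            blocks[b].append(item)
        yield blocks
        i = n - 1
        while i > 0 and rgs[i] == maxes[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        rgs[i] += 1
        maxes[i] = max(maxes[i - 1], rgs[i])
        for j in range(i + 1, n):
            rgs[j] = 0
            maxes[j] = maxes[i]


def modularity(g: BruteGraph, blocks) -> Fraction:
    """Weighted Newman modularity from first principles."""
    m2 = sum(2 * w for _, _, w in g.edges())  # 2m
    if m2 == 0:
        return Fraction(0)
    strength = {u: sum(g.adj[u].values()) for u in g.nodes}
    label = {u: i for i, blk in enumerate(blocks) for u in blk}
    q = Fraction(0)
    for u in g.nodes:
        for v in g.nodes:
            if label[u] != label[v]:
                continue
            a_uv = g.adj[u].get(v, 0)  # zero on the diagonal (no self-loops)
            q += Fraction(a_uv) - Fraction(strength[u] * strength[v], m2)
    return q / m2


def optimal_partitions(g: BruteGraph):
    """(max modularity, list of all optimal partitions as frozensets)."""
    best_q, best = None, []
    for blocks in _partitions_rgs(sorted(g.nodes, key=repr)):
        q = modularity(g, blocks)
        key = frozenset(frozenset(b) for b in blocks)
        if best_q is None or q > best_q:
            best_q, best = q, [key]
        elif q == best_q:
            best.append(key)
    return float(best_q), best


# -- egocentric oracles ------------------------------------------------------


def ego_subgraph(g: BruteGraph, ego) -> BruteGraph:
    keep = {ego} | set(g.adj[ego])
    edges = [(u, v, w) for u, v, w in g.edges() if u in keep and v in keep]
    return BruteGraph(sorted(keep, key=repr), edges)


def effective_size(g: BruteGraph, ego) -> float:
    alters = sorted(g.adj[ego], key=repr)
    ties_per_alter = [sum(1 for other in alters if other != j and g.has_edge(j, other)) for j in alters]
    return len(alters) - sum(ties_per_alter) / len(alters)


def efficiency(g: BruteGraph, ego) -> float:
    return effective_size(g, ego) / (len(g.adj[ego]) + 1)


def constraint(g: BruteGraph, ego) -> float:
    """Burt constraint recomputed from an explicit proportion table."""
    eg = ego_subgraph(g, ego)
    nbrs = sorted(eg.adj[ego], key=repr)
    p = {}
    for u in eg.nodes:
        tot = sum(eg.adj[u].values())
        for v in eg.nodes:
            p[(u, v)] = Fraction(eg.adj[u].get(v, 0), tot)
    total = Fraction(0)
    for j in nbrs:
        inner = p[(ego, j)] + sum(p[(ego, q)] * p[(q, j)] for q in nbrs if q != j)
        total += inner * inner
    return float(total)


def reach_efficiency(g: BruteGraph, ego) -> float:
    one = set(g.adj[ego])
    two = set(one)
    for v in one:
        two |= set(g.adj[v])
    two.discard(ego)
    return (len(two) / (g.n - 1)) / (len(one) + 1)


def avg_dyadic_redundancy(g: BruteGraph, ego) -> float:
    alters = sorted(g.adj[ego], key=repr)
    counts = [sum(1 for other in alters if other != j and g.has_edge(j, other)) for j in alters]
    return sum(counts) / len(counts)


def avg_similarity(g: BruteGraph, ego) -> float:
    alters = sorted(g.adj[ego], key=repr)
    nbrs = set(g.adj[ego])
    return sum(len(nbrs & set(g.adj[j])) for j in alters) / len(alters)


def rmssd(series) -> float:
    total = 0.0
    n = len(series)
    for i in range(n - 1):
        total += (series[i] - series[i + 1]) ** 2
    return (total / (n - 1)) ** 0.5


# -- random test graphs ------------------------------------------------------

#: Weights restricted to powers of two so inverse-weight path lengths are
#: exact in binary floating point and tie behavior matches the Fraction
#: arithmetic used here.
WEIGHT_CHOICES = (1, 2, 4, 8, 16)


def random_connected_graph(rng: random.Random, n_min: int = 3, n_max: int = 7):
    """(nodes, edges) of a random connected weighted graph."""
    n = rng.randint(n_min, n_max)
    nodes = list(range(n))
    while True:
        edges = [
            (u, v, rng.choice(WEIGHT_CHOICES))
            for u, v in itertools.combinations(nodes, 2)
            if rng.random() < 0.5
        ]
        g = BruteGraph(nodes, edges)
        if edges and len(next(iter(components(g)))) == n:
            return nodes, edges
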