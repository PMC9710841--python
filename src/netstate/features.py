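"""The 26 social-network features: 9 global structural, 4 global nodal,
13 egocentric.

Distance conventions
--------------------
Two shortest-path schemes coexist, mirroring common SNA practice on
contact-count networks:

* ``"inverse-weight"`` -- edge length 1/weight, so frequent contact means
  "close".  Used for closeness, betweenness and geodesic means.
* ``"hop"`` -- every edge has length 1.  Used for the diameter and for
  two-step reach.

Degree everywhere means unweighted edge count (number of distinct contact
partners), not strength.  Degree centralization uses the plain
sum-of-shortfalls normalization Σ_i (d_max − d_i) / (n − 1); note this is
not Freeman's (n−1)(n−2) denominator, a deliberate and documented choice.

Egocentric features follow Burt's structural-hole quantities where named
(effective size, efficiency, constraint), with constraint weighted by
contact counts and efficiency normalized by the ego-network order
(ego + alters); ``efficiency_denominator="alters"`` switches to Burt's
alters-only convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import networkx as nx
import numpy as np
import pandas as pd

from .networks import MissingEgoError, extract_ego_network

Scheme = Literal["inverse-weight", "hop"]

#: Feature-matrix column order: 9 global structural, 4 global nodal,
#: 13 egocentric, then the week index used as an additional predictor.
GLOBAL_STRUCTURAL_COLUMNS: tuple[str, ...] = (
    "order",
    "size",
    "n_ordered_pairs",
    "density",
    "diameter",
    "geodesic_distance",
    "transitivity",
    "centralization_degree",
    "n_subcommunities",
)
GLOBAL_NODAL_COLUMNS: tuple[str, ...] = (
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "community_percent_size",
)
EGO_COLUMNS: tuple[str, ...] = (
    "avg_dyadic_redundancy",
    "avg_similarity",
    "betweenness_ego",
    "centralization_ego",
    "constraint",
    "density_ego",
    "effective_size",
    "efficiency",
    "geodesic_distance_ego",
    "n_ordered_pairs_ego",
    "reach_efficiency",
    "size_ego",
    "transitivity_ego",
)
FEATURE_COLUMNS: tuple[str, ...] = GLOBAL_STRUCTURAL_COLUMNS + GLOBAL_NODAL_COLUMNS + EGO_COLUMNS
MATRIX_COLUMNS: tuple[str, ...] = FEATURE_COLUMNS + ("week",)

DEFAULT_LOUVAIN_SEED = 2012


def _with_lengths(net: nx.Graph, scheme: Scheme) -> nx.Graph:
    """Annotate a copy of ``net`` with a ``length`` edge attribute."""
    g = net.copy()
    for _, _, d in g.edges(data=True):
        d["length"] = 1.0 / d["weight"] if scheme == "inverse-weight" else 1.0
    return g


def shortest_paths(net: nx.Graph, scheme: Scheme = "inverse-weight") -> pd.DataFrame:
    """Exact all-pairs shortest-path matrix under the named scheme.

    Unreachable pairs are ``inf``; the diagonal is zero.
    """
    nodes = list(net.nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    g = _with_lengths(net, scheme)
    arr = np.full((len(nodes), len(nodes)), np.inf)
    np.fill_diagonal(arr, 0.0)
    for src, dists in nx.all_pairs_dijkstra_path_length(g, weight="length"):
        i = pos[src]
        for dst, d in dists.items():
            arr[i, pos[dst]] = d
    return pd.DataFrame(arr, index=nodes, columns=nodes)


def _mean_inverse_geodesic(net: nx.Graph) -> float:
    """Mean inverse-weight shortest-path length over connected pairs,
    without materializing the full matrix."""
    g = _with_lengths(net, "inverse-weight")
    total, count = 0.0, 0
    for _, dists in nx.all_pairs_dijkstra_path_length(g, weight="length"):
        for d in dists.values():
            total += d
        count += len(dists) - 1  # reachable others (self has d=0)
    return total / count if count else float("nan")


@dataclass
class Partition:
    """A Louvain community partition of one weekly network."""

    membership: dict  # node -> community label (0-based int)
    n_communities: int
    modularity: float
    seed: int
    sizes: dict[int, int] = field(default_factory=dict)

    def community_of(self, node) -> int:
        return self.membership[node]


#: Below this order the modularity optimum is found by exhaustive
#: enumeration; Louvain's greedy local moves can miss it on tiny graphs.
EXACT_PARTITION_MAX_NODES = 8
LOUVAIN_RESTARTS = 8


def _set_partitions(nodes: list):
    """All set partitions of ``nodes`` (recursive; only used for tiny n)."""
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def detect_communities(net: nx.Graph, seed: int = DEFAULT_LOUVAIN_SEED, resolution: float = 1.0) -> Partition:
    """Weighted modularity communities (resolution 1.0 by default).

    Tiny graphs (≤ 8 nodes) are partitioned by exhaustive search for the
    exact modularity optimum; larger graphs use seeded multi-restart
    Louvain, keeping the best-modularity run.  Deterministic for a fixed
    seed; every node is labeled exactly once.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty graph")
    if net.number_of_edges() == 0:
        membership = {v: i for i, v in enumerate(sorted(net.nodes, key=repr))}
        return Partition(
            membership=membership,
            n_communities=len(membership),
            modularity=float("nan"),
            seed=seed,
            sizes={i: 1 for i in membership.values()},
        )
    if net.number_of_nodes() <= EXACT_PARTITION_MAX_NODES:
        best_q, comms = -2.0, None
        for cand in _set_partitions(sorted(net.nodes, key=repr)):
            q = nx.community.modularity(net, cand, weight="weight", resolution=resolution)
            if q > best_q + 1e-12:
                best_q, comms = q, cand
    else:
        best_q, comms = -2.0, None
        for r in range(LOUVAIN_RESTARTS):
            cand = nx.community.louvain_communities(net, weight="weight", resolution=resolution, seed=seed + r)
            q = nx.community.modularity(net, cand, weight="weight", resolution=resolution)
            if q > best_q + 1e-12:
                best_q, comms = q, cand
    comms = sorted((sorted(c, key=repr) for c in comms), key=lambda c: repr(c[0]))
    membership = {node: i for i, comm in enumerate(comms) for node in comm}
    q = nx.community.modularity(net, comms, weight="weight", resolution=resolution)
    sizes = {i: len(comm) for i, comm in enumerate(comms)}
    return Partition(membership=membership, n_communities=len(comms), modularity=q, seed=seed, sizes=sizes)


def compute_global_structural(net: nx.Graph, partition: Partition | None = None) -> dict[str, float]:
    """The nine whole-network structural features.

    density and centralization are undefined (NaN) below two nodes; the
    diameter is hop-based on the largest connected component; the geodesic
    mean uses inverse-weight lengths over connected pairs only.
    """
    n = net.number_of_nodes()
    m = net.number_of_edges()
    out: dict[str, float] = {
        "order": float(n),
        "size": float(m),
        "n_ordered_pairs": float(n * (n - 1)),
    }
    if n < 2:
        out["density"] = float("nan")
        out["centralization_degree"] = float("nan")
        out["diameter"] = float("nan")
        out["geodesic_distance"] = float("nan")
    else:
        out["density"] = m / (n * (n - 1) / 2)
        degs = [d for _, d in net.degree()]
        out["centralization_degree"] = sum(max(degs) - d for d in degs) / (n - 1)
        largest_cc = max(nx.connected_components(net), key=len)
        out["diameter"] = float(nx.diameter(net.subgraph(largest_cc)))
        out["geodesic_distance"] = _mean_inverse_geodesic(net)
    out["transitivity"] = float(nx.transitivity(net))
    out["n_subcommunities"] = float(partition.n_communities) if partition is not None else float("nan")
    return out


def compute_global_nodal(
    net: nx.Graph,
    node,
    partition: Partition,
    distances: pd.DataFrame | None = None,
    betweenness_scheme: Scheme = "inverse-weight",
) -> dict[str, float]:
    """The four node-in-whole-network features for one participant.

    closeness is (n−1) / Σ_j d(node, j) with inverse-weight lengths summed
    over reachable j; betweenness is the normalized fraction of shortest
    paths between other pairs through the node; community percent size is
    the node's Louvain community size as a fraction of the order.
    """
    if node not in net:
        raise KeyError(node)
    n = net.number_of_nodes()
    betw = betweenness(net, scheme=betweenness_scheme)
    return {
        "degree_centrality": net.degree(node) / (n - 1) if n > 1 else float("nan"),
        "closeness_centrality": _closeness(net, node, distances),
        "betweenness_centrality": betw[node],
        "community_percent_size": partition.sizes[partition.community_of(node)] / n,
    }


def _closeness(net: nx.Graph, node, distances: pd.DataFrame | None = None) -> float:
    n = net.number_of_nodes()
    if n < 2:
        return float("nan")
    if distances is None:
        g = _with_lengths(net, "inverse-weight")
        dists = nx.single_source_dijkstra_path_length(g, node, weight="length")
        total = sum(d for dst, d in dists.items() if dst != node)
    else:
        row = distances.loc[node].drop(node)
        total = float(row[np.isfinite(row)].sum())
    return (n - 1) / total if total > 0 else float("nan")


def betweenness(net: nx.Graph, scheme: Scheme = "inverse-weight") -> dict:
    """Normalized betweenness centrality for every node (fractional path
    counting; pairs not involving the node)."""
    g = _with_lengths(net, scheme)
    return nx.betweenness_centrality(g, normalized=True, weight="length")


# ---------------------------------------------------------------------------
# Egocentric features


def _alters(ego_net: nx.Graph, ego) -> list:
    return [v for v in ego_net.nodes if v != ego]


def effective_size(ego_net: nx.Graph, ego) -> float:
    """Burt effective size: alters minus the mean alter-alter tie count."""
    alters = _alters(ego_net, ego)
    k = len(alters)
    if k == 0:
        raise ValueError("ego has no alters")
    t_aa = sum(1 for a, b in ego_net.edges if a != ego and b != ego)
    return k - 2.0 * t_aa / k


def ego_efficiency(ego_net: nx.Graph, ego, denominator: Literal["order", "alters"] = "order") -> float:
    """Effective size normalized by the ego-network order (ego + alters),
    or by the alter count under Burt's original convention."""
    es = effective_size(ego_net, ego)
    denom = ego_net.number_of_nodes() if denominator == "order" else len(_alters(ego_net, ego))
    return es / denom


def burt_constraint(ego_net: nx.Graph, ego) -> float:
    """Burt aggregate constraint, weighted by contact counts.

    C = Σ_j (p_ij + Σ_q p_iq p_qj)² where p_ij is the share of i's total
    tie weight invested in j and q ranges over contacts shared by i and j.
    A single-alter ego has all its investment in one tie: constraint 1.
    """
    alters = _alters(ego_net, ego)
    if not alters:
        raise ValueError("ego has no alters")
    w_ego = {j: ego_net[ego][j]["weight"] for j in alters}
    total = sum(w_ego.values())
    p_ego = {j: w_ego[j] / total for j in alters}

    def p(q, j) -> float:
        if not ego_net.has_edge(q, j):
            return 0.0
        denom = sum(d["weight"] for _, _, d in ego_net.edges(q, data=True))
        return ego_net[q][j]["weight"] / denom

    c = 0.0
    for j in alters:
        indirect = sum(p_ego[q] * p(q, j) for q in alters if q != j)
        c += (p_ego[j] + indirect) ** 2
    return c


def reach_efficiency(net: nx.Graph, ego, ego_net: nx.Graph | None = None,
                     denominator: Literal["order", "alters"] = "order") -> float:
    """Two-step reach of the ego in the whole weekly network, as a fraction
    of all other nodes, normalized by the ego-network order."""
    if ego not in net:
        raise MissingEgoError(ego)
    if ego_net is None:
        ego_net = extract_ego_network(net, ego)
    one_step = set(net[ego])
    two_step = set().union(*(set(net[v]) for v in one_step)) | one_step
    two_step.discard(ego)
    n = net.number_of_nodes()
    frac = len(two_step) / (n - 1) if n > 1 else float("nan")
    denom = ego_net.number_of_nodes() if denominator == "order" else len(one_step)
    return frac / denom


def avg_dyadic_redundancy(ego_net: nx.Graph, ego) -> float:
    """Mean over alters of how many *other* alters each alter is tied to."""
    alters = _alters(ego_net, ego)
    if not alters:
        raise ValueError("ego has no alters")
    counts = [sum(1 for other in alters if other != j and ego_net.has_edge(j, other)) for j in alters]
    return float(np.mean(counts))


def avg_similarity(net: nx.Graph, ego) -> float:
    """Mean over alters of the number of neighbors shared with the ego,
    counted in the whole weekly network."""
    alters = list(net[ego])
    if not alters:
        raise ValueError("ego has no alters")
    nbrs_ego = set(net[ego])
    shared = [len(nbrs_ego & set(net[j])) for j in alters]
    return float(np.mean(shared))


def compute_ego_features(
    net: nx.Graph,
    ego,
    ego_net: nx.Graph | None = None,
    betweenness_scheme: Scheme = "inverse-weight",
    efficiency_denominator: Literal["order", "alters"] = "order",
) -> dict[str, float]:
    """All 13 egocentric features for one participant-week.

    Structural quantities (density, transitivity, centralization, geodesic
    mean, size, ordered pairs) are the whole-network formulas applied to
    the ego network; betweenness_ego is the ego's normalized betweenness
    over alter-alter pairs within its own neighborhood.  Degenerate
    denominators on single-edge ego networks fall back to 0 so the row
    survives.
    """
    if ego_net is None:
        ego_net = extract_ego_network(net, ego)
    gs = compute_global_structural(ego_net)
    betw_ego = betweenness(ego_net, scheme=betweenness_scheme)[ego]
    out = {
        "avg_dyadic_redundancy": avg_dyadic_redundancy(ego_net, ego),
        "avg_similarity": avg_similarity(net, ego),
        "betweenness_ego": betw_ego,
        "centralization_ego": gs["centralization_degree"],
        "constraint": burt_constraint(ego_net, ego),
        "density_ego": gs["density"],
        "effective_size": effective_size(ego_net, ego),
        "efficiency": ego_efficiency(ego_net, ego, denominator=efficiency_denominator),
        "geodesic_distance_ego": gs["geodesic_distance"],
        "n_ordered_pairs_ego": gs["n_ordered_pairs"],
        "reach_efficiency": reach_efficiency(net, ego, ego_net),
        "size_ego": gs["size"],
        "transitivity_ego": gs["transitivity"],
    }
    for key in ("centralization_ego", "transitivity_ego"):
        if not np.isfinite(out[key]):
            out[key] = 0.0
    return out


def weekly_feature_rows(
    net: nx.Graph,
    week_index: int,
    seed: int = DEFAULT_LOUVAIN_SEED,
    betweenness_scheme: Scheme = "inverse-weight",
    efficiency_denominator: Literal["order", "alters"] = "order",
) -> pd.DataFrame:
    """One feature row per node of a weekly network.

    Shared whole-network quantities (partition, betweenness, distances)
    are computed once and reused across the week's nodal rows.
    """
    if net.number_of_nodes() == 0:
        return pd.DataFrame(columns=["participant_id", *MATRIX_COLUMNS])
    partition = detect_communities(net, seed=seed)
    gs = compute_global_structural(net, partition)
    betw = betweenness(net, scheme=betweenness_scheme)
    distances = shortest_paths(net, "inverse-weight")
    n = net.number_of_nodes()

    rows = []
    for node in sorted(net.nodes, key=repr):
        ego_net = extract_ego_network(net, node)
        row: dict = {"participant_id": node}
        row.update(gs)
        row.update(
            {
                "degree_centrality": net.degree(node) / (n - 1) if n > 1 else float("nan"),
                "closeness_centrality": _closeness(net, node, distances),
                "betweenness_centrality": betw[node],
                "community_percent_size": partition.sizes[partition.community_of(node)] / n,
            }
        )
        row.update(
            compute_ego_features(
                net,
                node,
                ego_net,
                betweenness_scheme=betweenness_scheme,
                efficiency_denominator=efficiency_denominator,
            )
        )
        row["week"] = week_index
        rows.append(row)
    return pd.DataFrame(rows, columns=["participant_id", *MATRIX_COLUMNS])


def assemble_feature_matrix(
    networks: dict[int, nx.Graph],
    participants: Iterable | None = None,
    seed: int = DEFAULT_LOUVAIN_SEED,
    betweenness_scheme: Scheme = "inverse-weight",
    efficiency_denominator: Literal["order", "alters"] = "order",
) -> pd.DataFrame:
    """Stack weekly rows into the person-week predictor matrix.

    A row exists only where the participant has at least one reconciled
    edge that week; the week index rides along as an integer predictor.
    ``participants`` optionally restricts rows to a known roster.
    """
    frames = [
        weekly_feature_rows(
            net,
            wk,
            seed=seed,
            betweenness_scheme=betweenness_scheme,
            efficiency_denominator=efficiency_denominator,
        )
        for wk, net in sorted(networks.items())
    ]
    matrix = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=["participant_id", *MATRIX_COLUMNS])
    if participants is not None:
        roster = set(participants)
        matrix = matrix[matrix["participant_id"].isin(roster)].reset_index(drop=True)
    matrix["week"] = matrix["week"].astype(int)
    return matrix
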