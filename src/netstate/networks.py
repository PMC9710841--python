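"""Weekly network construction with detector-reciprocity reconciliation.

Sociometric badges log interactions per direction, and the two detectors
of a dyad frequently disagree (one logs an event the other misses).  The
reconciliation rule is conservative: for an unordered pair {a, b} with
``c_ab`` records logged by a about b and ``c_ba`` logged by b about a, the
undirected edge weight is ``min(c_ab, c_ba)`` -- the minimum number of
interactions both detectors agree on.  Pairs where either direction is
zero get no edge, and participants with no reconciled edge that week get
no node (their person-week rows are later treated as missing).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd


class MissingEgoError(KeyError):
    """Raised when an ego network is requested for a participant absent
    from that week's reconciled network (a missing person-week)."""


def build_weekly_network(records: pd.DataFrame, week_index: int | None = None) -> nx.Graph:
    """Build one week's undirected weighted graph from directed records.

    Parameters
    ----------
    records : DataFrame
        Parsed interaction rows for a single week (``logger_id``,
        ``detected_id`` columns; timestamps are not used here).
    week_index : int, optional
        Stored as a graph attribute for bookkeeping.

    The output is independent of row order and of which side of a dyad
    did the logging: ``min(c_ab, c_ba)`` is symmetric by construction.
    An empty week yields an empty graph.
    """
    net = nx.Graph(week_index=week_index)
    if records.empty:
        return net
    counts = records.groupby(["logger_id", "detected_id"]).size()
    seen: set[tuple] = set()
    for (a, b), c_ab in counts.items():
        key = (a, b) if repr(a) <= repr(b) else (b, a)
        if key in seen:
            continue
        seen.add(key)
        c_ba = int(counts.get((b, a), 0))
        w = min(int(c_ab), c_ba)
        if w >= 1:
            net.add_edge(a, b, weight=w)
    return net


def build_all_networks(weekly_records: dict[int, pd.DataFrame]) -> dict[int, nx.Graph]:
    """Reconcile every week's records into a graph, keyed by week index."""
    return {wk: build_weekly_network(df, week_index=wk) for wk, df in sorted(weekly_records.items())}


def extract_ego_network(net: nx.Graph, ego) -> nx.Graph:
    """Vertex-induced subgraph on the ego plus its alters.

    All alter-alter edges of the parent network are retained with their
    weights (one-step neighborhood, edges induced).  Raises
    :class:`MissingEgoError` when the ego has no node that week.
    """
    if ego not in net:
        raise MissingEgoError(ego)
    nodes = {ego} | set(net[ego])
    ego_net = net.subgraph(nodes).copy()
    ego_net.graph["ego"] = ego
    return ego_net


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(net, path)


def read_graphml(path: str | Path) -> nx.Graph:
    net = nx.read_graphml(path)
    # GraphML stores attribute types; make sure weights come back numeric
    for _, _, d in net.edges(data=True):
        d["weight"] = int(d["weight"])
    return net


def write_edgelist(net: nx.Graph, path: str | Path) -> None:
    """Plain whitespace-delimited ``a b w`` weighted edge list."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for a, b, d in sorted(net.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{a} {b} {d['weight']}\n")


def read_edgelist(path: str | Path) -> nx.Graph:
    net = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            a, b, w = parts
            net.add_edge(a, b, weight=int(w))
    return net
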