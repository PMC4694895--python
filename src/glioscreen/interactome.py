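"""Molecular-interaction graph queries: shared interactants and hubs.

Edges are undirected and typed (protein-protein, protein-DNA, protein-RNA,
genetic); self-loops are dropped and duplicate rows collapse to one edge.
Edges expanded from a documented intermediary ("A interacts with B via X")
carry ``mediated=True``; directly documented bindings carry
``mediated=False``. Queries ignore edge types by default — the curated
tables mix them — but can be restricted.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = ["build_graph", "common_interactants", "hubs", "degree_table"]

DEFAULT_TYPE = "protein-protein"


def build_graph(edges: Iterable[Sequence]) -> nx.Graph:
    """Build a deduplicated undirected graph from edge rows.

    Each row is ``(a, b)`` optionally followed by a mediated flag (bool) or
    an interaction type (str) and evidence label. Duplicate rows collapse;
    a pair documented both directly and as mediated keeps ``mediated=False``
    (the stronger evidence).
    """
    g = nx.Graph()
    for row in edges:
        row = tuple(row)
        if len(row) < 2:
            raise ValueError(f"malformed edge row: {row!r}")
        a, b = str(row[0]).strip(), str(row[1]).strip()
        if not a or not b:
            raise ValueError(f"malformed edge row: {row!r}")
        if a == b:
            continue
        mediated = False
        etype = DEFAULT_TYPE
        evidence = ""
        known_types = {"protein-protein", "protein-DNA", "protein-RNA",
                       "genetic"}
        for extra in row[2:]:
            if isinstance(extra, (bool, np.bool_)):
                mediated = bool(extra)
            elif isinstance(extra, str) and extra in known_types:
                etype = extra
            elif isinstance(extra, str):
                evidence = extra
        if g.has_edge(a, b):
            g[a][b]["mediated"] = g[a][b]["mediated"] and mediated
        else:
            g.add_edge(a, b, mediated=mediated, type=etype, evidence=evidence)
    return g


def read_edges(path) -> nx.Graph:
    """Read an edge TSV (node_a, node_b[, type, evidence]) into a graph."""
    import pandas as pd

    f = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "node_a" not in f.columns or "node_b" not in f.columns:
        raise ValueError("edge file needs node_a and node_b columns")
    cols = [c for c in ("node_a", "node_b", "type", "evidence")
            if c in f.columns]
    return build_graph(f[cols].itertuples(index=False, name=None))


def _neighbors(g: nx.Graph, node: str, mediated_only: bool,
               etype: str | None) -> set[str]:
    out = set()
    for nbr, attrs in g[node].items():
        if mediated_only and not attrs.get("mediated", False):
            continue
        if etype is not None and attrs.get("type", DEFAULT_TYPE) != etype:
            continue
        out.add(nbr)
    return out


def common_interactants(
    g: nx.Graph,
    a: str,
    b: str,
    mediated_only: bool = False,
    etype: str | None = None,
) -> set[str]:
    """Shared neighbors of ``a`` and ``b``, excluding the endpoints.

    With ``mediated_only`` only neighbors reached through documented
    intermediary (mediated) edges on both sides count — the convention the
    curated interaction tables use when they enumerate the intermediaries of
    a pair, which excludes partners that happen to bind both endpoints
    directly.
    """
    for node in (a, b):
        if node not in g:
            raise KeyError(f"unknown node: {node!r}")
    shared = _neighbors(g, a, mediated_only, etype) & \
        _neighbors(g, b, mediated_only, etype)
    return shared - {a, b}


def degree_table(g: nx.Graph) -> dict[str, int]:
    return dict(g.degree())


def hubs(g: nx.Graph, min_degree: int | None = None) -> set[str]:
    """High-degree nodes.

    With ``min_degree`` given, nodes of degree >= min_degree. Default rule:
    degree strictly greater than mean + 1 population SD over all nodes (so
    a regular graph has no hubs).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    if min_degree is not None:
        return {n for n, d in g.degree() if d >= min_degree}
    threshold = degrees.mean() + degrees.std(ddof=0)
    return {n for n, d in g.degree() if d > threshold}
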