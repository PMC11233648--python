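"""Delimited-text serialization of functional networks.

Networks round-trip through an edge table (source, target, sign, weight,
lag, duration, significance) and a node table (node, area, x, y, z,
rate_hz); both are plain CSV so any external tool can consume them.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = ["network_tables", "write_network", "read_network"]

_EDGE_COLS = ["source", "target", "sign", "weight", "lag", "duration", "significance"]
_NODE_COLS = ["area", "x", "y", "z", "rate_hz"]


def network_tables(net: nx.DiGraph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(edge table, node table) views of a functional network."""
    edges = pd.DataFrame(
        [
            {
                "source": u,
                "target": v,
                "sign": d.get("sign", 1),
                "weight": d.get("weight", 1.0),
                "lag": d.get("lag"),
                "duration": d.get("duration"),
                "significance": d.get("significance"),
            }
            for u, v, d in net.edges(data=True)
        ],
        columns=_EDGE_COLS,
    )
    nodes = pd.DataFrame(
        [
            {"node": u, **{c: d.get(c) for c in _NODE_COLS}}
            for u, d in net.nodes(data=True)
        ],
        columns=["node"] + _NODE_COLS,
    )
    return edges, nodes


def write_network(net: nx.DiGraph, outdir, prefix: str = "network") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edges, nodes = network_tables(net)
    edges.to_csv(outdir / f"{prefix}_edges.csv", index=False)
    nodes.to_csv(outdir / f"{prefix}_nodes.csv", index=False)


def read_network(outdir, prefix: str = "network") -> nx.DiGraph:
    outdir = Path(outdir)
    edges = pd.read_csv(outdir / f"{prefix}_edges.csv")
    nodes = pd.read_csv(outdir / f"{prefix}_nodes.csv")
    g = nx.DiGraph()
    for row in nodes.itertuples(index=False):
        attrs = {
            c: getattr(row, c)
            for c in _NODE_COLS
            if c in nodes.columns and pd.notna(getattr(row, c))
        }
        g.add_node(row.node, **attrs)
    for row in edges.itertuples(index=False):
        g.add_edge(
            row.source,
            row.target,
            sign=int(row.sign),
            weight=float(row.weight),
            lag=int(row.lag) if pd.notna(row.lag) else None,
            duration=int(row.duration) if pd.notna(row.duration) else None,
            significance=float(row.significance)
            if pd.notna(row.significance)
            else None,
        )
    return g
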