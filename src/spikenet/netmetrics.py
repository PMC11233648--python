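"""Summary statistics of signed functional networks and tuning similarity."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd

from .data import SpikeTrainSet
from .stats import trend_test

__all__ = [
    "summary_metrics",
    "signal_correlation",
    "pairwise_distances",
    "connection_probability_profile",
]


def summary_metrics(net: nx.DiGraph) -> dict:
    """Density, sign/area fractions, directed clustering, degree sequences.

    Density is edges / (V(V-1)); the clustering coefficient is the mean
    directed (Fagiolo) clustering of the unsigned binarized graph. With zero
    edges the fractions are reported as None.
    """
    v = net.number_of_nodes()
    if v == 0:
        raise ValueError("empty node set")
    e = net.number_of_edges()
    density = e / (v * (v - 1)) if v > 1 else 0.0
    if e == 0:
        frac_pos = frac_within = clustering = None
    else:
        signs = [d.get("sign", 1) for _, _, d in net.edges(data=True)]
        frac_pos = sum(1 for s in signs if s > 0) / e
        areas = nx.get_node_attributes(net, "area")
        if areas:
            frac_within = (
                sum(1 for u, w in net.edges if areas.get(u) == areas.get(w)) / e
            )
        else:
            frac_within = None
        binary = nx.DiGraph()
        binary.add_nodes_from(net.nodes)
        binary.add_edges_from(net.edges)
        clustering = nx.average_clustering(binary)
    return {
        "n_nodes": v,
        "n_edges": e,
        "density": density,
        "frac_positive": frac_pos,
        "frac_within_area": frac_within,
        "clustering": clustering,
        "in_degree": dict(net.in_degree()),
        "out_degree": dict(net.out_degree()),
    }


def signal_correlation(data: SpikeTrainSet, conditions=None) -> pd.DataFrame:
    """Pairwise correlation of condition-averaged responses (tuning curves).

    ``conditions`` labels each trial with its stimulus condition (defaults
    to the trial stimulus labels); at least 3 distinct conditions are
    required — with only two, correlations of +/-1 are trivial. A unit's
    tuning vector is its mean total spike count per condition; units with
    zero variance across conditions get NaN rows/columns (absent).
    """
    conditions = (
        data.trial_stimulus if conditions is None else np.asarray(conditions)
    )
    if len(conditions) != data.n_trials:
        raise ValueError("one condition label per trial required")
    uniq = sorted(set(conditions.tolist()))
    if len(uniq) < 3:
        raise ValueError("signal correlation needs >= 3 distinct conditions")
    counts = data.spikes.sum(axis=1)  # (M, U) total count per trial
    tuning = np.stack(
        [counts[conditions == c].mean(axis=0) for c in uniq]
    )  # (C, U)
    sd = tuning.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(tuning.T)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    return pd.DataFrame(corr, index=data.units.index, columns=data.units.index)


def pairwise_distances(net: nx.DiGraph) -> pd.Series:
    """Euclidean distance per unordered node pair from x/y/z attributes.

    Pairs lacking positions are omitted.
    """
    pos = {}
    for u, d in net.nodes(data=True):
        if all(k in d and pd.notna(d[k]) for k in ("x", "y", "z")):
            pos[u] = np.array([d["x"], d["y"], d["z"]], float)
    out = {}
    for u, v in itertools.combinations(sorted(pos, key=repr), 2):
        out[(u, v)] = float(np.linalg.norm(pos[u] - pos[v]))
    return pd.Series(out, dtype=float)


def connection_probability_profile(
    net: nx.DiGraph, covariate: pd.Series, bins=8
) -> tuple[pd.DataFrame, dict]:
    """Connection probability vs. a pair covariate (distance, tuning, ...).

    ``covariate`` maps unordered node pairs (tuples) to values. Pairs are
    grouped into ``bins`` equal-width bins of the covariate; per bin we
    report the number of pairs, connected pairs (an edge in either
    direction), P(connect), and P(positive | connected) (the dominant-edge
    sign). The trend statistic is a two-sided Cochran-Armitage test on
    connectedness across the ordered bins; with fewer than two occupied bins
    it is reported as absent.
    """
    pairs = list(covariate.index)
    vals = covariate.to_numpy(dtype=float)
    if isinstance(bins, int):
        edges = np.linspace(vals.min(), vals.max(), bins + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    which = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, len(edges) - 2)

    rows = []
    for b in range(len(edges) - 1):
        members = [p for p, w in zip(pairs, which) if w == b]
        n_conn = n_pos = 0
        for u, v in members:
            e_uv = net.get_edge_data(u, v)
            e_vu = net.get_edge_data(v, u)
            if e_uv is None and e_vu is None:
                continue
            n_conn += 1
            best = max(
                (e for e in (e_uv, e_vu) if e is not None),
                key=lambda e: abs(e.get("weight", 1.0)),
            )
            if best.get("sign", 1) > 0:
                n_pos += 1
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n_pairs": len(members),
                "n_connected": n_conn,
                "p_connect": n_conn / len(members) if members else np.nan,
                "p_positive_given_connected": n_pos / n_conn if n_conn else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    occupied = table[table["n_pairs"] > 0]
    if len(occupied) < 2:
        trend = {"z": None, "p": None}
    else:
        z, p = trend_test(
            occupied["n_connected"].to_numpy(), occupied["n_pairs"].to_numpy()
        )
        trend = {"z": z, "p": p}
    return table, trend
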