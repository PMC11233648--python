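"""Signed community detection for directed, weighted functional networks.

Modularity for a signed directed graph is the weighted combination of a
positive and a negative part,

    Q = 1/(m+ + m-) * sum_ij [ A_ij - (g+ p+_ij - g- p-_ij) ] delta(s_i, s_j)

with A = A+ - A-, degree-based null terms p+-_ij = k+-out_i k+-in_j / m+-,
and resolution parameters g+ (gamma+) and g- (gamma-). A good partition puts
positive connections inside modules and negative connections between them.
The optimizer is a Louvain-style greedy node-move + aggregation scheme whose
quality function is this modified modularity; the per-edge "weighted" mode
replaces counts by absolute connection strengths throughout (degrees become
strengths, m+- become total strengths).

Also provided: resolution selection by maximizing the empirical-minus-null
modularity difference over a (gamma+, gamma-) grid, modularity Z-scores
against a surrogate ensemble, consensus voting over repeated stochastic
runs, and module-identity tracking across resolutions with a two-opt node
ordering for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .nulls import SurrogateSpec, surrogate_ensemble

__all__ = [
    "ModularityParams",
    "ModulePartition",
    "signed_modularity",
    "louvain_signed",
    "resolution_sweep",
    "modularity_zscore",
    "consensus_partition",
    "multires_id_assignment",
]

UNASSIGNED = -1


@dataclass(frozen=True)
class ModularityParams:
    gamma_plus: float = 1.0
    gamma_minus: float = 1.0
    weighted: bool = False
    min_module_size: int = 4
    max_passes: int = 100
    n_restarts: int = 8  # greedy descents per call; k>0 start from random cuts

    def __post_init__(self):
        if self.gamma_plus <= 0 or self.gamma_minus <= 0:
            raise ValueError("resolution parameters must be positive")


@dataclass
class ModulePartition:
    """Node -> module assignment with the modularity it achieves.

    ``labels`` marks nodes in modules below the minimum size as -1
    (unassigned); ``raw_labels`` keeps the unfiltered assignment. Module ids
    are contiguous, ordered by decreasing module size.
    """

    labels: pd.Series
    raw_labels: pd.Series
    Q: float
    params: ModularityParams
    seed: int | None = None
    n_levels: int = 0
    converged: bool = True
    Q_trace: list = field(default_factory=list)

    @property
    def modules(self) -> dict:
        out: dict = {}
        for node, m in self.labels.items():
            if m != UNASSIGNED:
                out.setdefault(int(m), set()).add(node)
        return out


def _signed_arrays(net: nx.DiGraph, weighted: bool):
    nodes = list(net.nodes)
    index = {u: i for i, u in enumerate(nodes)}
    v = len(nodes)
    ap = np.zeros((v, v))
    an = np.zeros((v, v))
    for a, b, d in net.edges(data=True):
        w = float(d.get("weight", 1.0))
        sign = int(d.get("sign", 1 if w >= 0 else -1))
        val = abs(w) if weighted else 1.0
        if sign > 0:
            ap[index[a], index[b]] += val
        else:
            an[index[a], index[b]] += val
    return nodes, ap, an


def _q_value(ap, an, labels, gp, gm) -> float:
    mp, mn = ap.sum(), an.sum()
    if mp + mn == 0:
        raise ValueError("modularity undefined for a network with no edges")
    a = ap - an
    kop, kip = ap.sum(1), ap.sum(0)
    kon, kin = an.sum(1), an.sum(0)
    total = 0.0
    for c in np.unique(labels):
        m = labels == c
        total += a[np.ix_(m, m)].sum()
        if mp > 0:
            total -= gp * kop[m].sum() * kip[m].sum() / mp
        if mn > 0:
            total += gm * kon[m].sum() * kin[m].sum() / mn
    return total / (mp + mn)


def signed_modularity(
    net: nx.DiGraph, assignment, params: ModularityParams = ModularityParams()
) -> float:
    """Modified modularity Q of a full node->module assignment."""
    nodes, ap, an = _signed_arrays(net, params.weighted)
    assignment = pd.Series(assignment)
    labels = assignment.reindex(nodes).to_numpy()
    if pd.isna(labels).any():
        raise ValueError("every node must be assigned for scoring")
    return _q_value(ap, an, np.asarray(labels), params.gamma_plus, params.gamma_minus)


def _local_move(
    ap, an, kop, kip, kon, kin, mp, mn, gp, gm, rng, max_passes, init=None
):
    """One Louvain level: greedy node moves until no move improves Q.

    Exact gain ties break toward the community with the larger direct
    connection weight, then the smaller community id (deterministic; also
    joins connected components the null term leaves at zero gain).
    """
    n = ap.shape[0]
    comm = np.arange(n) if init is None else np.asarray(init).copy()
    n_comm = comm.max() + 1
    skop = np.bincount(comm, weights=kop, minlength=n_comm)
    skip_ = np.bincount(comm, weights=kip, minlength=n_comm)
    skon = np.bincount(comm, weights=kon, minlength=n_comm)
    skin = np.bincount(comm, weights=kin, minlength=n_comm)
    anet = ap - an
    moved_any = False
    converged = False
    for _ in range(max_passes):
        n_moves = 0
        for u in rng.permutation(n):
            c0 = comm[u]
            row, col = anet[u], anet[:, u]
            w_to: dict[int, float] = {}
            for v in np.flatnonzero((row != 0) | (col != 0)):
                if v != u:
                    w_to[comm[v]] = w_to.get(comm[v], 0.0) + row[v] + col[v]
            # take u out of its community before comparing destinations
            skop[c0] -= kop[u]
            skip_[c0] -= kip[u]
            skon[c0] -= kon[u]
            skin[c0] -= kin[u]

            def gain(c):
                g = w_to.get(c, 0.0)
                if mp > 0:
                    g -= gp * (kop[u] * skip_[c] + kip[u] * skop[c]) / mp
                if mn > 0:
                    g += gm * (kon[u] * skin[c] + kin[u] * skon[c]) / mn
                return g

                # (self-pair terms are community-independent and cancel)

            candidates = sorted(set(w_to) | {c0})
            ranked = sorted(
                candidates,
                key=lambda c: (gain(c), w_to.get(c, 0.0), -c),
                reverse=True,
            )
            target = ranked[0]
            g0 = gain(c0)
            if gain(target) < g0 - 1e-12 or (
                abs(gain(target) - g0) <= 1e-12
                and w_to.get(target, 0.0) <= w_to.get(c0, 0.0) + 1e-12
            ):
                target = c0
            comm[u] = target
            skop[target] += kop[u]
            skip_[target] += kip[u]
            skon[target] += kon[u]
            skin[target] += kin[u]
            if target != c0:
                n_moves += 1
                moved_any = True
        if n_moves == 0:
            converged = True
            break
    return comm, moved_any, converged


def _aggregate(ap, an, comm):
    ids = np.unique(comm)
    remap = {c: i for i, c in enumerate(ids)}
    s = np.zeros((ap.shape[0], len(ids)))
    for u, c in enumerate(comm):
        s[u, remap[c]] = 1.0
    return s.T @ ap @ s, s.T @ an @ s, np.array([remap[c] for c in comm])


def louvain_signed(
    net: nx.DiGraph,
    params: ModularityParams = ModularityParams(),
    seed: int | None = None,
) -> ModulePartition:
    """Greedy modularity optimization with the signed quality function.

    Deterministic for a fixed seed (the node visiting order is seeded); Q is
    non-decreasing across levels (``Q_trace`` records it after each
    aggregation). Modules smaller than ``params.min_module_size`` are marked
    unassigned in ``labels`` after convergence.
    """
    if net.number_of_edges() == 0:
        raise ValueError("cannot partition a network with no edges")
    nodes, ap0, an0 = _signed_arrays(net, params.weighted)
    rng = np.random.default_rng(seed)
    mp, mn = ap0.sum(), an0.sum()
    gp, gm = params.gamma_plus, params.gamma_minus

    kop0, kip0 = ap0.sum(1), ap0.sum(0)
    kon0, kin0 = an0.sum(1), an0.sum(0)
    n = len(nodes)

    global_labels = None
    q_global = -np.inf
    q_trace: list = []
    converged = True
    n_levels = 0
    for restart in range(max(1, params.n_restarts)):
        if restart == 0:
            labels = np.arange(n)
        else:  # diversify: random coarse cut as the starting partition
            labels = rng.integers(0, max(2, n // 2), size=n)
        trace = []
        q_best = -np.inf
        while True:
            # refinement pass: move individual nodes, starting from `labels`
            _, labels = np.unique(labels, return_inverse=True)
            labels, _, conv = _local_move(
                ap0, an0, kop0, kip0, kon0, kin0, mp, mn, gp, gm, rng,
                params.max_passes, init=labels,
            )
            converged = converged and conv
            # hierarchical phase: aggregate communities, move super-nodes
            while True:
                ap, an, labels = _aggregate(ap0, an0, labels)
                comm, moved, conv = _local_move(
                    ap, an, ap.sum(1), ap.sum(0), an.sum(1), an.sum(0),
                    mp, mn, gp, gm, rng, params.max_passes,
                )
                converged = converged and conv
                if not moved:
                    break
                labels = comm[labels]
                n_levels += 1
            q = _q_value(ap0, an0, labels, gp, gm)
            trace.append(q)
            if q <= q_best + 1e-12:
                break
            q_best = q
        if q_best > q_global:
            q_global = q_best
            global_labels = labels
            q_trace = trace

    raw = _relabel_by_size(global_labels, nodes)
    q = _q_value(ap0, an0, raw.to_numpy(), gp, gm)
    labels = raw.copy()
    counts = labels.value_counts()
    small = counts[counts < params.min_module_size].index
    labels[labels.isin(small)] = UNASSIGNED
    labels = _relabel_by_size(
        labels.to_numpy(), nodes, keep_unassigned=True
    )
    return ModulePartition(
        labels=labels, raw_labels=raw, Q=float(q), params=params, seed=seed,
        n_levels=n_levels, converged=converged, Q_trace=q_trace,
    )


def _relabel_by_size(labels, nodes, keep_unassigned=False) -> pd.Series:
    labels = np.asarray(labels)
    out = np.full(len(labels), UNASSIGNED, dtype=int)
    groups = {}
    for i, c in enumerate(labels):
        if keep_unassigned and c == UNASSIGNED:
            continue
        groups.setdefault(c, []).append(i)
    order = sorted(groups, key=lambda c: (-len(groups[c]), min(groups[c])))
    for new, c in enumerate(order):
        out[groups[c]] = new
    return pd.Series(out, index=pd.Index(nodes, name="node"))


def modularity_zscore(
    net: nx.DiGraph,
    params: ModularityParams,
    ensemble,
    seed: int = 0,
    n_runs: int = 1,
):
    """Z-score of the network's modularity against a surrogate ensemble.

    Empirical Q is the best of ``n_runs`` seeded optimizations; each
    surrogate contributes one seeded run. Returns a dict with Q, the
    ensemble moments and Z (NaN + flag when the ensemble variance is zero).
    """
    ensemble = list(ensemble)
    if len(ensemble) < 2:
        raise ValueError("need >= 2 surrogates")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_runs + len(ensemble))
    q_emp = max(
        louvain_signed(net, params, seed=int(s)).Q for s in seeds[:n_runs]
    )
    qs = np.array(
        [
            louvain_signed(g, params, seed=int(s)).Q
            for g, s in zip(ensemble, seeds[n_runs:])
        ]
    )
    std = qs.std()
    z = float("nan") if std == 0 else (q_emp - qs.mean()) / std
    return {
        "Q": float(q_emp),
        "q_mean": float(qs.mean()),
        "q_std": float(std),
        "Z_Q": float(z),
        "degenerate": bool(std == 0),
    }


def resolution_sweep(
    net: nx.DiGraph,
    gamma_plus_grid=None,
    gamma_minus_grid=None,
    spec: SurrogateSpec | None = None,
    params: ModularityParams = ModularityParams(),
    n_runs: int = 200,
    ensemble_size: int = 20,
    seed: int = 0,
):
    """Pick (gamma+, gamma-) maximizing Q_empirical - mean Q_surrogate.

    Empirical Q at each grid point is the best of ``n_runs`` seeded runs;
    each of ``ensemble_size`` surrogates (signed-pair-preserving by default)
    contributes a single run. Returns (best gamma+, best gamma-, difference
    map as a DataFrame). An all-equal map falls back to the smallest grid
    point and is flagged in the map's attrs.
    """
    if gamma_plus_grid is None:
        gamma_plus_grid = np.geomspace(0.5, 2.0, 13)
    if gamma_minus_grid is None:
        gamma_minus_grid = np.array([0.8, 1.0, 1.25])
    gamma_plus_grid = np.sort(np.asarray(gamma_plus_grid, float))
    gamma_minus_grid = np.sort(np.asarray(gamma_minus_grid, float))
    if gamma_plus_grid.size == 0 or gamma_minus_grid.size == 0:
        raise ValueError("grids must be nonempty")
    spec = spec or SurrogateSpec(kind="signed_pair_preserving", n=ensemble_size, seed=seed)
    spec = replace(spec, n=ensemble_size)
    surrogates = surrogate_ensemble(net, spec)
    rng = np.random.default_rng(seed)
    diff = pd.DataFrame(
        index=pd.Index(gamma_plus_grid, name="gamma_plus"),
        columns=pd.Index(gamma_minus_grid, name="gamma_minus"),
        dtype=float,
    )
    for gp in gamma_plus_grid:
        for gm in gamma_minus_grid:
            p = replace(params, gamma_plus=float(gp), gamma_minus=float(gm))
            seeds = rng.integers(0, 2**31 - 1, size=n_runs + len(surrogates))
            q_emp = max(
                louvain_signed(net, p, seed=int(s)).Q for s in seeds[:n_runs]
            )
            q_sur = np.mean(
                [
                    louvain_signed(g, p, seed=int(s)).Q
                    for g, s in zip(surrogates, seeds[n_runs:])
                ]
            )
            diff.loc[gp, gm] = q_emp - q_sur
    vals = diff.to_numpy(dtype=float)
    flat = vals.ravel()
    if np.allclose(flat, flat[0]):
        diff.attrs["degenerate"] = True
        return float(gamma_plus_grid[0]), float(gamma_minus_grid[0]), diff
    i, j = np.unravel_index(np.nanargmax(vals), vals.shape)
    return float(gamma_plus_grid[i]), float(gamma_minus_grid[j]), diff


def consensus_partition(runs, net: nx.DiGraph | None = None,
                        params: ModularityParams = ModularityParams()):
    """Voting consensus over repeated stochastic partitionings.

    Every run contributes one vote per module (a specific node set). Each
    node is assigned to the most frequent module containing it; ties break
    toward the larger module, then lexicographic node-set order. Nodes that
    chose the same module form one consensus module.
    """
    label_sets = []
    for r in runs:
        labels = r.raw_labels if isinstance(r, ModulePartition) else pd.Series(r)
        label_sets.append(labels)
    if not label_sets:
        raise ValueError("need at least one run")
    node_set = set(label_sets[0].index)
    for s in label_sets[1:]:
        if set(s.index) != node_set:
            raise ValueError("all runs must cover the same node set")

    votes: dict[frozenset, int] = {}
    for labels in label_sets:
        for _, members in labels.groupby(labels):
            key = frozenset(members.index)
            votes[key] = votes.get(key, 0) + 1

    nodes = sorted(node_set, key=repr)
    assigned = pd.Series(UNASSIGNED, index=pd.Index(nodes, name="node"))
    next_id = 0
    unassigned = set(nodes)
    while unassigned:
        choice: dict = {}
        for u in sorted(unassigned, key=repr):
            cands = [m for m in votes if u in m]
            if not cands:
                choice[u] = frozenset([u])
                continue
            choice[u] = max(
                cands,
                key=lambda m: (votes[m], len(m), tuple(sorted(map(repr, m))))
            )
        for module in sorted(set(choice.values()),
                             key=lambda m: tuple(sorted(map(repr, m)))):
            members = [u for u, m in choice.items() if m == module]
            assigned[members] = next_id
            next_id += 1
            unassigned.difference_update(members)
    raw = _relabel_by_size(assigned.to_numpy(), nodes)
    q = float("nan")
    if net is not None:
        q = signed_modularity(net, raw, params)
    labels = raw.copy()
    counts = labels.value_counts()
    labels[labels.isin(counts[counts < params.min_module_size].index)] = UNASSIGNED
    return ModulePartition(labels=labels, raw_labels=raw, Q=q, params=params)


def _window_cost(rows: np.ndarray, order: np.ndarray, window: int) -> int:
    cost = 0
    n = len(order)
    for i in range(n):
        for j in range(i + 1, min(i + window, n)):
            cost += int(np.sum(rows[order[i]] != rows[order[j]]))
    return cost


def multires_id_assignment(
    partitions,
    areas: pd.Series | None = None,
    seed: int = 0,
    window: int = 10,
    n_proposals: int = 2000,
):
    """Track module identities across resolutions and order nodes for display.

    ``partitions`` are label Series ordered from the highest (finest)
    resolution downward. Finest-resolution modules get unique ids; each
    coarser module inherits the id of its maximum-overlap submodule from the
    previous (finer) level (ties: larger submodule, then smaller id). Node
    order comes from a seeded two-opt minimizing the summed Hamming distance
    between the module-id sequences of nodes within a ``window``-node
    adjacency span, run separately within each area when ``areas`` is given.

    Returns (id table: nodes x resolutions DataFrame, node order list).
    """
    parts = [
        p.labels if isinstance(p, ModulePartition) else pd.Series(p)
        for p in partitions
    ]
    if not parts:
        raise ValueError("need at least one partition")
    index = parts[0].index
    table = pd.DataFrame(index=index, columns=range(len(parts)), dtype=int)

    prev = parts[0]
    next_id = int(prev[prev != UNASSIGNED].max()) + 1 if (prev != UNASSIGNED).any() else 0
    table[0] = prev.to_numpy()
    prev_ids = prev.copy()
    for r in range(1, len(parts)):
        cur = parts[r]
        cur_ids = pd.Series(UNASSIGNED, index=index)
        for m in sorted(set(cur[cur != UNASSIGNED])):
            members = cur.index[cur == m]
            overlaps: dict[int, int] = {}
            for pid in prev_ids.loc[members]:
                if pid != UNASSIGNED:
                    overlaps[pid] = overlaps.get(pid, 0) + 1
            if overlaps:
                best = max(overlaps, key=lambda pid: (overlaps[pid], pid))
                cur_ids.loc[members] = best
            else:
                cur_ids.loc[members] = next_id
                next_id += 1
        table[r] = cur_ids.to_numpy()
        prev_ids = cur_ids

    rows = table.to_numpy()
    rng = np.random.default_rng(seed)
    groups = (
        [index] if areas is None
        else [index[areas.reindex(index) == a] for a in sorted(set(areas.reindex(index)))]
    )
    order: list = []
    pos = {u: i for i, u in enumerate(index)}
    for grp in groups:
        g_idx = np.array([pos[u] for u in grp])
        if len(g_idx) <= 2:
            order.extend(grp.tolist())
            continue
        perm = np.arange(len(g_idx))
        cost = _window_cost(rows[g_idx], perm, window)
        for _ in range(n_proposals):
            i, j = sorted(rng.integers(0, len(perm), size=2))
            if i == j:
                continue
            cand = perm.copy()
            cand[i : j + 1] = cand[i : j + 1][::-1]
            c = _window_cost(rows[g_idx], cand, window)
            if c < cost:
                perm, cost = cand, c
        order.extend(grp[perm].tolist())
    return table, order
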