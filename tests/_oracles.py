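"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (triple loops, exhaustive enumeration)
and shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_ccg_counts(a: np.ndarray, b: np.ndarray, n_lags: int) -> np.ndarray:
    """Triple-loop lagged coincidence counts sum_i sum_t a(t) b(t+tau)."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    m, n = a.shape
    out = np.zeros(n_lags + 1, dtype=np.int64)
    for tau in range(n_lags + 1):
        for i in range(m):
            for t in range(n - tau):
                out[tau] += int(a[i, t]) * int(b[i, t + tau])
    return out


def brute_force_detect(cc: np.ndarray, tau_max: int, n_sigma: float):
    """Literal sharp peak/interval search over all (D, t0).

    Returns (D, t0, sign) of the smallest qualifying duration (max |z| within
    it) or None. Population statistics over ALL full windows of the curve.
    """
    for d in range(1, tau_max + 2):
        if d > len(cc):
            break
        windows = [cc[t : t + d].mean() for t in range(len(cc) - d + 1)]
        mu, sd = float(np.mean(windows)), float(np.std(windows))
        if sd == 0:
            continue
        hits = []
        for t0 in range(0, tau_max - d + 2):
            mean = cc[t0 : t0 + d].mean()
            if mean > mu + n_sigma * sd:
                hits.append((abs(mean - mu) / sd, t0, 1))
            elif mean < mu - n_sigma * sd:
                hits.append((abs(mean - mu) / sd, t0, -1))
        if hits:
            z, t0, sign = max(hits)
            return d, t0, sign
    return None


def triad_isomorphic(edges1: dict, edges2: dict) -> bool:
    """Are two signed triads (dicts (i,j)->sign over nodes 0..2) isomorphic?"""
    for perm in itertools.permutations(range(3)):
        mapped = {(perm[i], perm[j]): s for (i, j), s in edges1.items()}
        if mapped == edges2:
            return True
    return False


def census_oracle(net) -> dict:
    """O(V^3) signed-triad census by explicit isomorphism matching.

    Returns {canonical signed-edge frozenset key: (count, intensity)} where
    the key is built by minimizing the edge-pattern encoding over node
    permutations (independent of the package's canonicalization).
    """
    nodes = list(net.nodes)
    out: dict = {}
    for tri in itertools.combinations(nodes, 3):
        local = {u: k for k, u in enumerate(tri)}
        edges = {}
        weights = []
        for u, v in itertools.permutations(tri, 2):
            if net.has_edge(u, v):
                d = net.edges[u, v]
                edges[(local[u], local[v])] = int(d.get("sign", 1))
                weights.append(abs(float(d.get("weight", 1.0))))
        if not edges:
            continue
        # weak connectivity on 3 nodes
        touched = set()
        for (i, j) in edges:
            touched.update((i, j))
        adj = {i: set() for i in range(3)}
        for (i, j) in edges:
            adj[i].add(j)
            adj[j].add(i)
        seen = {0}
        stack = [0]
        while stack:
            for w in adj[stack.pop()]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        if len(seen) != 3:
            continue
        key = min(
            tuple(sorted(((perm[i], perm[j]), s) for (i, j), s in edges.items()))
            for perm in itertools.permutations(range(3))
        )
        intensity = float(np.prod(weights) ** (1.0 / len(weights)))
        c, s = out.get(key, (0, 0.0))
        out[key] = (c + 1, s + intensity)
    return out


def set_partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1 :]
        yield [[first]] + part


def modularity_oracle(net, labels: dict, gp=1.0, gm=1.0, weighted=False) -> float:
    """Double-loop evaluation of the signed modularity."""
    nodes = list(net.nodes)
    v = len(nodes)
    ap = np.zeros((v, v))
    an = np.zeros((v, v))
    idx = {u: i for i, u in enumerate(nodes)}
    for a, b, d in net.edges(data=True):
        w = abs(float(d.get("weight", 1.0))) if weighted else 1.0
        if int(d.get("sign", 1)) > 0:
            ap[idx[a], idx[b]] += w
        else:
            an[idx[a], idx[b]] += w
    mp, mn = ap.sum(), an.sum()
    kop, kip = ap.sum(1), ap.sum(0)
    kon, kin = an.sum(1), an.sum(0)
    q = 0.0
    for i in range(v):
        for j in range(v):
            if labels[nodes[i]] != labels[nodes[j]]:
                continue
            pij_p = kop[i] * kip[j] / mp if mp > 0 else 0.0
            pij_n = kon[i] * kin[j] / mn if mn > 0 else 0.0
            q += (ap[i, j] - an[i, j]) - (gp * pij_p - gm * pij_n)
    return q / (mp + mn)


def ari_paircount(labels_a, labels_b) -> float:
    """ARI by direct counting of agreeing/disagreeing node pairs."""
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    n = len(labels_a)
    ss = sd = ds = dd = 0
    for i in range(n):
        for j in range(i + 1, n):
            a_same = labels_a[i] == labels_a[j]
            b_same = labels_b[i] == labels_b[j]
            if a_same and b_same:
                ss += 1
            elif a_same:
                sd += 1
            elif b_same:
                ds += 1
            else:
                dd += 1
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    max_index = 0.5 * ((ss + sd) + (ss + ds))
    if max_index == expected:
        return float("nan")
    return (ss - expected) / (max_index - expected)
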