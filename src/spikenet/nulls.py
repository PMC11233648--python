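"""Randomized reference (null) networks for motif and modularity scoring.

Four nested models, each preserving strictly more of the empirical network:

* ``erdos_renyi`` — node count, edge count, and the multiset of edge labels
  (sign + weight travel together, reassigned in random order);
* ``degree_preserving`` — additionally every node's in- and out-degree,
  via directed double-edge swaps;
* ``pair_preserving`` — additionally the multiset of unordered-pair states
  {unidirectional, bidirectional}, via category-restricted swaps
  (unidirectional edges swap with unidirectional edges, bidirectional pairs
  with bidirectional pairs), signs still reassigned at random;
* ``signed_pair_preserving`` — additionally the SIGNED pair states
  (+>, ->, +<>+, +<>-, -<>-) with labels travelling on their edges, so the
  signed two-node census of every surrogate equals the input's exactly.

An optional distance-preserving variant restricts all randomization within
discretized (equal-count) bins of the pairwise anatomical distance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["SurrogateSpec", "make_surrogate", "surrogate_ensemble"]

_KINDS = (
    "erdos_renyi",
    "degree_preserving",
    "pair_preserving",
    "signed_pair_preserving",
)


@dataclass(frozen=True)
class SurrogateSpec:
    kind: str = "signed_pair_preserving"
    n: int = 200
    preserve_distance: bool = False
    distance_bins: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown reference model {self.kind!r}")
        if self.n < 1:
            raise ValueError("ensemble size must be >= 1")


class SwapError(RuntimeError):
    """Randomization failed to reach the target number of accepted swaps."""


def _edge_attrs(net: nx.DiGraph) -> list[dict]:
    return [dict(d) for _, _, d in net.edges(data=True)]


def _empty_like(net: nx.DiGraph) -> nx.DiGraph:
    g = nx.DiGraph(**net.graph)
    g.add_nodes_from((u, dict(d)) for u, d in net.nodes(data=True))
    return g


def _pair_bins(net: nx.DiGraph, n_bins: int) -> dict[frozenset, int]:
    pos = {}
    for u, d in net.nodes(data=True):
        if not all(k in d for k in ("x", "y", "z")):
            raise ValueError("distance preservation needs x/y/z node positions")
        pos[u] = np.array([d["x"], d["y"], d["z"]], dtype=float)
    pairs = list(itertools.combinations(net.nodes, 2))
    dist = np.array([np.linalg.norm(pos[u] - pos[v]) for u, v in pairs])
    edges = np.quantile(dist, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1.0  # right-open last bin
    bins = np.searchsorted(edges, dist, side="right") - 1
    return {frozenset(p): int(b) for p, b in zip(pairs, bins)}


def _assign_labels(g: nx.DiGraph, labels: list[dict], rng) -> None:
    order = rng.permutation(len(labels))
    for (u, v), k in zip(g.edges, order):
        g.edges[u, v].clear()
        g.edges[u, v].update(labels[k])


def _er_surrogate(net, rng, bins) -> nx.DiGraph:
    g = _empty_like(net)
    nodes = list(net.nodes)
    V = len(nodes)
    E = net.number_of_edges()
    if E == 0:
        return g
    if bins is None:
        idx = rng.choice(V * (V - 1), size=E, replace=False)
        for k in idx:
            i, j = divmod(int(k), V - 1)
            j = j if j < i else j + 1
            g.add_edge(nodes[i], nodes[j])
    else:
        by_bin: dict[int, list] = {}
        for i in range(V):
            for j in range(V):
                if i != j:
                    b = bins[frozenset((nodes[i], nodes[j]))]
                    by_bin.setdefault(b, []).append((nodes[i], nodes[j]))
        want: dict[int, int] = {}
        for u, v in net.edges:
            want[bins[frozenset((u, v))]] = want.get(bins[frozenset((u, v))], 0) + 1
        for b, count in want.items():
            idx = rng.choice(len(by_bin[b]), size=count, replace=False)
            for k in idx:
                g.add_edge(*by_bin[b][int(k)])
    _assign_labels(g, _edge_attrs(net), rng)
    return g


def _swap_loop(n_items: int, rng, try_swap) -> None:
    """Run accepted-swap burn-in: 10 accepted swaps per item, bounded tries.

    Because randomization rewires the empirical network in place, the
    starting state is always realizable; a category where no legal swap
    exists (tiny or heavily constrained) is left as-is with a warning
    rather than treated as an error.
    """
    if n_items < 2:
        return
    target = 10 * n_items
    max_tries = 500 * n_items
    accepted = tries = 0
    while accepted < target and tries < max_tries:
        tries += 1
        if try_swap():
            accepted += 1
    if accepted < target:
        warnings.warn(
            f"swap burn-in incomplete: {accepted}/{target} accepted in "
            f"{max_tries} tries (state space may be frozen)",
            RuntimeWarning,
        )


def _degree_surrogate(net, rng, bins) -> nx.DiGraph:
    g = _empty_like(net)
    edges = list(net.edges)
    occupied = set(edges)

    def try_swap() -> bool:
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            return False
        a, b = edges[i]
        c, d = edges[j]
        if a == d or c == b or (a, d) in occupied or (c, b) in occupied:
            return False
        if bins is not None and (
            bins[frozenset((a, d))] != bins[frozenset((a, b))]
            or bins[frozenset((c, b))] != bins[frozenset((c, d))]
        ):
            return False
        occupied.discard((a, b))
        occupied.discard((c, d))
        occupied.add((a, d))
        occupied.add((c, b))
        edges[i] = (a, d)
        edges[j] = (c, b)
        return True

    _swap_loop(len(edges), rng, try_swap)
    g.add_edges_from(edges)
    _assign_labels(g, _edge_attrs(net), rng)
    return g


def _pair_categories(net: nx.DiGraph, signed: bool):
    """Split unordered pairs into swap categories.

    Unsigned: one unidirectional and one bidirectional category. Signed:
    unidirectional split by sign; bidirectional split into ++, --, and the
    oriented +- state (stored with the positive edge first).
    """
    seen = set()
    cats: dict[str, list] = {}
    for u, v in net.edges:
        key = frozenset((u, v))
        if key in seen:
            continue
        seen.add(key)
        mutual = net.has_edge(v, u)
        if not mutual:
            s = net.edges[u, v].get("sign", 1)
            cname = ("uni+" if s > 0 else "uni-") if signed else "uni"
            cats.setdefault(cname, []).append((u, v))
        else:
            if signed:
                su = net.edges[u, v].get("sign", 1)
                sv = net.edges[v, u].get("sign", 1)
                if su > 0 and sv > 0:
                    cats.setdefault("bi++", []).append((u, v))
                elif su < 0 and sv < 0:
                    cats.setdefault("bi--", []).append((u, v))
                else:  # orient with the positive edge first
                    pair = (u, v) if su > 0 else (v, u)
                    cats.setdefault("bi+-", []).append(pair)
            else:
                cats.setdefault("bi", []).append((u, v))
    return cats


def _pair_surrogate(net, rng, bins, signed: bool) -> nx.DiGraph:
    g = _empty_like(net)
    cats = _pair_categories(net, signed)
    occupied = {frozenset((u, v)) for u, v in net.edges}
    attrs = {(u, v): dict(d) for u, v, d in net.edges(data=True)}

    def make_try(items: list, bidirectional: bool, oriented: bool):
        def try_swap() -> bool:
            i, j = rng.integers(0, len(items), size=2)
            if i == j:
                return False
            a, b = items[i]
            c, d = items[j]
            if bidirectional and not oriented and rng.random() < 0.5:
                a, b = b, a  # random orientation for symmetric pair states
            if len({a, b, c, d}) < 4 and bidirectional:
                return False
            if a == d or c == b:
                return False
            new1, new2 = frozenset((a, d)), frozenset((c, b))
            if new1 == new2 or new1 in occupied or new2 in occupied:
                return False
            old1, old2 = frozenset((a, b)), frozenset((c, d))
            if bins is not None and (
                bins[new1] != bins[old1] or bins[new2] != bins[old2]
            ):
                return False
            # rewire, carrying edge attributes along
            occupied.discard(old1)
            occupied.discard(old2)
            occupied.add(new1)
            occupied.add(new2)
            attrs[(a, d)] = attrs.pop((a, b))
            attrs[(c, b)] = attrs.pop((c, d))
            if bidirectional:
                attrs[(d, a)] = attrs.pop((b, a))
                attrs[(b, c)] = attrs.pop((d, c))
            items[i] = (a, d)
            items[j] = (c, b)
            return True

        return try_swap

    for cname, items in cats.items():
        bidi = cname.startswith("bi")
        oriented = cname == "bi+-"
        _swap_loop(len(items), rng, make_try(items, bidi, oriented))

    for cname, items in cats.items():
        bidi = cname.startswith("bi")
        for u, v in items:
            g.add_edge(u, v, **attrs[(u, v)])
            if bidi:
                g.add_edge(v, u, **attrs[(v, u)])
    if not signed:
        _assign_labels(g, _edge_attrs(net), rng)
    return g


def make_surrogate(net: nx.DiGraph, spec: SurrogateSpec, index: int = 0) -> nx.DiGraph:
    """Draw surrogate ``index`` of the ensemble defined by ``spec``.

    Deterministic in (spec.seed, index). Node identities and attributes are
    kept; the edge set is randomized under the model's conservation laws.
    """
    if net.number_of_nodes() < 2:
        raise ValueError("network must have >= 2 nodes")
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, index])
    bins = _pair_bins(net, spec.distance_bins) if spec.preserve_distance else None
    if spec.kind == "erdos_renyi":
        return _er_surrogate(net, rng, bins)
    if spec.kind == "degree_preserving":
        return _degree_surrogate(net, rng, bins)
    if spec.kind == "pair_preserving":
        return _pair_surrogate(net, rng, bins, signed=False)
    return _pair_surrogate(net, rng, bins, signed=True)


def surrogate_ensemble(net: nx.DiGraph, spec: SurrogateSpec) -> list[nx.DiGraph]:
    """Ordered list of ``spec.n`` independent surrogates (replicate i is a
    deterministic function of (seed, i))."""
    out = []
    for i in range(spec.n):
        try:
            out.append(make_surrogate(net, spec, i))
        except SwapError as e:
            raise SwapError(f"replicate {i}: {e}") from e
    return out
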