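"""Signed two- and three-node motif analysis of functional networks.

A motif class is an isomorphism class of weakly connected labelled digraphs
on 2 or 3 nodes, optionally refined by the edge signs (+/-). The catalog is
built by exhaustive enumeration of all labelled digraphs with a deterministic
canonical representative per class (minimum lexicographic encoding over node
permutations). There are 13 unsigned connected triad classes; the transitive
triangle (feedforward loop, FFL) and every class containing it are flagged,
and each signed class records whether it embeds an all-positive FFL (the
defining property of pFFLb motifs).

Motif prevalence is scored by the intensity method: the intensity of one
subgraph is the geometric mean of its |edge weights|, the intensity of a
class is the sum over its instances, and significance is the Z-score of the
empirical intensity against a surrogate-network ensemble.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MotifClass",
    "MotifCatalog",
    "motif_catalog",
    "classify_triad",
    "motif_intensity_census",
    "motif_zscores",
    "mask_outlier_replicates",
    "pair_relative_counts",
    "pfflb_sets",
    "PFFLbSet",
    "within_motif_pairs",
    "motif_overlap",
]

# Ordered-pair slots for the adjacency encoding.
_POSITIONS = {
    2: [(0, 1), (1, 0)],
    3: [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)],
}


@dataclass(frozen=True)
class MotifClass:
    id: str
    unsigned_id: int
    canonical_code: int
    n_edges: int
    n_mutual: int
    contains_ffl: bool
    contains_pffl: bool = False  # signed classes only
    all_positive: bool = False
    all_negative: bool = False


@dataclass
class MotifCatalog:
    """Exhaustive catalog of connected motif classes with O(1) code lookup."""

    n_nodes: int
    signed: bool
    classes: list[MotifClass]
    code_to_class: np.ndarray  # digit-encoded adjacency -> class index or -1
    n_edges_of_code: np.ndarray
    _by_id: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._by_id = {c.id: i for i, c in enumerate(self.classes)}

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.classes]

    def class_of(self, class_id: str) -> MotifClass:
        return self.classes[self._by_id[class_id]]


def _perm_position_maps(n_nodes: int) -> list[np.ndarray]:
    pos = _POSITIONS[n_nodes]
    index = {p: i for i, p in enumerate(pos)}
    maps = []
    for perm in itertools.permutations(range(n_nodes)):
        maps.append(
            np.array([index[(perm[a], perm[b])] for (a, b) in pos], dtype=np.intp)
        )
    return maps


def _digits(code: int, base: int, length: int) -> np.ndarray:
    d = np.empty(length, dtype=np.int64)
    for i in range(length):
        code, d[i] = divmod(code, base)
    return d


def _encode(digits: np.ndarray, base: int) -> int:
    return int(np.sum(digits * base ** np.arange(len(digits))))


def _weakly_connected(digits: np.ndarray, n_nodes: int) -> bool:
    pos = _POSITIONS[n_nodes]
    adj = {i: set() for i in range(n_nodes)}
    for (a, b), s in zip(pos, digits):
        if s:
            adj[a].add(b)
            adj[b].add(a)
    seen, stack = {0}, [0]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == n_nodes


def _has_ffl(digits: np.ndarray, n_nodes: int, positive_only: bool) -> bool:
    """Does the pattern contain a transitive triangle a->b, b->c, a->c?"""
    if n_nodes < 3:
        return False
    pos = _POSITIONS[n_nodes]
    index = {p: i for i, p in enumerate(pos)}
    ok = (lambda s: s == 1) if positive_only else (lambda s: s != 0)
    for a, b, c in itertools.permutations(range(n_nodes), 3):
        if (
            ok(digits[index[(a, b)]])
            and ok(digits[index[(b, c)]])
            and ok(digits[index[(a, c)]])
        ):
            return True
    return False


def _n_mutual(digits: np.ndarray, n_nodes: int) -> int:
    pos = _POSITIONS[n_nodes]
    index = {p: i for i, p in enumerate(pos)}
    return sum(
        1
        for a, b in itertools.combinations(range(n_nodes), 2)
        if digits[index[(a, b)]] and digits[index[(b, a)]]
    )


def motif_catalog(n_nodes: int = 3, signed: bool = False) -> MotifCatalog:
    """Enumerate all weakly connected motif classes on 2 or 3 nodes.

    Unsigned ids are integers ordered by (edge count, mutual-pair count
    descending, FFL-containing first, canonical code); with this ordering the
    feedforward loop is unsigned class 6 of 13. Signed ids derive from the
    parent unsigned id with prefix ``p`` (all edges positive), ``n`` (all
    negative) or suffix ``mK`` for mixed-sign variants.
    """
    if n_nodes not in (2, 3):
        raise ValueError("motif catalog supports 2 or 3 nodes")
    length = len(_POSITIONS[n_nodes])
    base = 3 if signed else 2
    perm_maps = _perm_position_maps(n_nodes)

    # Group codes by canonical (minimum) code over node permutations.
    canon_of = np.full(base**length, -1, dtype=np.int64)
    n_edges_of = np.zeros(base**length, dtype=np.int64)
    groups: dict[int, int] = {}
    for code in range(base**length):
        digits = _digits(code, base, length)
        n_edges_of[code] = int(np.count_nonzero(digits))
        if not _weakly_connected(digits, n_nodes):
            continue
        canon = min(_encode(digits[m], base) for m in perm_maps)
        canon_of[code] = canon
        groups.setdefault(canon, 0)

    def unsigned_canon(digits: np.ndarray) -> int:
        d = (digits != 0).astype(np.int64)
        return min(_encode(d[m], 2) for m in perm_maps)

    # Stable unsigned ids (needed as parents for the signed catalog too).
    ucat = (
        motif_catalog(n_nodes, signed=False) if signed else None
    )

    records = []
    for canon in groups:
        digits = _digits(canon, base, length)
        n_edges = int(np.count_nonzero(digits))
        n_mut = _n_mutual(digits, n_nodes)
        ffl = _has_ffl(digits, n_nodes, positive_only=False)
        if signed:
            uc = unsigned_canon(digits)
            uidx = int(ucat.code_to_class[uc])
            uid = ucat.classes[uidx].unsigned_id
            records.append(
                dict(
                    canon=canon, n_edges=n_edges, n_mutual=n_mut,
                    contains_ffl=ffl, unsigned_id=uid,
                    contains_pffl=_has_ffl(digits, n_nodes, positive_only=True),
                    all_positive=bool(np.all(digits[digits != 0] == 1)),
                    all_negative=bool(np.all(digits[digits != 0] == 2)),
                )
            )
        else:
            records.append(
                dict(
                    canon=canon, n_edges=n_edges, n_mutual=n_mut,
                    contains_ffl=ffl,
                )
            )

    if signed:
        records.sort(key=lambda r: (r["unsigned_id"], r["canon"]))
        classes = []
        mixed_counter: dict[int, int] = {}
        for r in records:
            uid = r["unsigned_id"]
            if r["all_positive"]:
                cid = f"p{uid}"
            elif r["all_negative"]:
                cid = f"n{uid}"
            else:
                mixed_counter[uid] = mixed_counter.get(uid, 0) + 1
                cid = f"{uid}m{mixed_counter[uid]}"
            classes.append(
                MotifClass(
                    id=cid, unsigned_id=uid, canonical_code=r["canon"],
                    n_edges=r["n_edges"], n_mutual=r["n_mutual"],
                    contains_ffl=r["contains_ffl"],
                    contains_pffl=r["contains_pffl"],
                    all_positive=r["all_positive"],
                    all_negative=r["all_negative"],
                )
            )
    else:
        records.sort(
            key=lambda r: (
                r["n_edges"], -r["n_mutual"], not r["contains_ffl"], r["canon"]
            )
        )
        classes = [
            MotifClass(
                id=str(i + 1), unsigned_id=i + 1, canonical_code=r["canon"],
                n_edges=r["n_edges"], n_mutual=r["n_mutual"],
                contains_ffl=r["contains_ffl"],
            )
            for i, r in enumerate(records)
        ]

    canon_to_idx = {c.canonical_code: i for i, c in enumerate(classes)}
    code_to_class = np.full(base**length, -1, dtype=np.int64)
    for code in range(base**length):
        if canon_of[code] >= 0:
            code_to_class[code] = canon_to_idx[int(canon_of[code])]
    return MotifCatalog(
        n_nodes=n_nodes, signed=signed, classes=classes,
        code_to_class=code_to_class, n_edges_of_code=n_edges_of,
    )


def _net_matrices(net: nx.DiGraph) -> tuple[list, np.ndarray, np.ndarray]:
    nodes = list(net.nodes)
    index = {u: i for i, u in enumerate(nodes)}
    V = len(nodes)
    S = np.zeros((V, V), dtype=np.int64)
    W = np.zeros((V, V), dtype=float)
    for u, v, d in net.edges(data=True):
        w = float(d.get("weight", 1.0))
        sign = int(d.get("sign", 1 if w >= 0 else -1))
        S[index[u], index[v]] = 1 if sign > 0 else 2
        W[index[u], index[v]] = abs(w) if w != 0 else 1.0
    return nodes, S, W


def _triple_codes(S: np.ndarray, triples: np.ndarray) -> np.ndarray:
    pos = _POSITIONS[3]
    code = np.zeros(len(triples), dtype=np.int64)
    for p, (a, b) in enumerate(pos):
        code += S[triples[:, a], triples[:, b]] * 3**p
    return code


def classify_triad(net: nx.DiGraph, nodes, catalog: MotifCatalog):
    """Classify the induced subgraph on three named nodes.

    Returns (unsigned_id, signed_id) or None when the triple is not weakly
    connected (not a motif). Ids are invariant under any permutation of the
    node names.
    """
    if not catalog.signed or catalog.n_nodes != 3:
        raise ValueError("classify_triad needs the signed 3-node catalog")
    nodes = list(nodes)
    if len(set(nodes)) != 3:
        raise ValueError("need three distinct nodes")
    sub = net.subgraph(nodes)
    _, S, _ = _net_matrices(nx.DiGraph(sub))
    order = {u: i for i, u in enumerate(sub.nodes)}
    triple = np.array([[order[u] for u in sub.nodes]])
    idx = catalog.code_to_class[_triple_codes(S, triple)[0]]
    if idx < 0:
        return None
    cls = catalog.classes[idx]
    return cls.unsigned_id, cls.id


def motif_intensity_census(
    net: nx.DiGraph, catalog: MotifCatalog, return_instances: bool = False
) -> pd.DataFrame:
    """Count and intensity of every signed 3-node motif class in ``net``.

    Iterates over all weakly connected node triples; the intensity of a
    triple is the geometric mean of its |edge weights| and class intensity is
    the sum over member triples. With ``return_instances=True`` the result
    gains an ``instances`` column holding the list of node triples per class.
    """
    if not catalog.signed or catalog.n_nodes != 3:
        raise ValueError("census needs the signed 3-node catalog")
    nodes, S, W = _net_matrices(net)
    V = len(nodes)
    n_cls = len(catalog.classes)
    counts = np.zeros(n_cls, dtype=np.int64)
    intens = np.zeros(n_cls, dtype=float)
    inst: list[list] = [[] for _ in range(n_cls)]

    if V >= 3 and net.number_of_edges() > 0:
        triples = np.array(list(itertools.combinations(range(V), 3)), dtype=np.intp)
        codes = _triple_codes(S, triples)
        cls_idx = catalog.code_to_class[codes]
        mask = cls_idx >= 0
        triples, codes, cls_idx = triples[mask], codes[mask], cls_idx[mask]
        if len(triples):
            logw = np.zeros(len(triples), dtype=float)
            present = np.zeros(len(triples), dtype=np.int64)
            for p, (a, b) in enumerate(_POSITIONS[3]):
                w = W[triples[:, a], triples[:, b]]
                has = w > 0
                logw += np.where(has, np.log(np.where(has, w, 1.0)), 0.0)
                present += has
            tri_int = np.exp(logw / present)
            counts = np.bincount(cls_idx, minlength=n_cls)
            intens = np.bincount(cls_idx, weights=tri_int, minlength=n_cls)
            if return_instances:
                for t, ci in zip(triples, cls_idx):
                    inst[ci].append(frozenset(nodes[i] for i in t))

    df = pd.DataFrame(
        {
            "count": counts,
            "intensity": intens,
            "unsigned_id": [c.unsigned_id for c in catalog.classes],
        },
        index=pd.Index(catalog.ids, name="motif"),
    )
    if return_instances:
        df["instances"] = inst
    return df


def motif_zscores(
    net: nx.DiGraph, ensemble, catalog: MotifCatalog
) -> pd.DataFrame:
    """Intensity Z-score per signed motif class against a surrogate ensemble.

    Z = (I - <i>) / sqrt(<i^2> - <i>^2) with population moments over the
    ensemble. Classes with zero ensemble variance are flagged (Z = 0 when
    the empirical intensity equals the degenerate ensemble value, NaN
    otherwise).
    """
    ensemble = list(ensemble)
    if len(ensemble) < 2:
        raise ValueError("need an ensemble of >= 2 surrogate networks")
    emp = motif_intensity_census(net, catalog)
    ens = np.stack(
        [motif_intensity_census(g, catalog)["intensity"].to_numpy() for g in ensemble]
    )
    mean = ens.mean(axis=0)
    std = ens.std(axis=0)  # population SD, matching the moment definition
    # zero ensemble variance up to float accumulation noise
    degenerate = std <= 1e-12 * np.maximum(1.0, np.abs(mean))
    I = emp["intensity"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(degenerate, np.nan, (I - mean) / np.where(degenerate, 1, std))
    z = np.where(degenerate & np.isclose(I, mean), 0.0, z)
    return pd.DataFrame(
        {
            "count": emp["count"],
            "intensity": I,
            "ensemble_mean": mean,
            "ensemble_std": std,
            "zscore": z,
            "degenerate": degenerate,
        },
        index=emp.index,
    )


def mask_outlier_replicates(z_by_replicate: pd.DataFrame, n_sd: float = 2.0):
    """Mask per-class Z values lying beyond ``n_sd`` SD across replicates.

    ``z_by_replicate`` has one row per analysis replicate (session/seed) and
    one column per motif class; returns a same-shaped boolean mask (True =
    keep) applied across replicates, not across classes.
    """
    z = z_by_replicate.to_numpy(dtype=float)
    mean = np.nanmean(z, axis=0, keepdims=True)
    sd = np.nanstd(z, axis=0, keepdims=True)
    keep = np.abs(z - mean) <= n_sd * np.where(sd == 0, np.inf, sd)
    return pd.DataFrame(keep, index=z_by_replicate.index, columns=z_by_replicate.columns)


def pair_census(net: nx.DiGraph, catalog: MotifCatalog | None = None) -> pd.Series:
    """Signed 2-node motif counts over all unordered node pairs."""
    if catalog is None:
        catalog = motif_catalog(2, signed=True)
    nodes, S, _ = _net_matrices(net)
    counts = np.zeros(len(catalog.classes), dtype=np.int64)
    V = len(nodes)
    iu, ju = np.triu_indices(V, k=1)
    codes = S[iu, ju] + 3 * S[ju, iu]
    idx = catalog.code_to_class[codes]
    got = idx[idx >= 0]
    counts = np.bincount(got, minlength=len(catalog.classes))
    return pd.Series(counts, index=pd.Index(catalog.ids, name="pair_motif"))


def pair_relative_counts(net: nx.DiGraph, ensemble) -> pd.DataFrame:
    """Empirical / ensemble-mean count per signed 2-node class.

    The reference ensemble is conventionally Erdős–Rényi. A ratio with zero
    ensemble mean but positive empirical count is reported as +inf and
    flagged.
    """
    ensemble = list(ensemble)
    if not ensemble:
        raise ValueError("ensemble must be nonempty")
    cat2 = motif_catalog(2, signed=True)
    emp = pair_census(net, cat2)
    ens = np.stack([pair_census(g, cat2).to_numpy() for g in ensemble])
    mean = ens.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            mean > 0, emp.to_numpy() / np.where(mean > 0, mean, 1.0),
            np.where(emp.to_numpy() > 0, np.inf, 0.0),
        )
    return pd.DataFrame(
        {
            "count": emp,
            "ensemble_mean": mean,
            "ratio": ratio,
            "undefined": (mean == 0) & (emp.to_numpy() > 0),
        }
    )


@dataclass
class PFFLbSet:
    """Instances of one pFFLb class plus its regional composition."""

    class_id: str
    instances: set  # frozensets of three node ids
    frac_any_in_area: float | None
    frac_all_in_area: float | None


def pfflb_sets(
    net: nx.DiGraph, catalog: MotifCatalog, area: str | None = None
) -> dict[str, PFFLbSet]:
    """Instance sets of the pFFLb motif classes and their area composition.

    pFFLb classes are the signed classes embedding at least one all-positive
    feedforward loop. When ``area`` is given (e.g. the primary visual area
    label), the fraction of instances with >= 1 node and with all 3 nodes in
    that area is reported; fractions are None for empty instance sets.
    """
    census = motif_intensity_census(net, catalog, return_instances=True)
    areas = nx.get_node_attributes(net, "area")
    out: dict[str, PFFLbSet] = {}
    for cls in catalog.classes:
        if not cls.contains_pffl:
            continue
        instances = set(census.loc[cls.id, "instances"])
        frac_any = frac_all = None
        if instances and area is not None:
            n_any = sum(
                1 for t in instances if any(areas.get(u) == area for u in t)
            )
            n_all = sum(
                1 for t in instances if all(areas.get(u) == area for u in t)
            )
            frac_any = n_any / len(instances)
            frac_all = n_all / len(instances)
        out[cls.id] = PFFLbSet(cls.id, instances, frac_any, frac_all)
    return out


def within_motif_pairs(instances) -> set:
    """Unordered node pairs that co-occur inside at least one motif instance."""
    pairs = set()
    for t in instances:
        for a, b in itertools.combinations(sorted(t, key=repr), 2):
            pairs.add(frozenset((a, b)))
    return pairs


def motif_overlap(sets_by_condition: dict, min_size: int = 0) -> pd.DataFrame:
    """Exact-subset intersection sizes of unique-motif sets across conditions.

    A unique motif is a (signed class, node triple) key. For every nonempty
    subset of conditions, counts the motifs present in exactly that subset
    (UpSet-style partition); rows with fewer than ``min_size`` elements are
    dropped.
    """
    conditions = list(sets_by_condition)
    membership: dict = {}
    for c in conditions:
        for key in sets_by_condition[c]:
            membership.setdefault(key, set()).add(c)
    rows = []
    for r in range(1, len(conditions) + 1):
        for subset in itertools.combinations(conditions, r):
            count = sum(1 for s in membership.values() if s == set(subset))
            rows.append({"conditions": subset, "count": count})
    df = pd.DataFrame(rows)
    if len(df):
        df = df[df["count"] >= min_size].reset_index(drop=True)
    return df
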