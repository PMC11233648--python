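import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest


def random_signed_network(
    n_nodes=30,
    density=0.1,
    frac_positive=0.7,
    frac_mutual=0.15,
    seed=0,
    areas=("V1", "LM", "AM"),
    positions=True,
):
    """Random signed directed graph with metadata, for oracle/null tests."""
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    for u in range(n_nodes):
        attrs = {"area": areas[u % len(areas)]}
        if positions:
            attrs.update(
                x=float(rng.uniform(0, 800)),
                y=float(rng.uniform(0, 800)),
                z=float(rng.uniform(0, 800)),
            )
        g.add_node(u, **attrs)
    for u, v in itertools.combinations(range(n_nodes), 2):
        r = rng.random()
        if r < density * frac_mutual:
            for a, b in ((u, v), (v, u)):
                sign = 1 if rng.random() < frac_positive else -1
                g.add_edge(a, b, sign=sign, weight=sign * rng.uniform(0.1, 2.0))
        elif r < density:
            a, b = (u, v) if rng.random() < 0.5 else (v, u)
            sign = 1 if rng.random() < frac_positive else -1
            g.add_edge(a, b, sign=sign, weight=sign * rng.uniform(0.1, 2.0))
    return g


def planted_block_network(
    n_nodes=60, n_blocks=3, p_in=0.5, p_out=0.3, seed=0
):
    """Positive within-block / negative between-block planted partition."""
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    blocks = {u: u * n_blocks // n_nodes for u in range(n_nodes)}
    g.add_nodes_from(range(n_nodes))
    for u, v in itertools.permutations(range(n_nodes), 2):
        if blocks[u] == blocks[v]:
            if rng.random() < p_in:
                g.add_edge(u, v, sign=1, weight=1.0)
        elif rng.random() < p_out:
            g.add_edge(u, v, sign=-1, weight=-1.0)
    return g, pd.Series(blocks)


@pytest.fixture
def signed_net():
    return random_signed_network(seed=11)


@pytest.fixture
def toy_three_area_units():
    """12 nodes in 3 areas of 4 (the worked partition-metric example)."""
    return pd.Series(
        ["V1"] * 4 + ["LM"] * 4 + ["AM"] * 4,
        index=pd.Index(range(12), name="node"),
    )
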