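"""Shared fixtures: synthetic communities and the networks inferred from them.

Everything is generated programmatically at test time; session scope keeps
the expensive all-pairs inference to a handful of runs.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import estuarnet as en


@pytest.fixture(scope="session")
def environment():
    """Default 7-station × 4-season × 3-year metadata (84 samples)."""
    return en.generate_environment(seed=1)


def _infer(table, tax):
    rel = en.filter_taxa(en.to_relative(table))
    cset = en.spearman_all_pairs(rel)
    enh = en.enhanced_weights(cset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = en.build_network(rel, cset, enh, tax=tax)
    return rel, cset, enh, net


@pytest.fixture(scope="session")
def default_fixture(environment):
    """Default-noise community and the network inferred from it."""
    table, tax, truth = en.generate_community(environment, en.GuildConfig(seed=1))
    rel, cset, enh, net = _infer(table, tax)
    return {"table": table, "tax": tax, "truth": truth, "rel": rel,
            "cset": cset, "enh": enh, "net": net}


@pytest.fixture(scope="session")
def zero_noise_fixture(environment):
    """Noise-free community: planted structure should be fully recoverable."""
    cfg = en.GuildConfig(seed=2, noise_sd=0.0)
    table, tax, truth = en.generate_community(environment, cfg)
    rel, cset, enh, net = _infer(table, tax)
    return {"table": table, "tax": tax, "truth": truth, "rel": rel,
            "cset": cset, "enh": enh, "net": net, "cfg": cfg}


@pytest.fixture(scope="session")
def small_table():
    """Tiny deterministic count table for IO/preprocess unit tests."""
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(10, 6))
    df = pd.DataFrame(counts,
                      index=[f"T{i}" for i in range(10)],
                      columns=[f"S{j}" for j in range(6)])
    return en.CountTable(df)


@pytest.fixture()
def toy_net():
    """3-node, 2-edge signed network with full node attributes."""
    g = nx.Graph()
    g.add_edge("A", "B", weight=0.8, sign="positive")
    g.add_edge("B", "C", weight=-0.8, sign="negative")
    for i, n in enumerate(g.nodes):
        g.nodes[n].update(abundance=0.1 * (i + 1), family=f"F{i}",
                          lineage="Bacteria;P;C;O;F;G", degree=g.degree(n),
                          betweenness=0.0, community=0)
    return g


def caveman_chain(n_cliques: int = 12, clique_size: int = 6) -> nx.Graph:
    """Chain of cliques joined by single bridge edges (for attack tests)."""
    g = nx.Graph()
    for c in range(n_cliques):
        members = [f"c{c:02d}_{i}" for i in range(clique_size)]
        for i in range(clique_size):
            for j in range(i + 1, clique_size):
                g.add_edge(members[i], members[j], weight=0.9, sign="positive")
        if c > 0:
            g.add_edge(f"c{c - 1:02d}_{clique_size - 1}", f"c{c:02d}_0",
                       weight=0.9, sign="positive")
    return g
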