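import logging

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from activemod.io_scores import AttributedNetwork
from activemod.scoring import pvalue_to_z

logging.getLogger("activemod").setLevel(logging.WARNING)


def make_attnet(pvalues: dict[str, float],
                edges: list[tuple[str, str]] | None = None) -> AttributedNetwork:
    """Attributed network straight from a p-value map (complete or given edges)."""
    g = nx.Graph()
    g.add_nodes_from(pvalues)
    if edges is None:
        nodes = sorted(pvalues)
        edges = [(nodes[i], nodes[i + 1]) for i in range(len(nodes) - 1)]
    for a, b in edges:
        g.add_edge(a, b, confidence=1.0)
    node_p = {v: float(p) for v, p in pvalues.items()}
    node_z = {v: float(pvalue_to_z(p)) for v, p in node_p.items()}
    return AttributedNetwork(graph=g, node_p=node_p, node_z=node_z,
                             provenance={v: "measured" for v in node_p})


@pytest.fixture
def attnet_factory():
    return make_attnet


@pytest.fixture
def random_attnet_factory():
    """Random graph + uniform p-values, seeded."""

    def build(n=20, p_edge=0.2, seed=0):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(n, p_edge, seed=int(rng.integers(2**31 - 1)))
        g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes()})
        pvals = {v: float(rng.uniform(1e-6, 1 - 1e-6)) for v in sorted(g.nodes())}
        return make_attnet(pvals, edges=list(g.edges()))

    return build


@pytest.fixture
def scores_csv(tmp_path):
    """Small DESeq2-style score table on disk."""
    path = tmp_path / "scores.csv"
    pd.DataFrame({
        "gene": ["G1", "G2", "G3", "G4"],
        "log2FoldChange": [0.40, 0.10, -0.50, 1.2],
        "pvalue": [0.001, 0.0005, 0.02, 0.002],
        "padj": [0.01, 0.001, 0.06, 0.03],
    }).to_csv(path, index=False)
    return path
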