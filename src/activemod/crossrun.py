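"""Cross-run comparisons: module overlap and the inter-module graph.

When the pipeline is run once per experimental condition (e.g. per
time point), two questions arise: which genes recur across runs, and how do
modules from different runs interact on the underlying network. The
inter-module graph answers the latter with a three-level edge label:
``shared_gene`` (nonempty member intersection), ``one_hop`` (a direct
interaction between members), ``two_hop`` (an interaction mediated by a
single gene outside both modules); only the strongest applicable relation
is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .merge import ModuleSet

__all__ = ["ModuleInteractionGraph", "module_overlap", "intermodule_graph"]

LABEL_ORDER = ("shared_gene", "one_hop", "two_hop")


@dataclass
class ModuleInteractionGraph:
    """Nodes are (run_label, module_id) pairs; edges carry a relation label."""

    nodes: list[tuple[str, int]]
    edges: dict[frozenset, str] = field(default_factory=dict)

    def label(self, a: tuple[str, int], b: tuple[str, int]) -> str | None:
        return self.edges.get(frozenset((a, b)))

    @staticmethod
    def node_name(node: tuple[str, int]) -> str:
        run, mid = node
        return f"{run}_m{mid}"

    def write_tsv(self, outdir: str | Path) -> dict[str, Path]:
        """Cytoscape-importable node and edge tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        node_path = outdir / "intermodule_nodes.tsv"
        with node_path.open("w") as fh:
            fh.write("module\trun\tmodule_id\n")
            for run, mid in sorted(self.nodes):
                fh.write(f"{run}_m{mid}\t{run}\t{mid}\n")
        edge_path = outdir / "intermodule_edges.tsv"
        with edge_path.open("w") as fh:
            fh.write("module_a\tmodule_b\trelation\n")
            rows = sorted(
                (tuple(sorted(pair)), label)
                for pair, label in self.edges.items()
            )
            for (a, b), label in rows:
                fh.write(f"{self.node_name(a)}\t{self.node_name(b)}\t{label}\n")
        return {"nodes": node_path, "edges": edge_path}


def module_overlap(runs: list[tuple[str, ModuleSet]]) -> pd.DataFrame:
    """Pairwise gene sharing between modules of different runs.

    One row per cross-run module pair with a nonempty intersection;
    ``jaccard`` is |intersection| / |union|.
    """
    if len(runs) < 2:
        raise ValueError("module_overlap requires at least two runs")
    rows = []
    for i, (run_a, mset_a) in enumerate(runs):
        for run_b, mset_b in runs[i + 1:]:
            for ma in mset_a:
                for mb in mset_b:
                    shared = ma.members & mb.members
                    if not shared:
                        continue
                    union = ma.members | mb.members
                    rows.append({
                        "run_a": run_a, "module_a": ma.module_id,
                        "run_b": run_b, "module_b": mb.module_id,
                        "shared_genes": len(shared),
                        "jaccard": len(shared) / len(union),
                    })
    return pd.DataFrame(rows, columns=["run_a", "module_a", "run_b",
                                       "module_b", "shared_genes", "jaccard"])


def intermodule_graph(runs: list[tuple[str, ModuleSet]],
                      net: nx.Graph) -> ModuleInteractionGraph:
    """Label every pair of modules (across and within runs) by their
    strongest network relation.

    The mediating gene of a ``two_hop`` relation must lie outside both
    modules — a mediator inside either would already make the pair
    ``one_hop`` through that gene.
    """
    entries: list[tuple[tuple[str, int], frozenset[str]]] = []
    for run, mset in runs:
        for mod in mset:
            for g in mod.members:
                if g not in net:
                    raise ValueError(
                        f"module member {g!r} (run {run!r}, module "
                        f"{mod.module_id}) is not a network node"
                    )
            entries.append(((run, mod.module_id), mod.members))

    neighbor_sets = {
        node_id: set().union(*(set(net.neighbors(g)) for g in members))
        if members else set()
        for node_id, members in entries
    }

    graph = ModuleInteractionGraph(nodes=[e[0] for e in entries])
    for i, (id_a, mem_a) in enumerate(entries):
        nbrs_a = neighbor_sets[id_a]
        for id_b, mem_b in entries[i + 1:]:
            if id_a == id_b:
                continue
            if mem_a & mem_b:
                label = "shared_gene"
            elif nbrs_a & mem_b:
                label = "one_hop"
            elif (nbrs_a - mem_a - mem_b) & neighbor_sets[id_b]:
                label = "two_hop"
            else:
                continue
            graph.edges[frozenset((id_a, id_b))] = label
    return graph
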