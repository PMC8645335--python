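"""Model/Results interface over the active-module pipeline.

``ActiveModuleModel`` holds the data (interaction network + gene score
table) and the method settings; ``fit`` runs embedding, per-vertex greedy
search, cohesive merging and permutation significance, returning an
``ActiveModuleResults`` that carries the final modules, their z-scores and
empirical p-values, diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .benchmark import PlantedBenchmark, score_recovery
from .embedding import EmbeddingConfig, EmbeddingSpace, embed
from .io_scores import (AttributedNetwork, attach_scores, read_network,
                        read_scores)
from .merge import ModuleSet, empirical_significance, finalize, merge_cohesive
from .search import CandidateModule, enumerate_candidates

logger = logging.getLogger(__name__)

__all__ = ["ActiveModuleModel", "ActiveModuleResults"]


class ActiveModuleModel:
    """Active-module detection on an attributed gene network.

    Parameters
    ----------
    network
        Undirected interaction graph (edges may carry a ``confidence``
        attribute in [0, 1]).
    scores
        Gene score table with columns ``gene`` and ``pvalue`` (as returned
        by :func:`activemod.io_scores.read_scores`).
    missing_policy
        ``neutral`` (default) imputes p=0.5 for unmeasured network nodes,
        keeping topology intact; ``drop`` removes them.
    embedding
        :class:`EmbeddingConfig` for the node2vec-style embedding.
    k_max, normalizer
        Greedy search cap on neighbours per seed and the Stouffer
        normaliser (``sqrt`` or ``mean``).
    n_perm, alpha, min_size
        Permutation count and the selection thresholds applied by
        ``finalize``.

    Examples
    --------
    >>> bench = generate_benchmark(seed=7)          # doctest: +SKIP
    >>> model = ActiveModuleModel.from_benchmark(bench)  # doctest: +SKIP
    >>> res = model.fit(seed=7)                     # doctest: +SKIP
    >>> print(res.summary())                        # doctest: +SKIP
    """

    def __init__(self, network: nx.Graph, scores: pd.DataFrame, *,
                 missing_policy: str = "neutral", case_fold: bool = False,
                 embedding: EmbeddingConfig | None = None,
                 k_max: int = 100, normalizer: str = "sqrt",
                 n_perm: int = 1000, alpha: float = 0.05, min_size: int = 3):
        self.network = network
        self.scores = scores
        self.missing_policy = missing_policy
        self.case_fold = case_fold
        self.embedding_config = embedding or EmbeddingConfig()
        self.k_max = k_max
        self.normalizer = normalizer
        self.n_perm = n_perm
        self.alpha = alpha
        self.min_size = min_size

    @classmethod
    def from_files(cls, network_path: str | Path, scores_path: str | Path,
                   *, dialect: str = "generic_tsv",
                   min_confidence: float = 0.7,
                   gene_column: str | None = None,
                   p_column: str | None = None, **kwargs):
        net = read_network(network_path, dialect=dialect,
                           min_confidence=min_confidence)
        table = read_scores(scores_path, gene_column=gene_column,
                            p_column=p_column)
        return cls(net, table, **kwargs)

    @classmethod
    def from_benchmark(cls, bench: PlantedBenchmark, **kwargs):
        model = cls(bench.network, bench.scores, **kwargs)
        model._truth = bench.truth
        return model

    def fit(self, seed: int = 0) -> "ActiveModuleResults":
        """Run the full detection pipeline with all randomness under ``seed``."""
        attnet = attach_scores(self.network, self.scores,
                               missing_policy=self.missing_policy,
                               case_fold=self.case_fold)
        space = embed(attnet.graph, self.embedding_config.with_seed(seed),
                      node_score=attnet.node_z)
        candidates = enumerate_candidates(space, attnet, k_max=self.k_max,
                                          normalizer=self.normalizer)
        merged = merge_cohesive(candidates, attnet,
                                normalizer=self.normalizer)
        scored = empirical_significance(merged, attnet, n_perm=self.n_perm,
                                        seed=seed + 1, space=space,
                                        k_max=self.k_max,
                                        normalizer=self.normalizer)
        final = finalize(scored, alpha=self.alpha, min_size=self.min_size)
        final.provenance.update({"seed": seed, "n_perm": self.n_perm,
                                 "alpha": self.alpha,
                                 "min_size": self.min_size})
        return ActiveModuleResults(
            model=self, attnet=attnet, space=space, candidates=candidates,
            modules_all=scored, modules=final, seed=seed,
            truth=getattr(self, "_truth", None),
        )


class ActiveModuleResults:
    """Fitted modules plus everything needed to inspect or export them."""

    def __init__(self, model: ActiveModuleModel, attnet: AttributedNetwork,
                 space: EmbeddingSpace,
                 candidates: list[CandidateModule],
                 modules_all: ModuleSet, modules: ModuleSet, seed: int,
                 truth=None):
        self.model = model
        self.attnet = attnet
        self.space = space
        self.candidates = candidates
        self.modules_all = modules_all
        self.modules = modules
        self.seed = seed
        self.truth = truth

    def to_frame(self) -> pd.DataFrame:
        """Final modules as a DataFrame (one row per module)."""
        rows = [{
            "module_id": m.module_id, "size": m.size, "zscore": m.z,
            "empirical_p": m.empirical_p,
            "members": ";".join(sorted(m.members)),
        } for m in self.modules]
        return pd.DataFrame(rows, columns=["module_id", "size", "zscore",
                                           "empirical_p", "members"])

    def summary(self) -> str:
        """Human-readable run summary."""
        n_measured = sum(1 for v in self.attnet.provenance.values()
                         if v == "measured")
        lines = [
            "Active-module detection results",
            "=" * 64,
            f"Network: {self.attnet.graph.number_of_nodes()} nodes, "
            f"{self.attnet.graph.number_of_edges()} edges "
            f"({n_measured} measured)",
            f"Candidates: {len(self.candidates)}  "
            f"Merged modules: {len(self.modules_all)}  "
            f"Significant (alpha={self.model.alpha:g}, "
            f"min_size={self.model.min_size}): {len(self.modules)}",
            f"Seed: {self.seed}  n_perm: {self.model.n_perm}  "
            f"normalizer: {self.model.normalizer}",
            "-" * 64,
            f"{'id':>3} {'size':>5} {'z':>9} {'emp_p':>9}  members",
        ]
        for m in self.modules:
            members = ";".join(sorted(m.members))
            if len(members) > 40:
                members = members[:37] + "..."
            lines.append(f"{m.module_id:>3} {m.size:>5} {m.z:>9.3f} "
                         f"{m.empirical_p:>9.4g}  {members}")
        if not self.modules:
            lines.append("(no significant module)")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        from .pipeline import write_modules
        return write_modules(self.modules, self.attnet, outdir)

    def score_recovery(self, truth=None) -> pd.DataFrame:
        """Best-match precision/recall/F1 against planted truth sets."""
        truth = truth if truth is not None else self.truth
        if truth is None:
            raise ValueError("no truth sets available")
        return score_recovery(self.modules, truth)
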