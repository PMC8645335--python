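"""End-to-end orchestration: configuration, pipeline run, output files.

``run_pipeline`` composes the stages read_network -> read_scores ->
attach_scores -> embed -> enumerate_candidates -> merge_cohesive ->
empirical_significance -> finalize, and writes the module summary, node
table, edge table and run-metadata JSON. Identical config + seed gives
byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .embedding import EmbeddingConfig
from .io_scores import AttributedNetwork
from .merge import Module, ModuleSet

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "write_modules",
           "read_modules"]


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass
class RunConfig:
    """Everything a run needs; serialisable and digestible.

    The SHA-256 digest of the canonical serialisation is embedded in every
    output header so results can be traced to their exact configuration.
    """

    network: str = ""
    dialect: str = "generic_tsv"
    min_confidence: float = 0.7
    scores: str = ""
    gene_column: str | None = None
    p_column: str | None = None
    missing_policy: str = "neutral"
    case_fold: bool = False
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    k_max: int = 100
    normalizer: str = "sqrt"
    n_perm: int = 1000
    alpha: float = 0.05
    min_size: int = 3
    seed: int = 0
    outdir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        emb = data.pop("embedding", None)
        config = cls(**data)
        if emb is not None:
            config.embedding = EmbeddingConfig(**emb)
        return config

    def digest(self) -> str:
        # the output directory is not part of the scientific configuration
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> ModuleSet:
    """Run the full pipeline described by ``config``.

    Returns the final :class:`ModuleSet`; when ``config.outdir`` is set the
    module summary, node table, edge table and metadata JSON are written
    there as well.
    """
    from .model import ActiveModuleModel  # local import to avoid a cycle

    timings: dict[str, float] = {}

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"[{name}] {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        return out

    model = stage("read_inputs", ActiveModuleModel.from_files,
                  config.network, config.scores,
                  dialect=config.dialect,
                  min_confidence=config.min_confidence,
                  gene_column=config.gene_column,
                  p_column=config.p_column,
                  missing_policy=config.missing_policy,
                  case_fold=config.case_fold,
                  embedding=config.embedding,
                  k_max=config.k_max,
                  normalizer=config.normalizer,
                  n_perm=config.n_perm,
                  alpha=config.alpha,
                  min_size=config.min_size)
    results = stage("fit", model.fit, seed=config.seed)
    mset = results.modules
    mset.provenance.update({
        "config_digest": config.digest(),
        "seed": config.seed,
        "timings": timings,
    })
    if config.outdir:
        stage("write_outputs", write_modules, mset, results.attnet,
              config.outdir, config=config)
    logger.info("pipeline finished: %d final modules (%s)",
                len(mset), timings)
    return mset


def _header(config: RunConfig | None, seed) -> str:
    digest = config.digest() if config is not None else "unknown"
    return f"# activemod v{__version__} config={digest} seed={seed}\n"


def write_modules(mset: ModuleSet, attnet: AttributedNetwork,
                  outdir: str | Path,
                  config: RunConfig | None = None) -> dict[str, Path]:
    """Write the module summary, node table, edge table and metadata JSON.

    The summary line format round-trips: :func:`read_modules` reconstructs
    the member sets exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = mset.provenance.get("seed", config.seed if config else "unknown")
    header = _header(config, seed)

    summary = outdir / "modules.tsv"
    with summary.open("w") as fh:
        fh.write(header)
        fh.write("module_id\tsize\tzscore\tempirical_p\tmembers\n")
        for m in mset:
            p_str = "" if m.empirical_p is None else f"{m.empirical_p:.6g}"
            fh.write(f"{m.module_id}\t{m.size}\t{m.z:.6f}\t{p_str}\t"
                     + ";".join(sorted(m.members)) + "\n")

    node_table = outdir / "nodes.tsv"
    with node_table.open("w") as fh:
        fh.write(header)
        fh.write("gene\tmodule_id\tpvalue\tzscore\tseed_flag\n")
        for m in mset:
            for g in sorted(m.members):
                fh.write(f"{g}\t{m.module_id}\t{attnet.node_p[g]:.6g}\t"
                         f"{attnet.node_z[g]:.6f}\t{int(g in m.seeds)}\n")

    edge_table = outdir / "edges.tsv"
    with edge_table.open("w") as fh:
        fh.write(header)
        fh.write("gene1\tgene2\tconfidence\tmodule_id\n")
        for m in mset:
            members = sorted(m.members)
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    if attnet.graph.has_edge(a, b):
                        conf = attnet.graph[a][b].get("confidence", 1.0)
                        fh.write(f"{a}\t{b}\t{conf:g}\t{m.module_id}\n")

    meta = outdir / "run_meta.json"
    meta.write_text(json.dumps({
        "version": __version__,
        "config": config.to_dict() if config else None,
        "config_digest": config.digest() if config else None,
        "provenance": {k: v for k, v in mset.provenance.items()
                       if k != "timings"},
        "timings": mset.provenance.get("timings"),
        "n_modules": len(mset),
    }, indent=2, default=str))

    if not mset.modules:
        logger.warning("empty module set written to %s", outdir)
    return {"summary": summary, "nodes": node_table, "edges": edge_table,
            "meta": meta}


def read_modules(summary_path: str | Path) -> ModuleSet:
    """Reconstruct a ModuleSet from a written module summary TSV."""
    modules = []
    lines = Path(summary_path).read_text().splitlines()
    for line in lines:
        if line.startswith("#") or line.startswith("module_id") or not line:
            continue
        mid, size, z, emp_p, members = line.split("\t")
        modules.append(Module(
            module_id=int(mid),
            members=frozenset(members.split(";")) if members else frozenset(),
            z=float(z),
            empirical_p=float(emp_p) if emp_p else None,
        ))
    return ModuleSet(modules=modules)
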