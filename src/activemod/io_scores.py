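"""Input handling: interaction networks, differential-expression score tables,
and their fusion into an attributed network.

The pipeline consumes two inputs: a gene-interaction network (an edge list,
either in the STRING ``protein.links`` dialect with a 0-1000 combined score,
or a generic 2/3-column TSV) and a per-gene score table as produced by
differential-expression pipelines such as DESeq2 or edgeR (CSV or XLSX with a
gene column and a p-value column). The two are merged into an
:class:`AttributedNetwork` in which every node carries a p-value and the
corresponding z-score ``z = Phi^-1(1 - p)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .scoring import pvalue_to_z

logger = logging.getLogger(__name__)

#: p-values are clipped into [P_EPS, 1 - P_EPS] before the normal quantile
#: transform; DESeq2 routinely reports adjusted p-values of exactly 0.
P_EPS = 1e-16

#: column aliases for auto-detection, in priority order (matched
#: case-insensitively). Adjusted p-values outrank raw p-values because the
#: upstream pipelines this targets (DESeq2/edgeR/limma) report both.
P_COLUMN_ALIASES = ("padj", "fdr", "adj.p.val", "qvalue", "pvalue", "p_value", "p")
GENE_COLUMN_ALIASES = ("gene", "gene_id", "geneid")
LOG2FC_COLUMN_ALIASES = ("log2foldchange", "log2fc", "logfc")
PADJ_COLUMN_ALIASES = ("padj", "fdr", "adj.p.val", "qvalue")

_GENERIC_HEADER_TOKENS = {
    "source", "target", "gene1", "gene2", "protein1", "protein2",
    "node1", "node2", "from", "to",
}
_GENERIC_HEADER_SCORE_TOKENS = {
    "weight", "score", "confidence", "combined_score", "w",
}


class InputError(ValueError):
    """Raised for unreadable, malformed or empty inputs."""


@dataclass
class AttributedNetwork:
    """An interaction network whose nodes carry p-values and z-scores.

    ``provenance[v]`` is ``"measured"`` when the p-value came from the score
    table and ``"imputed"`` when the neutral value p=0.5 (z=0) was assigned.
    """

    graph: nx.Graph
    node_p: dict[str, float]
    node_z: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes())

    def __contains__(self, node: str) -> bool:
        return node in self.graph


def _parse_confidence(token: str, path: Path, lineno: int, scale: float) -> float:
    try:
        value = float(token) / scale
    except ValueError:
        raise InputError(
            f"{path}, line {lineno}: non-numeric confidence {token!r}"
        ) from None
    if not 0.0 <= value <= 1.0:
        raise InputError(
            f"{path}, line {lineno}: confidence {value:g} outside [0, 1]"
        )
    return value


def read_network(
    path: str | Path,
    dialect: str = "generic_tsv",
    min_confidence: float = 0.0,
) -> nx.Graph:
    """Read an undirected weighted interaction network from an edge list.

    Parameters
    ----------
    path
        Edge-list file. ``string_links`` expects a header line with columns
        ``protein1 protein2 combined_score`` and integer scores on a 0-1000
        scale (divided by 1000 before thresholding). ``generic_tsv`` expects
        2 columns (confidence 1.0) or 3 columns with a confidence in [0, 1];
        a header line is skipped when its third field is non-numeric or its
        node fields are recognised header tokens.
    min_confidence
        Edges with confidence strictly below this value are discarded.

    Returns
    -------
    networkx.Graph
        Undirected graph; each edge has a ``confidence`` attribute. Self
        loops are dropped, duplicate edges collapse to the maximum
        confidence, and nodes appear only as edge endpoints (no isolates).
    """
    path = Path(path)
    if dialect not in ("string_links", "generic_tsv"):
        raise InputError(f"unknown network dialect {dialect!r}")
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise InputError(f"cannot read network file {path}: {exc}") from exc

    graph = nx.Graph()
    start = 0
    if dialect == "string_links":
        # mandatory header
        if not lines:
            raise InputError(f"{path}: empty file")
        header = lines[0].split()
        if [h.lower() for h in header[:3]] != ["protein1", "protein2", "combined_score"]:
            raise InputError(
                f"{path}, line 1: expected header 'protein1 protein2 "
                f"combined_score', got {lines[0]!r}"
            )
        start = 1
        scale = 1000.0
    else:
        scale = 1.0
        if lines:
            first = lines[0].split()
            if len(first) >= 2:
                is_header = bool({t.lower() for t in first[:2]}
                                 & _GENERIC_HEADER_TOKENS)
                if len(first) == 3 and not is_header:
                    is_header = first[2].lower() in _GENERIC_HEADER_SCORE_TOKENS
                if is_header:
                    start = 1

    n_read = 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) == 2 and dialect == "generic_tsv":
            a, b = fields
            conf = 1.0
        elif len(fields) == 3:
            a, b = fields[:2]
            conf = _parse_confidence(fields[2], path, lineno, scale)
        else:
            raise InputError(
                f"{path}, line {lineno}: expected 2 or 3 columns, "
                f"got {len(fields)}"
            )
        n_read += 1
        if a == b:
            continue
        if conf < min_confidence:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["confidence"] = max(graph[a][b]["confidence"], conf)
        else:
            graph.add_edge(a, b, confidence=conf)

    if graph.number_of_edges() == 0:
        raise InputError(
            f"{path}: no edges remain (read {n_read} edge lines, "
            f"min_confidence={min_confidence:g})"
        )
    logger.info(
        "read network %s: %d nodes, %d edges (min_confidence=%g)",
        path.name, graph.number_of_nodes(), graph.number_of_edges(),
        min_confidence,
    )
    return graph


def write_network(graph: nx.Graph, path: str | Path) -> Path:
    """Export a network in the generic 3-column TSV dialect."""
    path = Path(path)
    with path.open("w") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            u, v = sorted((a, b))
            fh.write(f"{u}\t{v}\t{data.get('confidence', 1.0):g}\n")
    return path


def _resolve_column(columns, requested, aliases, kind, required=True):
    if requested is not None:
        if requested in columns:
            return requested
        raise InputError(
            f"requested {kind} column {requested!r} not found; "
            f"available: {list(columns)}"
        )
    lowered = {str(c).strip().lower(): c for c in reversed(list(columns))}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    if required:
        raise InputError(
            f"no {kind} column recognised; available headers: {list(columns)}"
        )
    return None


def read_scores(
    path: str | Path,
    gene_column: str | None = None,
    p_column: str | None = None,
) -> pd.DataFrame:
    """Read a per-gene score table from CSV or XLSX.

    Column resolution is automatic unless overridden: the p-value column is
    the first match among ``padj, FDR, adj.P.Val, qvalue, pvalue, PValue,
    p_value, P`` (case-insensitive) and the gene column the first among
    ``gene, gene_id, Geneid`` falling back to an unnamed leading index
    column. ``log2fc`` and ``padj`` columns are carried along when present
    so that the differential-expression filter can be applied downstream.

    Returns a DataFrame with columns ``gene``, ``pvalue`` and, when
    available, ``log2fc`` and ``padj``. p-values are clipped into
    ``[1e-16, 1 - 1e-16]``; rows with missing p-values are dropped (count
    logged); duplicate genes keep the smallest p-value.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".xlsx", ".xls"):
            raw = pd.read_excel(path, sheet_name=0)
        else:
            raw = pd.read_csv(path)
    except OSError as exc:
        raise InputError(f"cannot read score table {path}: {exc}") from exc

    if raw.empty:
        raise InputError(f"{path}: score table has no rows")

    columns = list(raw.columns)
    gene_col = _resolve_column(columns, gene_column, GENE_COLUMN_ALIASES,
                               "gene", required=False)
    if gene_col is None:
        first = str(columns[0])
        if first.startswith("Unnamed") or first == "" or gene_column is None:
            gene_col = columns[0]
        else:
            raise InputError(
                f"no gene column recognised; available headers: {columns}"
            )
    p_col = _resolve_column(columns, p_column, P_COLUMN_ALIASES, "p-value")
    fc_col = _resolve_column(columns, None, LOG2FC_COLUMN_ALIASES,
                             "log2 fold-change", required=False)
    padj_col = _resolve_column(columns, None, PADJ_COLUMN_ALIASES,
                               "adjusted p-value", required=False)

    table = pd.DataFrame({
        "gene": raw[gene_col].astype(str),
        "pvalue": pd.to_numeric(raw[p_col], errors="coerce").astype(float),
    })
    if fc_col is not None:
        table["log2fc"] = pd.to_numeric(raw[fc_col],
                                        errors="coerce").astype(float)
    if padj_col is not None:
        table["padj"] = pd.to_numeric(raw[padj_col],
                                      errors="coerce").astype(float)

    n_missing = int(table["pvalue"].isna().sum())
    if n_missing:
        logger.info("dropped %d rows with missing p-values", n_missing)
        table = table.dropna(subset=["pvalue"])
    if table.empty:
        raise InputError(f"{path}: no rows with a valid p-value")

    table["pvalue"] = table["pvalue"].clip(P_EPS, 1.0 - P_EPS)
    if "padj" in table:
        table["padj"] = table["padj"].clip(P_EPS, 1.0 - P_EPS)
    # most significant evidence wins on duplicate identifiers
    table = (table.sort_values(["pvalue", "gene"], kind="stable")
                  .drop_duplicates(subset="gene", keep="first")
                  .reset_index(drop=True))
    logger.info("read %d gene scores from %s", len(table), path.name)
    return table


def filter_differential(
    table: pd.DataFrame,
    fold_threshold: float = 1.25,
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Keep genes called differentially expressed.

    A gene passes when ``|log2fc| >= log2(fold_threshold)`` (default factor
    1.25, i.e. |log2FC| >= 0.3219) and ``padj <= padj_threshold`` (default
    0.05). Both columns must be present and complete.
    """
    for col in ("log2fc", "padj"):
        if col not in table.columns:
            raise InputError(f"filter_differential requires a {col!r} column")
        if table[col].isna().any():
            raise InputError(f"filter_differential: missing values in {col!r}")
    cut = math.log2(fold_threshold)
    mask = (table["log2fc"].abs() >= cut) & (table["padj"] <= padj_threshold)
    return table[mask].reset_index(drop=True)


def attach_scores(
    net: nx.Graph,
    table: pd.DataFrame,
    missing_policy: str = "neutral",
    case_fold: bool = False,
) -> AttributedNetwork:
    """Merge a score table onto a network, producing an attributed network.

    Matching is exact string identity (optionally case-folded). Network
    nodes absent from the table receive the neutral p=0.5 (z=0) under the
    default ``neutral`` policy, or are removed under ``drop``. Table genes
    absent from the network are logged and ignored.
    """
    if missing_policy not in ("neutral", "drop"):
        raise InputError(f"unknown missing_policy {missing_policy!r}")

    scores: Mapping[str, float]
    if case_fold:
        scores = {str(g).lower(): p for g, p in
                  zip(table["gene"], table["pvalue"])}
        key = lambda v: str(v).lower()  # noqa: E731
    else:
        scores = dict(zip(table["gene"], table["pvalue"]))
        key = str

    matched = [v for v in net.nodes() if key(v) in scores]
    if not matched:
        raise InputError(
            "no gene in the score table matches any network node — the two "
            "inputs likely use different identifier namespaces "
            "(e.g. FlyBase IDs vs gene symbols vs STRING protein IDs)"
        )
    net_keys = {key(v) for v in net.nodes()}
    unmatched_table = sum(1 for g in scores if g not in net_keys)
    logger.info(
        "attach_scores: %d/%d network nodes measured; %d table genes "
        "not in the network", len(matched), net.number_of_nodes(),
        unmatched_table,
    )

    if missing_policy == "drop":
        graph = net.subgraph(matched).copy()
    else:
        graph = net.copy()

    node_p: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for v in graph.nodes():
        if key(v) in scores:
            node_p[v] = float(min(max(scores[key(v)], P_EPS), 1.0 - P_EPS))
            provenance[v] = "measured"
        else:
            node_p[v] = 0.5
            provenance[v] = "imputed"
    node_z = {v: float(pvalue_to_z(p)) for v, p in node_p.items()}
    return AttributedNetwork(graph=graph, node_p=node_p, node_z=node_z,
                             provenance=provenance)
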