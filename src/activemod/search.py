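"""Greedy per-vertex module search over cosine-ranked neighbour lists.

For each seed vertex v the candidate module of size k+1 is the first k+1
entries of lov(v) (v itself plus its k nearest embedded neighbours); the
retained candidate is the prefix length maximising the Stouffer aggregate
z-score. One candidate per vertex, deduplicated by member set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_scores import AttributedNetwork

__all__ = ["CandidateModule", "best_cluster", "enumerate_candidates"]


@dataclass(frozen=True)
class CandidateModule:
    """A seed vertex with its k nearest embedded neighbours.

    ``members`` is exactly the first k+1 entries of lov(seed); ``z`` the
    Stouffer aggregate of the members' z-scores.
    """

    seed: str
    members: frozenset[str]
    k: int
    z: float


def _prefix_scores(z_along_lov: np.ndarray, k_max: int,
                   normalizer: str) -> np.ndarray:
    """Aggregate z of each lov prefix of length 1..k_max+1."""
    sizes = np.arange(1, k_max + 2, dtype=float)
    csum = np.cumsum(z_along_lov[: k_max + 1])
    if normalizer == "sqrt":
        return csum / np.sqrt(sizes)
    if normalizer == "mean":
        return csum / sizes
    raise ValueError(f"unknown normalizer {normalizer!r}")


def best_cluster(space, attnet: AttributedNetwork, seed: str,
                 k_max: int = 100, normalizer: str = "sqrt") -> CandidateModule:
    """The lov(seed) prefix with maximal aggregate z, k in [0, k_max].

    Ties in the aggregate are broken toward the smallest k (parsimony).
    """
    lov = space.rank_neighbors(seed)
    k_max = min(k_max, len(lov) - 1)
    z_along = np.array([attnet.node_z[v] for v in lov[: k_max + 1]])
    scores = _prefix_scores(z_along, k_max, normalizer)
    k_star = int(np.argmax(scores))  # first max -> smallest k on ties
    return CandidateModule(
        seed=seed,
        members=frozenset(lov[: k_star + 1]),
        k=k_star,
        z=float(scores[k_star]),
    )


def enumerate_candidates(space, attnet: AttributedNetwork,
                         k_max: int = 100,
                         normalizer: str = "sqrt") -> list[CandidateModule]:
    """One best-prefix candidate per vertex, deduplicated and z-sorted.

    Candidates with identical member sets collapse to the one with the
    lexicographically smallest seed; the result is sorted by z descending
    (seed id as deterministic tie-break).
    """
    nodes = sorted(attnet.graph.nodes())
    z_map = attnet.node_z

    candidates: list[CandidateModule] = []
    rank_all = getattr(space, "rank_all", None)
    if rank_all is not None and list(space.nodes) == nodes:
        lov_idx = rank_all()
        z_arr = np.array([z_map[v] for v in nodes])
        k_cap = min(k_max, len(nodes) - 1)
        sizes = np.sqrt(np.arange(1, k_cap + 2, dtype=float))
        prefix = np.cumsum(z_arr[lov_idx[:, : k_cap + 1]], axis=1)
        scores = prefix / sizes if normalizer == "sqrt" \
            else prefix / np.arange(1, k_cap + 2, dtype=float)
        k_star = np.argmax(scores, axis=1)
        for i, v in enumerate(nodes):
            ks = int(k_star[i])
            members = frozenset(nodes[j] for j in lov_idx[i, : ks + 1])
            candidates.append(CandidateModule(
                seed=v, members=members, k=ks,
                z=float(scores[i, ks]),
            ))
    else:
        for v in nodes:
            candidates.append(
                best_cluster(space, attnet, v, k_max=k_max,
                             normalizer=normalizer)
            )

    unique: dict[frozenset, CandidateModule] = {}
    for cand in candidates:
        prev = unique.get(cand.members)
        if prev is None or cand.seed < prev.seed:
            unique[cand.members] = cand
    return sorted(unique.values(), key=lambda c: (-c.z, c.seed))
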