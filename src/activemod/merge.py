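"""Cohesive merging of candidate modules and permutation significance.

Two candidates are spatially cohesive when their member sets intersect.
Starting from the highest-z candidate, all unions with subsets of its
highest-scoring cohesive partners are evaluated and the best-scoring union
is emitted as a final module; everything touching the emitted module is
consumed, which guarantees pairwise-disjoint output. Because the empty
subset is always evaluated, an emitted module never scores below its best
constituent.

The subset search runs over a bounded pool (the ``MERGE_POOL_SIZE``
highest-z distinct candidates overlapping the module being grown) and is
always exhaustive on that pool. Bounding matters twice: it caps the
exponential powerset, and it makes the merge step exactly replayable
inside the permutation null, so the significance test compares the
observed modules against the same maximisation that produced them.

The method advertises itself as parameter-free, so module selection is
automatic: each final module receives an empirical p-value from a
permutation null in which node p-values are shuffled across the fixed
topology and the search (per-seed best prefix + bounded cohesive merge)
is repeated, and ``finalize`` keeps modules that beat the null at a given
alpha and minimum size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io_scores import AttributedNetwork
from .search import CandidateModule

logger = logging.getLogger(__name__)

__all__ = ["Module", "ModuleSet", "merge_cohesive",
           "empirical_significance", "finalize"]

#: cohesive-merge pool: the powerset of at most this many overlapping
#: candidates is enumerated exhaustively (2^10 unions per emitted module)
MERGE_POOL_SIZE = 10


@dataclass(frozen=True)
class Module:
    module_id: int
    members: frozenset[str]
    z: float
    empirical_p: float | None = None
    seeds: frozenset[str] = frozenset()

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ModuleSet:
    """Final disjoint modules ordered by z descending, plus run metadata."""

    modules: list[Module]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def member_sets(self) -> list[frozenset[str]]:
        return [m.members for m in self.modules]


def _score(total: float, n: int, normalizer: str) -> float:
    return total / math.sqrt(n) if normalizer == "sqrt" else total / n


def _best_pool_union(base_members, pool_sets, z_map, normalizer):
    """Exhaustive union search over all subsets of ``pool_sets``.

    Returns ``(best_z, best_members, chosen_indices)``. Float sums run in
    sorted-member order so results do not depend on set-iteration order
    (string-hash randomisation).
    """
    members = set(base_members)
    cur_sum = sum(z_map[m] for m in sorted(members))
    best = [_score(cur_sum, len(members), normalizer), set(members), []]
    chosen: list[int] = []

    def recurse(i, cur_sum):
        for j in range(i, len(pool_sets)):
            new = [m for m in sorted(pool_sets[j]) if m not in members]
            members.update(new)
            s2 = cur_sum + sum(z_map[m] for m in new)
            val = _score(s2, len(members), normalizer)
            chosen.append(j)
            if val > best[0] + 1e-12:
                best[0] = val
                best[1] = set(members)
                best[2] = list(chosen)
            recurse(j + 1, s2)
            chosen.pop()
            members.difference_update(new)

    recurse(0, cur_sum)
    return best[0], best[1], best[2]


def merge_cohesive(candidates: list[CandidateModule],
                   attnet: AttributedNetwork,
                   normalizer: str = "sqrt") -> ModuleSet:
    """Merge overlapping candidates into disjoint final modules.

    ``candidates`` must already be deduplicated and sorted by z descending
    (the output of :func:`activemod.search.enumerate_candidates`). For
    each emitted module the union search considers the
    ``MERGE_POOL_SIZE`` highest-z candidates with distinct member sets
    that overlap the base candidate.
    """
    z_map = attnet.node_z
    pool = list(candidates)
    emitted: list[Module] = []
    while pool:
        base = pool.pop(0)
        overlapping: list[CandidateModule] = []
        seen_sets = {base.members}
        for cand in pool:
            if len(overlapping) >= MERGE_POOL_SIZE:
                break
            if cand.members in seen_sets:
                continue
            if cand.members & base.members:
                overlapping.append(cand)
                seen_sets.add(cand.members)
        z_val, members, chosen_idx = _best_pool_union(
            base.members, [c.members for c in overlapping], z_map, normalizer)
        seeds = frozenset([base.seed] + [overlapping[j].seed
                                         for j in chosen_idx])
        emitted.append(Module(
            module_id=0, members=frozenset(members), z=float(z_val),
            seeds=seeds,
        ))
        pool = [c for c in pool if not (c.members & members)]

    emitted.sort(key=lambda m: (-m.z, min(m.members)))
    modules = [replace(m, module_id=i + 1) for i, m in enumerate(emitted)]
    return ModuleSet(modules=modules)


def _subset_masks(pool_size: int) -> np.ndarray:
    """(2^pool_size, pool_size + 1) float matrix; column 0 (the base) is
    always selected, the remaining columns enumerate every subset."""
    n_subsets = 1 << pool_size
    masks = np.ones((n_subsets, pool_size + 1), dtype=np.float64)
    for j in range(pool_size):
        masks[:, j + 1] = (np.arange(n_subsets) >> j) & 1
    return masks


def _null_max_replay(z_arr, lov_prefix, sqrt_sizes, rng, normalizer,
                     subset_masks):
    """Max merged-module z for one permutation of the node z-scores.

    Replays the observed pipeline on shuffled z: per-seed best lov prefix,
    then the same bounded cohesive merge around the top candidate. All
    subset unions are evaluated with one boolean matrix product.
    """
    n = z_arr.size
    zp = z_arr[rng.permutation(n)]
    prefix = np.cumsum(zp[lov_prefix], axis=1)
    prefix = prefix / sqrt_sizes if normalizer == "sqrt" \
        else prefix / (sqrt_sizes ** 2)
    best_k = np.argmax(prefix, axis=1)
    best_z = prefix[np.arange(n), best_k]
    order = np.argsort(-best_z, kind="stable")

    # boolean membership of every candidate (rows align with nodes)
    width = lov_prefix.shape[1]
    keep = np.arange(width) <= best_k[:, None]
    members = np.zeros((n, n), dtype=bool)
    np.put_along_axis(members, lov_prefix, keep, axis=1)

    base_i = order[0]
    base_row = members[base_i]
    pool_rows = [base_row]
    seen = {(int(best_k[base_i]), lov_prefix[base_i, 0])}
    for i in order[1:]:
        if len(pool_rows) >= MERGE_POOL_SIZE + 1:
            break
        row = members[i]
        if not (row & base_row).any():
            continue
        key = (int(best_k[i]), lov_prefix[i, 0])
        if key in seen or any(np.array_equal(row, r) for r in pool_rows):
            continue
        pool_rows.append(row)
        seen.add(key)

    B = np.array(pool_rows, dtype=np.float64)
    n_pool = B.shape[0] - 1
    masks = subset_masks[: 1 << n_pool, : n_pool + 1] if n_pool \
        else subset_masks[:1, :1]
    union = (masks @ B) > 0
    sizes = union.sum(axis=1)
    zsums = union @ zp
    scores = zsums / np.sqrt(sizes) if normalizer == "sqrt" else zsums / sizes
    return float(scores.max())


def empirical_significance(mset: ModuleSet, attnet: AttributedNetwork,
                           n_perm: int = 1000, seed: int = 0,
                           space=None, k_max: int = 100,
                           normalizer: str = "sqrt") -> ModuleSet:
    """Attach a permutation-based empirical p-value to every module.

    Node p-values are shuffled across nodes ``n_perm`` times with the
    topology (and embedding) fixed. When ``space`` is given, each
    permutation replays the module search itself — per-seed best-prefix
    candidates on the shuffled scores followed by the same bounded
    cohesive merge — and the null statistic is the maximum resulting
    module z, so the null is calibrated against the same maximisation
    that produced the observed modules. Without a space, the null
    statistic falls back to the maximum Stouffer z over one random
    same-size node set per network node, computed per module size.
    Either way ``empirical_p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if not mset.modules:
        return ModuleSet(modules=[], provenance=dict(mset.provenance))

    nodes = sorted(attnet.graph.nodes())
    z_arr = np.array([attnet.node_z[v] for v in nodes])
    n = z_arr.size
    rng = np.random.default_rng(seed)

    if space is not None:
        k_cap = min(k_max, n - 1)
        lov_prefix = space.rank_all()[:, : k_cap + 1]
        sqrt_sizes = np.sqrt(np.arange(1, k_cap + 2, dtype=float))
        subset_masks = _subset_masks(MERGE_POOL_SIZE)
        null_max = np.empty(n_perm)
        for b in range(n_perm):
            null_max[b] = _null_max_replay(
                z_arr, lov_prefix, sqrt_sizes, rng, normalizer,
                subset_masks)
        modules = [
            replace(m, empirical_p=float(
                (1 + int((null_max >= m.z).sum())) / (n_perm + 1)))
            for m in mset.modules
        ]
    else:
        sizes = sorted({m.size for m in mset.modules})
        null_by_size: dict[int, np.ndarray] = {}
        for s in sizes:
            stat = np.empty(n_perm)
            for b in range(n_perm):
                zp = z_arr[rng.permutation(n)]
                idx = rng.integers(0, n, size=(n, s))
                stat[b] = (zp[idx].sum(axis=1) / math.sqrt(s)).max()
            null_by_size[s] = stat
        modules = [
            replace(m, empirical_p=float(
                (1 + int((null_by_size[m.size] >= m.z).sum())) / (n_perm + 1)))
            for m in mset.modules
        ]
    return ModuleSet(modules=modules, provenance=dict(mset.provenance))


def finalize(mset: ModuleSet, alpha: float = 0.05,
             min_size: int = 3) -> ModuleSet:
    """Keep significant, informative modules and renumber them.

    Modules with ``empirical_p <= alpha`` and at least ``min_size`` members
    survive, renumbered 1..N by descending z. An empty result is legal
    (and logged): it is the method's way of reporting no detectable
    perturbation.
    """
    for m in mset.modules:
        if m.empirical_p is None:
            raise ValueError("finalize requires empirical_p on every module")
    kept = [m for m in mset.modules
            if m.empirical_p <= alpha and m.size >= min_size]
    if not kept:
        logger.warning("no module passed alpha=%g, min_size=%d",
                       alpha, min_size)
    kept.sort(key=lambda m: (-m.z, min(m.members)))
    modules = [replace(m, module_id=i + 1) for i, m in enumerate(kept)]
    return ModuleSet(modules=modules, provenance=dict(mset.provenance))
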