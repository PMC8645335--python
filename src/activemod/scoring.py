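"""p-value to z-score transform and Stouffer aggregation of vertex sets.

A node with p-value ``p`` gets ``z = Phi^-1(1 - p)`` where ``Phi`` is the
standard normal CDF; small p-values map to large positive z. A set of nodes
is scored with Stouffer's Z method, ``sum(z_i) / sqrt(n)``, which is
standard normal under the null of independent uniform p-values — so the
score rewards adding genuinely perturbed nodes and penalises diluting a
module with unperturbed (z ~ 0) ones.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = ["pvalue_to_z", "aggregate_z", "module_z"]


def pvalue_to_z(p):
    """Map a p-value in the open interval (0, 1) to a z-score.

    ``z = Phi^-1(1 - p)``; strictly decreasing in p. Accepts scalars or
    arrays. Values at or outside the interval boundaries raise — callers
    are expected to clip (see :data:`activemod.io_scores.P_EPS`).
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError("p-values must lie strictly inside (0, 1); clip first")
    z = stats.norm.isf(arr)
    return float(z) if np.isscalar(p) or arr.ndim == 0 else z


def aggregate_z(zs: Sequence[float], normalizer: str = "sqrt") -> float:
    """Combine z-scores: Stouffer ``sum/sqrt(n)`` (default) or plain mean.

    Order-invariant; raises on an empty or non-finite input.
    """
    arr = np.asarray(list(zs), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty list of z-scores")
    if not np.all(np.isfinite(arr)):
        raise ValueError("z-scores must be finite")
    total = float(arr.sum())
    if normalizer == "sqrt":
        return total / math.sqrt(arr.size)
    if normalizer == "mean":
        return total / arr.size
    raise ValueError(f"unknown normalizer {normalizer!r}")


def module_z(attnet, members: Iterable[str], normalizer: str = "sqrt") -> float:
    """Aggregate z-score of a node set on an attributed network."""
    members = sorted(members) if isinstance(members, (set, frozenset)) \
        else list(members)
    zs = []
    for m in members:
        try:
            zs.append(attnet.node_z[m])
        except KeyError:
            raise KeyError(f"node {m!r} is not in the attributed network") from None
    return aggregate_z(zs, normalizer=normalizer)
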