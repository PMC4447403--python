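"""The cross-match two-sample test on a minimum-weight perfect matching.

All units from both groups are matched pairwise on a complete graph so the
total within-pair distance is minimal, ignoring the group labels; the test
statistic A1 is the number of pairs joining the two groups.  If the groups
come from the same distribution, labels are exchangeable given the matching
and A1 follows a known combinatorial null; well-separated groups yield few
cross pairs and a small lower-tail p-value P(A1 <= a1).

The null distribution is exact and distribution-free:

    P(A1 = a1) = 2^a1 * I! / [ ((n1-a1)/2)! * a1! * ((n2-a1)/2)! * C(N, n1) ]

with N = n1 + n2 total units and I = N/2 pairs; a1 must share the parity
of n1.  For an odd total, a phantom unit farther from every real unit than
any observed distance is added; its partner is discarded before counting
and the null uses the reduced even count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb, factorial
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import InvalidInputError

__all__ = [
    "CrossMatchResult",
    "crossmatch_null_pvalue",
    "crossmatch_null_pmf",
    "crossmatch_test",
    "min_weight_pairing",
]


@dataclass
class CrossMatchResult:
    a1: int
    matching: list[tuple[str, str]]
    n_total: int
    n_group1: int
    p: float
    method: str = "closed-form"


def _achievable(a1: int, n1: int, n2: int) -> bool:
    return 0 <= a1 <= min(n1, n2) and (n1 - a1) % 2 == 0


def crossmatch_null_pmf(a1: int, n_total: int, n_group1: int) -> float:
    """Exact null probability P(A1 = a1) for a fixed perfect matching."""
    n1, n2 = n_group1, n_total - n_group1
    if n_total % 2 != 0:
        raise InvalidInputError("n_total must be even (after phantom handling)")
    if not _achievable(a1, n1, n2):
        return 0.0
    pairs = n_total // 2
    num = 2**a1 * factorial(pairs)
    den = (
        factorial((n1 - a1) // 2)
        * factorial(a1)
        * factorial((n2 - a1) // 2)
        * comb(n_total, n1)
    )
    return num / den


def crossmatch_null_pvalue(a1: int, n_total: int, n_group1: int) -> float:
    """Lower-tail exact p-value P(A1 <= a1) under random labelings."""
    n1, n2 = n_group1, n_total - n_group1
    if n_total % 2 != 0:
        raise InvalidInputError("n_total must be even (after phantom handling)")
    if not _achievable(a1, n1, n2):
        raise InvalidInputError(
            f"a1={a1} impossible for group sizes {n1}/{n2} (parity/range)"
        )
    lo = 0 if n1 % 2 == 0 else 1
    return float(sum(
        crossmatch_null_pmf(k, n_total, n_group1)
        for k in range(lo, a1 + 1, 2)
    ))


def min_weight_pairing(
    dist: np.ndarray, ids: Sequence[str]
) -> list[tuple[int, int]]:
    """Minimum-weight perfect matching of a complete graph.

    ``dist`` is a symmetric matrix over an even number of units.  Equal-
    weight alternatives are broken deterministically by adding a tiny
    penalty increasing in lexicographic (id, id) pair order.
    """
    n = dist.shape[0]
    if n % 2 != 0:
        raise InvalidInputError("perfect matching needs an even unit count")
    order = sorted(range(n), key=lambda i: str(ids[i]))
    pair_rank = {}
    r = 0
    for a in range(n):
        for b in range(a + 1, n):
            pair_rank[(order[a], order[b])] = r
            pair_rank[(order[b], order[a])] = r
            r += 1
    scale = float(dist.max()) or 1.0
    eps = 1e-9 * scale / max(r, 1)
    g = nx.Graph()
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=float(dist[i, j]) + eps * pair_rank[(i, j)])
    mate = nx.min_weight_matching(g)
    return [tuple(sorted(e)) for e in sorted(mate)]


def crossmatch_test(
    points: np.ndarray,
    labels: Sequence,
    ids: Sequence[str] | None = None,
    metric: str = "euclidean",
) -> CrossMatchResult:
    """Cross-match test of two groups of points.

    ``points`` is an (n_units, n_features) array — in the E-M state-space
    use the default 2-D (mean E, mean M) coordinates — and ``labels`` holds
    exactly two distinct group labels.  Returns the cross-pair count A1,
    the matching, and the exact lower-tail p-value.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if points.shape[0] == 1:
        points = points.T
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise InvalidInputError(f"need exactly two groups, got {list(uniq)}")
    if min((labels == u).sum() for u in uniq) < 2:
        raise InvalidInputError("need >= 2 units per group")
    n = points.shape[0]
    if ids is None:
        ids = [f"u{i:04d}" for i in range(n)]
    ids = list(ids)

    dist = squareform(pdist(points, metric=metric))
    if dist.max() == 0:
        warnings.warn("all pairwise distances are zero; matching is arbitrary "
                      "up to the deterministic tie-break")

    phantom = n % 2 == 1
    if phantom:
        far = dist.max() * 2.0 + 1.0
        dist = np.pad(dist, ((0, 1), (0, 1)), constant_values=far)
        dist[-1, -1] = 0.0
        ids = ids + ["__phantom__"]

    pairs = min_weight_pairing(dist, ids)
    group1 = uniq[0]
    a1 = 0
    matching: list[tuple[str, str]] = []
    for i, j in pairs:
        if phantom and (i == n or j == n):
            continue  # drop the phantom's partner
        matching.append((ids[i], ids[j]))
        if labels[i] != labels[j]:
            a1 += 1
    n_eff = n - 1 if phantom else n
    if phantom:
        # group sizes after removing the phantom's real partner
        kept = {u for pair in matching for u in pair}
        n1_eff = int(sum(labels[k] == group1 for k in range(n) if ids[k] in kept))
    else:
        n1_eff = int((labels == group1).sum())
    p = crossmatch_null_pvalue(a1, n_eff, n1_eff)
    return CrossMatchResult(
        a1=a1, matching=matching, n_total=n_eff, n_group1=n1_eff, p=p
    )
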