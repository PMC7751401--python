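"""Independent brute-force oracles used to pin implementation semantics.

These deliberately take different computational routes from the package:
dense pairwise adjacency matrices + scipy csgraph, instead of the
sorted-sweep union-find and the greedy windowed matcher.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, maximum_bipartite_matching

from consensv.benchmark import MatchParams
from consensv.merge import MergeParams


def _codes(values):
    uniq = {v: i for i, v in enumerate(dict.fromkeys(values))}
    return np.array([uniq[v] for v in values])


def merge_components_oracle(calls, params: MergeParams) -> list[frozenset[int]]:
    """Connected components of the full pairwise merge graph.

    Builds the dense n x n adjacency from the merge predicate's
    definition (group identity + both breakpoint deltas within
    max_dist) and hands it to scipy's connected_components.
    """
    n = len(calls)
    if n == 0:
        return []
    group = []
    first = np.empty(n, dtype=np.int64)
    second = np.empty(n, dtype=np.int64)
    for i, c in enumerate(calls):
        t = c.svtype if params.require_type_match else ("BND" if c.svtype == "BND" else "SV")
        group.append((c.contig, t, c.mate_contig if c.svtype == "BND" else None))
        first[i] = c.pos
        second[i] = c.mate_pos if c.svtype == "BND" else c.end
    g = _codes(group)
    adj = (
        (g[:, None] == g[None, :])
        & (np.abs(first[:, None] - first[None, :]) <= params.max_dist)
        & (np.abs(second[:, None] - second[None, :]) <= params.max_dist)
    )
    _, labels = connected_components(csr_matrix(adj), directed=False)
    comps: dict[int, set[int]] = {}
    for i, lab in enumerate(labels):
        comps.setdefault(int(lab), set()).add(i)
    return [frozenset(s) for s in comps.values()]


def compat_matrix(candidates, truth_calls, params: MatchParams) -> np.ndarray:
    """Boolean candidate x truth compatibility under the match contract."""
    nc, nt = len(candidates), len(truth_calls)
    compat = np.zeros((nc, nt), dtype=bool)
    for i, c in enumerate(candidates):
        for j, t in enumerate(truth_calls):
            if c.contig != t.contig or c.svtype != t.svtype:
                continue
            if abs(c.pos - t.pos) > params.refdist or abs(c.end - t.end) > params.refdist:
                continue
            a, b = c.svlen, t.svlen
            ratio = 1.0 if a == b else (0.0 if 0 in (a, b) else min(a, b) / max(a, b))
            if ratio < params.pctsize:
                continue
            compat[i, j] = True
    return compat


def max_matching_size(candidates, truth_calls, params: MatchParams) -> int:
    """Size of the maximum bipartite matching of compatible pairs."""
    compat = compat_matrix(candidates, truth_calls, params)
    if not compat.any():
        return 0
    match = maximum_bipartite_matching(csr_matrix(compat), perm_type="column")
    return int((match >= 0).sum())
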