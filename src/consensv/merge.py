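"""Breakpoint-distance clustering of calls across callers.

Consensus candidates are the connected components (single linkage,
transitive) of the graph whose vertices are all input calls and whose
edges join pairs with both breakpoints within ``max_dist``.  A caller
contributing several calls to one component still counts once in the
support set.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from consensv.model import CallSet, ConsensusCall, SVCall


@dataclass(frozen=True)
class MergeParams:
    """Merging thresholds.

    max_dist: maximum distance in bp allowed between both start
        breakpoints and both end breakpoints of mergeable calls.
    require_type_match: only merge calls of identical SVTYPE.
    min_support: minimum number of distinct supporting callers for a
        consensus record to be emitted.
    """

    max_dist: int = 1000
    require_type_match: bool = True
    min_support: int = 1

    def __post_init__(self) -> None:
        if self.max_dist < 0:
            raise ValueError("max_dist must be >= 0")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


class SizeBin(str, Enum):
    """Size strata used by both calibration and benchmarking.

    Bounds are half-open: SMALL = [50, 300), MEDIUM = [300, 1000),
    LARGE = [1000, inf).  UNSIZED marks events that are not size
    stratified: breakends, and insertions (whose quality ruleset
    collapses all sizes into one category).
    """

    SMALL = "SMALL"
    MEDIUM = "MEDIUM"
    LARGE = "LARGE"
    UNSIZED = "UNSIZED"


SIZE_BOUNDS: dict[SizeBin, tuple[int, float]] = {
    SizeBin.SMALL: (50, 300),
    SizeBin.MEDIUM: (300, 1000),
    SizeBin.LARGE: (1000, float("inf")),
}


def size_bin(svlen: int, svtype: str) -> SizeBin:
    """Map an event to its size stratum; BND and INS are unstratified."""
    if svtype == "BND":
        return SizeBin.UNSIZED
    if svlen < 50:
        raise ValueError(f"svlen {svlen} below the 50 bp SV floor")
    if svtype == "INS":
        return SizeBin.UNSIZED
    for b, (lo, hi) in SIZE_BOUNDS.items():
        if lo <= svlen < hi:
            return b
    raise AssertionError("unreachable")


def mergeable(a: SVCall, b: SVCall, params: MergeParams) -> bool:
    """True iff ``a`` and ``b`` may describe the same event.

    Same contig, same SVTYPE when required, and both breakpoint pairs
    within ``max_dist``.  Breakends additionally require matching mate
    contigs and mate positions within ``max_dist``; a BND never merges
    with a non-BND call.
    """
    if a.contig != b.contig:
        return False
    if params.require_type_match and a.svtype != b.svtype:
        return False
    a_bnd, b_bnd = a.svtype == "BND", b.svtype == "BND"
    if a_bnd != b_bnd:
        return False
    if a_bnd:
        return (
            a.mate_contig == b.mate_contig
            and abs(a.pos - b.pos) <= params.max_dist
            and abs(a.mate_pos - b.mate_pos) <= params.max_dist
        )
    return abs(a.pos - b.pos) <= params.max_dist and abs(a.end - b.end) <= params.max_dist


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _lower_median(values: Sequence[int]) -> int:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def _component_consensus(members: list[SVCall]) -> ConsensusCall:
    members = sorted(members, key=lambda c: (c.contig, c.pos, c.end, c.caller))
    svtype = members[0].svtype
    pos = _lower_median([m.pos for m in members])
    genotype = next((m.genotype for m in members if m.genotype not in ("./.", ".|.")), None)
    common = dict(
        contig=members[0].contig,
        svtype=svtype,
        support=frozenset(m.caller for m in members),
        members=members,
        genotype=genotype,
    )
    if svtype == "BND":
        return ConsensusCall(
            pos=pos, end=pos, svlen=0,
            mate_contig=members[0].mate_contig,
            mate_pos=_lower_median([m.mate_pos for m in members]),
            **common,
        )
    if svtype == "INS":
        return ConsensusCall(pos=pos, end=pos, svlen=_lower_median([m.svlen for m in members]), **common)
    end = _lower_median([m.end for m in members])
    return ConsensusCall(pos=pos, end=max(end, pos), svlen=max(end, pos) - pos, **common)


def merge_callsets(callsets: Iterable[CallSet], params: MergeParams = MergeParams()) -> list[ConsensusCall]:
    """Cluster calls from several callers into consensus candidates.

    Components are found by a sorted sweep: within each (contig[, type])
    group, calls sorted by ``pos`` are compared only while start
    breakpoints are within ``max_dist``, which covers every edge of the
    merge graph.  Components with fewer than ``min_support`` distinct
    callers are discarded.  Output is sorted by (contig, pos).
    """
    callsets = list(callsets)
    if not callsets:
        return []
    samples = {cs.sample for cs in callsets}
    if len(samples) > 1:
        raise ValueError(f"cannot merge call sets from different samples: {sorted(samples)}")

    calls: list[SVCall] = [c for cs in callsets for c in cs.calls]
    if not calls:
        return []

    def group_key(c: SVCall):
        t = c.svtype if params.require_type_match else ("BND" if c.svtype == "BND" else "SV")
        return (c.contig, t, c.mate_contig if c.svtype == "BND" else None)

    uf = _UnionFind(len(calls))
    order = sorted(range(len(calls)), key=lambda i: (group_key(calls[i]), calls[i].pos))
    for a_idx in range(len(order)):
        i = order[a_idx]
        for b_idx in range(a_idx + 1, len(order)):
            j = order[b_idx]
            if group_key(calls[j]) != group_key(calls[i]):
                break
            if calls[j].pos - calls[i].pos > params.max_dist:
                break
            if mergeable(calls[i], calls[j], params):
                uf.union(i, j)

    components: dict[int, list[SVCall]] = {}
    for i, c in enumerate(calls):
        components.setdefault(uf.find(i), []).append(c)

    consensus = [_component_consensus(members) for members in components.values()]
    consensus = [c for c in consensus if len(c.support) >= params.min_support]
    consensus.sort(key=lambda c: (c.contig, c.pos, c.end, c.svtype))
    return consensus
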