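"""Truth-set matching and size-stratified precision/recall/F1 evaluation.

The matching contract mirrors the common SV benchmarking protocol: a
candidate and a truth record match when they share contig and type,
both breakpoints lie within ``refdist`` (default 2,000 bp), and their
sizes agree to at least ``pctsize`` (default 0.7).  Sequence similarity
is not used (the ``pctsim`` knob exists for interface parity and is
fixed at 0).  Assignment is greedy one-to-one with deterministic
tie-breaks; an oracle test bounds it against maximum bipartite matching.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from intervaltree import IntervalTree

from consensv.merge import SIZE_BOUNDS, MergeParams, SizeBin, merge_callsets
from consensv.model import CallSet, ConsensusCall, SVCall

CallLike = Union[SVCall, ConsensusCall]


@dataclass(frozen=True)
class MatchParams:
    """Candidate-truth matching thresholds.

    refdist: maximum breakpoint displacement in bp (both ends).
    pctsize: minimum size-similarity ratio min(a,b)/max(a,b).
    pctsim: sequence-similarity threshold; fixed 0 (disabled).
    passonly: consider only PASS/'.' records on both sides.
    include_bed: optional (contig, start, end) 0-based half-open
        high-confidence regions; records must lie fully inside one.
    size_min/size_max: optional half-open [size_min, size_max) stratum
        bounds applied to both sides before matching.
    """

    refdist: int = 2000
    pctsize: float = 0.7
    pctsim: float = 0.0
    passonly: bool = True
    include_bed: Optional[tuple[tuple[str, int, int], ...]] = None
    size_min: Optional[int] = None
    size_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.refdist < 0:
            raise ValueError("refdist must be >= 0")
        if not 0.0 <= self.pctsize <= 1.0:
            raise ValueError("pctsize must be in [0, 1]")


@dataclass
class BenchmarkReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    per_stratum: dict[SizeBin, "BenchmarkReport"] = field(default_factory=dict)
    #: (candidate index, truth index) pairs, indices into the inputs
    matched_pairs: list[tuple[int, int]] = field(default_factory=list)
    #: indices of candidates that passed the filters and were evaluated
    evaluated_candidates: list[int] = field(default_factory=list)


@dataclass
class ConcordanceReport:
    """Jaccard similarity between two call sets of the same sample."""

    n_a: int
    n_b: int
    matches: int
    jaccard: float
    qv_threshold: Optional[float] = None


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _size_ratio(a: int, b: int) -> float:
    if a == b:
        return 1.0
    if a == 0 or b == 0:
        return 0.0
    return min(a, b) / max(a, b)


def _truth_calls(truth: Union[CallSet, Sequence[CallLike]]) -> list[CallLike]:
    return list(truth.calls) if isinstance(truth, CallSet) else list(truth)


def _bed_trees(regions) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for contig, start, end in regions:
        trees.setdefault(contig, IntervalTree()).addi(start, end)
    return trees


def _inside_bed(call: CallLike, trees: dict[str, IntervalTree]) -> bool:
    tree = trees.get(call.contig)
    if tree is None:
        return False
    # VCF 1-based inclusive span -> 0-based half-open [pos-1, end)
    lo, hi = call.pos - 1, max(call.end, call.pos)
    return any(iv.begin <= lo and hi <= iv.end for iv in tree.overlap(lo, hi))


def _passes_filters(call: CallLike, params: MatchParams, trees) -> bool:
    if call.svtype == "BND":
        return False  # breakends are outside the truth protocol
    if params.passonly and not call.is_pass:
        return False
    if params.size_min is not None and call.svlen < params.size_min:
        return False
    if params.size_max is not None and call.svlen >= params.size_max:
        return False
    if trees is not None and not _inside_bed(call, trees):
        return False
    return True


def match_calls(
    candidates: Sequence[CallLike],
    truth: Union[CallSet, Sequence[CallLike]],
    params: MatchParams = MatchParams(),
    _stratify: bool = True,
) -> BenchmarkReport:
    """Label candidates TP/FP against a truth set and compute metrics.

    Candidates are processed in coordinate order; each takes its nearest
    compatible unmatched truth record, with distance |dpos| + |dend| and
    ties broken toward the lower truth pos.  Each record on either side
    is matched at most once.  The report carries per-stratum metrics for
    the SMALL/MEDIUM/LARGE size bins (computed by re-matching within the
    half-open stratum bounds, so stratified TP+FN tiles the totals).
    """
    candidates = list(candidates)
    truth_calls = _truth_calls(truth)
    trees = _bed_trees(params.include_bed) if params.include_bed else None

    cand_idx = [i for i, c in enumerate(candidates) if _passes_filters(c, params, trees)]
    truth_idx = [j for j, t in enumerate(truth_calls) if _passes_filters(t, params, trees)]

    # truth grouped by (contig, svtype) and sorted by pos for windowed lookup
    by_group: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for j in truth_idx:
        t = truth_calls[j]
        by_group.setdefault((t.contig, t.svtype), []).append((t.pos, j))
    for entries in by_group.values():
        entries.sort()

    matched_truth: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for i in sorted(cand_idx, key=lambda k: (candidates[k].contig, candidates[k].pos,
                                             candidates[k].end, candidates[k].svtype)):
        c = candidates[i]
        entries = by_group.get((c.contig, c.svtype))
        if not entries:
            continue
        positions = [p for p, _ in entries]
        lo = bisect_left(positions, c.pos - params.refdist)
        hi = bisect_right(positions, c.pos + params.refdist)
        best: Optional[tuple[int, int, int]] = None  # (distance, truth pos, truth idx)
        for pos_t, j in entries[lo:hi]:
            if j in matched_truth:
                continue
            t = truth_calls[j]
            if abs(c.end - t.end) > params.refdist:
                continue
            if _size_ratio(c.svlen, t.svlen) < params.pctsize:
                continue
            key = (abs(c.pos - t.pos) + abs(c.end - t.end), pos_t, j)
            if best is None or key < best:
                best = key
        if best is not None:
            matched_truth.add(best[2])
            pairs.append((i, best[2]))

    tp = len(pairs)
    fp = len(cand_idx) - tp
    fn = len(truth_idx) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    report = BenchmarkReport(
        tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall, f1=f1(precision, recall),
        matched_pairs=pairs, evaluated_candidates=cand_idx,
    )
    if _stratify and params.size_min is None and params.size_max is None:
        for sbin, (lo_b, hi_b) in SIZE_BOUNDS.items():
            sub = replace(params, size_min=lo_b, size_max=hi_b)
            report.per_stratum[sbin] = match_calls(candidates, truth_calls, sub, _stratify=False)
    return report


def combination_breakdown(
    consensus: Sequence[ConsensusCall],
    truth: Union[CallSet, Sequence[CallLike]],
    params: MatchParams = MatchParams(),
) -> pd.DataFrame:
    """Per-combination precision and recall contribution.

    One global one-to-one matching is computed, then calls are grouped
    by their exact support set.  ``pct_calls`` is each combination's
    share of the evaluated calls (sums to 100); ``recall_contribution``
    is the fraction of all truth records matched by calls with that
    support set.
    """
    consensus = list(consensus)
    report = match_calls(consensus, truth, params)
    matched = dict(report.matched_pairs)
    n_truth = report.tp + report.fn
    rows: dict[tuple[str, ...], dict] = {}
    for i in report.evaluated_candidates:
        combo = tuple(sorted(consensus[i].support))
        row = rows.setdefault(combo, {"n_calls": 0, "tp": 0})
        row["n_calls"] += 1
        row["tp"] += int(i in matched)
    total = sum(r["n_calls"] for r in rows.values())
    out = []
    for combo, row in sorted(rows.items()):
        out.append({
            "combination": ",".join(combo),
            "n_callers": len(combo),
            "n_calls": row["n_calls"],
            "pct_calls": 100.0 * row["n_calls"] / total if total else 0.0,
            "tp": row["tp"],
            "precision": row["tp"] / row["n_calls"] if row["n_calls"] else 0.0,
            "recall_contribution": row["tp"] / n_truth if n_truth else 0.0,
        })
    return pd.DataFrame(out, columns=["combination", "n_callers", "n_calls", "pct_calls",
                                      "tp", "precision", "recall_contribution"])


def concordance(
    a: Sequence[ConsensusCall],
    b: Sequence[ConsensusCall],
    params: MatchParams = MatchParams(),
    qv_threshold: Optional[float] = None,
) -> ConcordanceReport:
    """Jaccard concordance between two call sets of the same sample.

    With ``qv_threshold`` set, both sets are first filtered to calls
    with quality strictly greater than the threshold.  Matching treats
    ``b`` as the truth side; the Jaccard index is
    ``matches / (|a| + |b| - matches)`` over the evaluated records.
    """
    a, b = list(a), list(b)
    if qv_threshold is not None:
        a = [c for c in a if c.qv > qv_threshold]
        b = [c for c in b if c.qv > qv_threshold]
    report = match_calls(a, b, params, _stratify=False)
    n_a = len(report.evaluated_candidates)
    n_b = report.tp + report.fn
    m = report.tp
    union = n_a + n_b - m
    return ConcordanceReport(
        n_a=n_a, n_b=n_b, matches=m,
        jaccard=m / union if union else 1.0,
        qv_threshold=qv_threshold,
    )


def _allele_counts(genotype: Optional[str]) -> Optional[tuple[int, int]]:
    """(alt alleles, total called alleles) or None when fully missing."""
    if not genotype:
        return None
    alleles = [a for a in genotype.replace("|", "/").split("/") if a != "."]
    if not alleles:
        return None
    return sum(1 for a in alleles if a != "0"), len(alleles)


def population_af(
    per_sample: dict[str, Sequence[ConsensusCall]],
    params: MergeParams = MergeParams(),
) -> pd.DataFrame:
    """Cross-sample merge and allele-frequency table.

    Each sample's consensus calls are merged with the same single-linkage
    semantics used across callers.  The carrier count is the number of
    samples contributing at least one member.  Allele frequency uses the
    alternate-allele count over 2N when genotypes are present on the
    members, else carriers / N.
    """
    n_samples = len(per_sample)
    if n_samples == 0:
        raise ValueError("population_af requires at least one sample")
    callsets = []
    for sample, calls in per_sample.items():
        svcalls = [
            SVCall(
                contig=c.contig, pos=c.pos, end=c.end, svtype=c.svtype, svlen=c.svlen,
                caller=sample, qual=c.qv, genotype=c.genotype or "./.",
                mate_contig=c.mate_contig, mate_pos=c.mate_pos,
            )
            for c in calls
        ]
        callsets.append(CallSet(caller=sample, sample="population", calls=svcalls))
    merged = merge_callsets(callsets, params)
    rows = []
    for ev in merged:
        carriers = len(ev.support)
        gts = [_allele_counts(m.genotype) for m in ev.members]
        gts = [g for g in gts if g is not None]
        if gts:
            af = sum(alt for alt, _ in gts) / (2 * n_samples)
        else:
            af = carriers / n_samples
        rows.append({
            "contig": ev.contig, "pos": ev.pos, "end": ev.end,
            "svtype": ev.svtype, "svlen": ev.svlen,
            "carriers": carriers, "af": af,
        })
    df = pd.DataFrame(rows, columns=["contig", "pos", "end", "svtype", "svlen", "carriers", "af"])
    return df.sort_values(["contig", "pos"], kind="stable").reset_index(drop=True)
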