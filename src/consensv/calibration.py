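"""Phred quality calibration keyed by caller combination, type and size.

Each consensus call is labeled TP/FP against a truth set; calls are
grouped by (supporting-caller combination, SV type, size bin) and each
category's empirical precision is Phred-encoded as

    QV = min(40, -10 * log10(1 - precision))

Categories with fewer than three calls are dropped (too little evidence
to estimate a precision).  At assignment time, types missing from the
table (e.g. inversions, for which no truth data existed) fall back to
the deletion-trained entry for the same combination and size bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from consensv.benchmark import MatchParams, match_calls
from consensv.merge import SizeBin, size_bin
from consensv.model import CallSet, ConsensusCall

DEFAULT_QV_CAP = 40.0


@dataclass(frozen=True)
class CalibrationKey:
    combination: tuple[str, ...]  # sorted caller names
    svtype: str
    size_bin: SizeBin

    def __post_init__(self) -> None:
        if not self.combination:
            raise ValueError("empty caller combination")
        object.__setattr__(self, "combination", tuple(sorted(self.combination)))


@dataclass(frozen=True)
class CalibrationEntry:
    precision: float
    n_calls: int
    qv: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.precision <= 1.0:
            raise ValueError("precision outside [0, 1]")


@dataclass
class CalibrationTable:
    entries: dict[CalibrationKey, CalibrationEntry] = field(default_factory=dict)
    default_qv: float = 0.0
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, combination: Iterable[str], svtype: str, sbin: SizeBin) -> float:
        """Quality for a key, with the deletion-ruleset fallback chain.

        Exact key first; then the same combination and size bin with the
        type replaced by DEL (the deletion-trained ruleset applied to
        types lacking truth data); finally ``default_qv``.  Never fails.
        """
        key = CalibrationKey(tuple(combination), svtype, sbin)
        entry = self.entries.get(key)
        if entry is None and svtype != "DEL":
            entry = self.entries.get(CalibrationKey(key.combination, "DEL", sbin))
        return entry.qv if entry is not None else self.default_qv


def phred_quality(precision: float, cap: float = DEFAULT_QV_CAP) -> float:
    """Phred-encode a precision: ``min(cap, -10*log10(1 - precision))``.

    A precision of 1.0 maps to the cap (default 40); the result is
    rounded to 2 decimals.
    """
    if not 0.0 <= precision <= 1.0:
        raise ValueError(f"precision {precision} outside [0, 1]")
    if precision >= 1.0:
        return float(cap)
    return round(min(float(cap), max(0.0, -10.0 * math.log10(1.0 - precision))), 2)


def key_for_call(call: ConsensusCall) -> CalibrationKey:
    return CalibrationKey(tuple(sorted(call.support)), call.svtype,
                          size_bin(call.svlen, call.svtype))


def build_calibration_table(
    consensus: Sequence[ConsensusCall],
    truth: Union[CallSet, Sequence],
    match_params: MatchParams = MatchParams(),
    min_category_count: int = 3,
    cap: float = DEFAULT_QV_CAP,
    provenance: str = "",
) -> CalibrationTable:
    """Estimate per-category precision against a truth set.

    Only categories with at least ``min_category_count`` calls (default
    3, i.e. more than two) are retained; smaller categories carry too
    little evidence.
    """
    consensus = list(consensus)
    report = match_calls(consensus, truth, match_params)
    matched = dict(report.matched_pairs)
    groups: dict[CalibrationKey, list[bool]] = {}
    for i in report.evaluated_candidates:
        groups.setdefault(key_for_call(consensus[i]), []).append(i in matched)
    table = CalibrationTable(provenance=provenance)
    for key, labels in groups.items():
        n = len(labels)
        if n < min_category_count:
            continue
        precision = sum(labels) / n
        table.entries[key] = CalibrationEntry(precision=precision, n_calls=n,
                                              qv=phred_quality(precision, cap))
    if not consensus:
        import logging
        logging.getLogger(__name__).warning("no consensus calls: empty calibration table")
    return table


def assign_qualities(consensus: Sequence[ConsensusCall], table: CalibrationTable) -> list[ConsensusCall]:
    """Set each call's ``qv`` from the table (in place); returns the list."""
    for call in consensus:
        call.qv = table.lookup(call.support, call.svtype,
                               size_bin(call.svlen, call.svtype))
    return list(consensus)


def filter_by_quality(consensus: Iterable[ConsensusCall], threshold: float) -> list[ConsensusCall]:
    """Keep calls with quality strictly greater than ``threshold``."""
    return [c for c in consensus if c.qv > threshold]


# -- table serialization (TSV with '#' metadata lines) -----------------------

_COLUMNS = ("combination", "svtype", "size_bin", "n_calls", "precision", "qv")


def write_calibration_table(table: CalibrationTable, path: str) -> None:
    """Persist a table as TSV; '#' lines carry provenance and defaults.

    Precision is written with full float precision (repr) so the round
    trip is bit-exact.
    """
    with open(path, "w") as fh:
        if table.provenance:
            for line in table.provenance.splitlines():
                fh.write(f"# provenance: {line}\n")
        fh.write(f"# default_qv: {table.default_qv!r}\n")
        fh.write("#" + "\t".join(_COLUMNS) + "\n")
        for key in sorted(table.entries, key=lambda k: (k.combination, k.svtype, k.size_bin.value)):
            e = table.entries[key]
            fh.write("\t".join([
                ",".join(key.combination), key.svtype, key.size_bin.value,
                str(e.n_calls), repr(e.precision), f"{e.qv:.2f}",
            ]) + "\n")


def read_calibration_table(path: str) -> CalibrationTable:
    table = CalibrationTable()
    provenance: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("provenance:"):
                    provenance.append(body[len("provenance:"):].strip())
                elif body.startswith("default_qv:"):
                    table.default_qv = float(body[len("default_qv:"):].strip())
                continue
            combo, svtype, sbin, n_calls, precision, qv = line.split("\t")
            key = CalibrationKey(tuple(combo.split(",")), svtype, SizeBin(sbin))
            table.entries[key] = CalibrationEntry(
                precision=float(precision), n_calls=int(n_calls), qv=float(qv))
    table.provenance = "\n".join(provenance)
    return table
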