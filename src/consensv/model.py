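"""SV data model and VCF input/output.

Coordinates follow VCF conventions throughout: 1-based, inclusive start
(``pos``) and end (``end``).  Breakpoint distances are therefore plain
integer differences.  Event sizes (``svlen``) are stored as non-negative
integers; callers that emit signed deletion SVLEN values are normalized
at ingest.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pysam

logger = logging.getLogger(__name__)

SV_TYPES = ("DEL", "DUP", "INS", "INV", "BND")

#: events below this size are not structural variants and are dropped at ingest
DEFAULT_MIN_SIZE = 50

_BND_ALT = re.compile(r"[\[\]](?P<contig>[^:\[\]]+):(?P<pos>\d+)[\[\]]")


@dataclass(frozen=True)
class SVCall:
    """One normalized structural-variant record from a single caller.

    ``pos``/``end`` are the 1-based VCF breakpoints; for insertions
    ``end == pos`` and the event size lives entirely in ``svlen``.
    Breakend (BND) records carry the partner breakpoint in
    ``mate_contig``/``mate_pos`` and have ``svlen == 0``.
    """

    contig: str
    pos: int
    end: int
    svtype: str
    svlen: int
    caller: str
    qual: Optional[float] = None
    genotype: str = "./."
    filter: tuple[str, ...] = ("PASS",)
    mate_contig: Optional[str] = None
    mate_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SVTYPE {self.svtype!r}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.svlen < 0:
            raise ValueError("svlen must be non-negative")
        if self.svtype in ("DEL", "DUP", "INV") and self.end < self.pos:
            raise ValueError(f"end {self.end} < pos {self.pos} for {self.svtype}")
        if self.svtype == "INS" and self.end != self.pos:
            raise ValueError("insertions must have end == pos")
        if self.svtype == "BND" and (self.mate_contig is None or self.mate_pos is None):
            raise ValueError("BND records require mate coordinates")

    @property
    def is_pass(self) -> bool:
        return all(tok in ("PASS", ".") for tok in self.filter) or not self.filter


@dataclass
class CallSet:
    """All calls of one caller (or one sample) in coordinate order."""

    caller: str
    sample: str
    calls: list[SVCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = sorted(self.calls, key=_call_key)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)


@dataclass
class ConsensusCall:
    """A merged cluster of per-caller calls describing one SV event.

    ``support`` is the set of distinct callers contributing members;
    ``qv`` is the calibrated Phred quality in [0, 40] (0 until a
    calibration table has been applied).
    """

    contig: str
    pos: int
    end: int
    svtype: str
    svlen: int
    support: frozenset[str]
    members: list[SVCall] = field(default_factory=list)
    qv: float = 0.0
    genotype: Optional[str] = None
    mate_contig: Optional[str] = None
    mate_pos: Optional[int] = None

    def __post_init__(self) -> None:
        self.support = frozenset(self.support)
        if not self.support:
            raise ValueError("consensus call must have at least one supporting caller")
        if not 0.0 <= self.qv <= 40.0:
            raise ValueError(f"qv {self.qv} outside [0, 40]")
        for m in self.members:
            if m.caller not in self.support:
                raise ValueError(f"member caller {m.caller!r} missing from support set")

    @property
    def is_pass(self) -> bool:  # consensus records carry no FILTER
        return True


def _call_key(c) -> tuple:
    return (c.contig, c.pos, c.end, c.svtype)


def normalize_call(call: SVCall, min_size: int = 0) -> Optional[SVCall]:
    """Re-apply the ingest conventions to a call; idempotent.

    Returns ``None`` when the call falls below ``min_size``.
    """
    if call.svtype != "BND" and call.svlen < min_size:
        return None
    if call.svtype == "INS" and call.end != call.pos:
        return replace(call, end=call.pos)
    return call


def _svtype_from_alt(alt: str) -> Optional[str]:
    if alt.startswith("<") and alt.endswith(">"):
        token = alt[1:-1].split(":")[0].upper()
        if token in SV_TYPES:
            return token
        if token == "TRA":
            return "BND"
    if _BND_ALT.search(alt):
        return "BND"
    return None


def _scalar(value):
    if isinstance(value, (tuple, list)):
        return value[0] if value else None
    return value


def _parse_record(rec, alt: str, alt_index: int, caller: str, min_size: int) -> Optional[SVCall]:
    info = dict(rec.info)
    # the ALT carries the per-allele type in multi-allelic records
    svtype = _svtype_from_alt(alt)
    if svtype is None:
        svtype = str(info.get("SVTYPE", "")).upper() or None
        if svtype == "TRA":
            svtype = "BND"
        if svtype not in SV_TYPES:
            svtype = None
    if svtype is None:
        raise ValueError(f"no SVTYPE for record at {rec.contig}:{rec.pos}")

    pos = rec.pos
    svlen_info = info.get("SVLEN")
    if isinstance(svlen_info, (tuple, list)):
        svlen_info = svlen_info[alt_index] if alt_index < len(svlen_info) else svlen_info[0]
    svlen = abs(int(svlen_info)) if svlen_info is not None else None

    # pysam folds INFO/END into rec.stop; END is "present" whenever stop
    # differs from the reference-allele span.
    end_present = "END" in info or "CHR2" in info or rec.stop != rec.start + len(rec.ref or "N")
    end = int(info["END"]) if "END" in info else (rec.stop if end_present else None)

    mate_contig = mate_pos = None
    if svtype == "BND":
        m = _BND_ALT.search(alt)
        if m:
            mate_contig, mate_pos = m.group("contig"), int(m.group("pos"))
        elif "CHR2" in info and end is not None:  # Delly-style TRA
            mate_contig, mate_pos = str(_scalar(info["CHR2"])), int(end)
        if mate_contig is None:
            raise ValueError(f"BND record at {rec.contig}:{pos} lacks mate coordinates")
        # keep only the lexicographically smaller breakend as the anchor
        if (mate_contig, mate_pos) < (rec.contig, pos):
            return None
        end, svlen = pos, 0
    elif svtype == "INS":
        if svlen is None:
            raise ValueError(f"INS record at {rec.contig}:{pos} lacks SVLEN")
        end = pos
    else:  # DEL / DUP / INV
        if svlen is None and end is None:
            raise ValueError(f"record at {rec.contig}:{pos} lacks both SVLEN and END")
        if end is None:
            end = pos + svlen
        if svlen is None:
            svlen = end - pos

    filt = tuple(rec.filter.keys()) or (".",)
    genotype = "./."
    if rec.samples:
        sample = rec.samples[0]
        gt = sample.get("GT")
        if gt is not None and any(a is not None for a in gt):
            sep = "|" if sample.phased else "/"
            genotype = sep.join("." if a is None else str(a) for a in gt)

    call = SVCall(
        contig=rec.contig, pos=pos, end=max(end, pos) if svtype != "INS" else pos,
        svtype=svtype, svlen=svlen, caller=caller,
        qual=rec.qual, genotype=genotype, filter=filt,
        mate_contig=mate_contig, mate_pos=mate_pos,
    )
    return normalize_call(call, min_size=min_size)


def read_sv_vcf(path: str, caller: str, min_size: int = DEFAULT_MIN_SIZE) -> CallSet:
    """Read one caller's SV VCF into a normalized, sorted :class:`CallSet`.

    SVTYPE is taken from INFO, a symbolic ALT (``<DEL>`` ...) or BND ALT
    syntax; ``svlen`` from ``|SVLEN|`` when present, else ``END - POS``;
    ``END`` from INFO, else ``POS + |SVLEN|``.  Multi-allelic records are
    split per ALT.  Events shorter than ``min_size`` (default 50 bp, the
    conventional SV size floor) and malformed records are dropped with a
    warning counter; only an unreadable file is fatal.
    """
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read VCF {path}: {exc}") from exc

    sample = vcf.header.samples[0] if list(vcf.header.samples) else caller
    calls: list[SVCall] = []
    skipped = 0
    with vcf:
        for rec in vcf:
            alts = rec.alts or (".",)
            for i, alt in enumerate(alts):
                try:
                    call = _parse_record(rec, alt, i, caller, min_size)
                except (ValueError, KeyError, TypeError) as exc:
                    skipped += 1
                    logger.warning("skipping record %s:%s (%s)", rec.contig, rec.pos, exc)
                    continue
                if call is not None:
                    calls.append(call)
    if skipped:
        logger.warning("%s: skipped %d malformed record(s)", path, skipped)
    return CallSet(caller=caller, sample=sample, calls=calls)


def _consensus_header(contig_lengths: Mapping[str, int], sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_meta("source", "consensv")
    for name in sorted(contig_lengths):
        header.contigs.add(name, length=int(contig_lengths[name]))
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("END", 1, "Integer", "End position of the variant")
    header.info.add("SVLEN", 1, "Integer", "Length of the variant in bp")
    header.info.add("SUPP", 1, "Integer", "Number of distinct supporting callers")
    header.info.add("SUPP_CALLERS", ".", "String", "Sorted names of supporting callers")
    header.info.add("MATEPOS", 1, "String", "Mate breakend contig:pos for BND records")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample)
    return header


def write_consensus_vcf(
    calls: Iterable[ConsensusCall],
    path: str,
    contig_lengths: Mapping[str, int],
    sample: str = "SAMPLE",
) -> None:
    """Write consensus calls as VCF 4.2 with ``QUAL`` = calibrated quality.

    Each record carries SVTYPE/SVLEN/END plus SUPP (supporting-caller
    count) and SUPP_CALLERS (comma-joined sorted names).  Records are
    sorted by (contig, pos); a contig missing from ``contig_lengths`` is
    a fatal error naming the offending record.
    """
    calls = sorted(calls, key=lambda c: (c.contig, c.pos, c.end, c.svtype))
    for c in calls:
        if c.contig not in contig_lengths:
            raise ValueError(f"contig {c.contig!r} of record {c.contig}:{c.pos} {c.svtype} "
                             "missing from contig_lengths")
    header = _consensus_header(contig_lengths, sample)
    with pysam.VariantFile(path, "w", header=header) as out:
        for c in calls:
            if c.svtype == "BND":
                alt = f"N[{c.mate_contig}:{c.mate_pos}["
            else:
                alt = f"<{c.svtype}>"
            rec = out.new_record(
                contig=c.contig, start=c.pos - 1, stop=max(c.end, c.pos),
                alleles=("N", alt), qual=round(float(c.qv), 2),
            )
            rec.info["SVTYPE"] = c.svtype  # END is emitted from rec.stop
            rec.info["SVLEN"] = c.svlen
            rec.info["SUPP"] = len(c.support)
            rec.info["SUPP_CALLERS"] = tuple(sorted(c.support))
            if c.svtype == "BND":
                rec.info["MATEPOS"] = f"{c.mate_contig}:{c.mate_pos}"
            gt = c.genotype or "./."
            phased = "|" in gt
            alleles = tuple(None if a == "." else int(a) for a in re.split(r"[/|]", gt))
            rec.samples[sample]["GT"] = alleles
            rec.samples[sample].phased = phased
            out.write(rec)


def read_consensus_vcf(path: str) -> list[ConsensusCall]:
    """Read back a consensus VCF written by :func:`write_consensus_vcf`."""
    out: list[ConsensusCall] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            svtype = str(info["SVTYPE"])
            support = info.get("SUPP_CALLERS", ())
            if isinstance(support, str):
                support = (support,)
            mate_contig = mate_pos = None
            if svtype == "BND" and "MATEPOS" in info:
                mc, mp = str(_scalar(info["MATEPOS"])).rsplit(":", 1)
                mate_contig, mate_pos = mc, int(mp)
            genotype = None
            if rec.samples:
                sample = rec.samples[0]
                gt = sample.get("GT")
                if gt is not None and any(a is not None for a in gt):
                    sep = "|" if sample.phased else "/"
                    genotype = sep.join("." if a is None else str(a) for a in gt)
            end = int(info.get("END", rec.stop))
            out.append(ConsensusCall(
                contig=rec.contig, pos=rec.pos,
                end=rec.pos if svtype in ("INS", "BND") else end,
                svtype=svtype, svlen=int(info["SVLEN"]),
                support=frozenset(str(s) for s in support),
                qv=float(rec.qual) if rec.qual is not None else 0.0,
                genotype=genotype, mate_contig=mate_contig, mate_pos=mate_pos,
            ))
    return out


def write_callset_vcf(callset: CallSet, path: str, contig_lengths: Mapping[str, int]) -> None:
    """Write one caller's calls as a plain SV VCF (SVTYPE/SVLEN/END + GT)."""
    header = pysam.VariantHeader()
    header.add_meta("source", "consensv-simulate")
    for name in sorted(contig_lengths):
        header.contigs.add(name, length=int(contig_lengths[name]))
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("END", 1, "Integer", "End position of the variant")
    header.info.add("SVLEN", 1, "Integer", "Length of the variant in bp")
    header.formats.add("GT", 1, "String", "Genotype")
    for tok in sorted({t for c in callset.calls for t in c.filter} - {"PASS", "."}):
        header.filters.add(tok, None, None, "caller-assigned filter")
    header.add_sample(callset.sample)
    with pysam.VariantFile(path, "w", header=header) as out:
        for c in callset.calls:
            if c.contig not in contig_lengths:
                raise ValueError(f"contig {c.contig!r} missing from contig_lengths")
            alt = f"N[{c.mate_contig}:{c.mate_pos}[" if c.svtype == "BND" else f"<{c.svtype}>"
            rec = out.new_record(contig=c.contig, start=c.pos - 1,
                                 stop=max(c.end, c.pos), alleles=("N", alt), qual=c.qual)
            rec.info["SVTYPE"] = c.svtype  # END is emitted from rec.stop
            rec.info["SVLEN"] = c.svlen
            for tok in c.filter:
                if tok != ".":
                    rec.filter.add(tok)
            alleles = tuple(None if a == "." else int(a)
                            for a in re.split(r"[/|]", c.genotype or "./."))
            rec.samples[callset.sample]["GT"] = alleles
            rec.samples[callset.sample].phased = "|" in (c.genotype or "")
            out.write(rec)


def read_bed(path: str) -> list[tuple[str, int, int]]:
    """Read a 3-column BED file (0-based half-open intervals)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            regions.append((parts[0], int(parts[1]), int(parts[2])))
    return regions
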