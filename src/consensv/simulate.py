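"""Synthetic multi-caller SV ensembles with known ground truth.

The generator emulates the behaviour the consensus framework is built
around: several callers observing one sample's true SVs, each with its
own sensitivity per (type, size bin), breakpoint jitter, size error and
false-call rate.  Every simulated call carries a label (the truth SV id
it derives from, or ``FALSE``), so precision bookkeeping is exact and
does not depend on any matcher.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from consensv.merge import SizeBin, size_bin
from consensv.model import CallSet, SVCall

FALSE_LABEL = "FALSE"


@dataclass(frozen=True)
class CallerProfile:
    """Error model of one simulated caller.

    sensitivity: per-event detection probability; the default applies
        to every (svtype, size bin) not overridden in ``sensitivity_by``
        (keys are "SVTYPE:BIN", e.g. "DEL:SMALL").
    fp_per_mb: expected false calls per megabase of genome (Poisson).
    jitter_sd: standard deviation in bp of the rounded Gaussian noise
        applied independently to each breakpoint.
    size_error: relative standard deviation of the multiplicative size
        perturbation.
    """

    name: str
    sensitivity: float = 0.7
    sensitivity_by: dict = field(default_factory=dict)
    fp_per_mb: float = 0.5
    jitter_sd: float = 20.0
    size_error: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity must be in [0, 1]")
        if self.fp_per_mb < 0 or self.jitter_sd < 0 or self.size_error < 0:
            raise ValueError("error rates must be non-negative")

    def sensitivity_for(self, svtype: str, sbin: SizeBin) -> float:
        return float(self.sensitivity_by.get(f"{svtype}:{sbin.value}", self.sensitivity))


@dataclass
class SimulationConfig:
    """Genome layout, truth-SV distribution and caller error profiles.

    Defaults describe a 35x-WGS-like single-sample call set scaled to a
    20 Mb toy genome: a thousand true SVs dominated by deletions and
    insertions, log-uniform sizes from the 50 bp SV floor up to 100 kb,
    and a 2 kb exclusion buffer (twice the default merge distance) so
    distinct truth events never collide during merging.
    """

    contigs: dict[str, int] = field(default_factory=lambda: {"chr1": 12_000_000,
                                                             "chr2": 8_000_000})
    n_true: int = 1000
    type_mix: dict[str, float] = field(
        default_factory=lambda: {"DEL": 0.4, "INS": 0.4, "DUP": 0.1, "INV": 0.1})
    size_range: tuple[int, int] = (50, 100_000)
    exclusion_buffer: int = 2000
    het_fraction: float = 0.67
    profiles: dict[str, CallerProfile] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.type_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"type_mix must sum to 1, got {total}")
        if any(v < 0 for v in self.type_mix.values()):
            raise ValueError("type_mix probabilities must be non-negative")
        if any(l <= 0 for l in self.contigs.values()):
            raise ValueError("contig lengths must be positive")
        if self.size_range[0] < 50:
            raise ValueError("minimum simulated size is the 50 bp SV floor")


@dataclass
class SimulatedEnsemble:
    truth: CallSet
    callsets: dict[str, CallSet]
    #: per caller, one label per call (aligned with the sorted CallSet):
    #: a truth SV id ("sv<i>", index into truth.calls) or "FALSE"
    labels: dict[str, list[str]]


def caller_seed(master_seed: int, name: str) -> int:
    """Stable per-caller stream seed; adding a caller leaves others unchanged."""
    return (int(master_seed) + zlib.crc32(name.encode())) % 2**31


def _draw_event(rng: np.random.Generator, config: SimulationConfig,
                contig_names: list[str], weights: np.ndarray) -> tuple[str, int, int, str]:
    types = sorted(config.type_mix)
    probs = np.array([config.type_mix[t] for t in types])
    svtype = types[rng.choice(len(types), p=probs / probs.sum())]
    lo, hi = config.size_range
    svlen = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
    svlen = min(max(svlen, lo), hi)
    contig = contig_names[rng.choice(len(contig_names), p=weights)]
    span = 1 if svtype == "INS" else svlen
    limit = config.contigs[contig] - span
    if limit < 1:
        return contig, -1, svlen, svtype
    pos = int(rng.integers(1, limit + 1))
    return contig, pos, svlen, svtype


def simulate_truth(config: SimulationConfig) -> CallSet:
    """Draw the ground-truth SV set for one sample.

    Events are placed uniformly (contigs weighted by length) and kept
    disjoint within an ``exclusion_buffer`` margin, so no two truth SVs
    can be clustered together at the default merge distance.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    contig_names = sorted(config.contigs)
    lengths = np.array([config.contigs[c] for c in contig_names], dtype=float)
    weights = lengths / lengths.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_names}
    calls: list[SVCall] = []
    attempts, max_attempts = 0, max(1000, 200 * config.n_true)
    while len(calls) < config.n_true:
        attempts += 1
        if attempts > max_attempts:
            needed = config.n_true * (int(np.exp(np.mean(np.log(config.size_range))))
                                      + 2 * config.exclusion_buffer)
            raise RuntimeError(
                f"could not place {config.n_true} disjoint SVs on a "
                f"{int(lengths.sum())} bp genome; roughly {needed} bp are needed — "
                "enlarge the contigs or reduce n_true")
        contig, pos, svlen, svtype = _draw_event(rng, config, contig_names, weights)
        if pos < 1:
            continue
        end = pos if svtype == "INS" else pos + svlen
        lo, hi = pos - config.exclusion_buffer, end + config.exclusion_buffer
        if any(not (hi < s or e < lo) for s, e in placed[contig]):
            continue
        placed[contig].append((lo, hi))
        genotype = "0/1" if rng.random() < config.het_fraction else "1/1"
        calls.append(SVCall(contig=contig, pos=pos, end=end, svtype=svtype,
                            svlen=svlen, caller="truth", genotype=genotype))
    return CallSet(caller="truth", sample="simulated", calls=calls)


def _perturb(rng: np.random.Generator, t: SVCall, profile: CallerProfile,
             caller: str, min_size: int = 50) -> SVCall:
    dpos = int(round(rng.normal(0.0, profile.jitter_sd))) if profile.jitter_sd else 0
    pos = max(1, t.pos + dpos)
    scale = 1.0 + (rng.normal(0.0, profile.size_error) if profile.size_error else 0.0)
    svlen = max(min_size, int(round(t.svlen * scale)))
    if t.svtype == "INS":
        end = pos
    else:
        dend = int(round(rng.normal(0.0, profile.jitter_sd))) if profile.jitter_sd else 0
        end = max(pos + min_size, pos + svlen + dend)
        svlen = end - pos
    return SVCall(contig=t.contig, pos=pos, end=end, svtype=t.svtype, svlen=svlen,
                  caller=caller, qual=round(float(rng.uniform(20, 60)), 1),
                  genotype=t.genotype)


def simulate_caller_output(
    truth: CallSet,
    profile: CallerProfile,
    seed: int,
    config: Optional[SimulationConfig] = None,
) -> tuple[CallSet, list[str]]:
    """One caller's view of the truth: misses, jitter, and false calls.

    Each truth SV is detected independently with the profile's
    (type, size-bin) sensitivity; detections get jittered breakpoints
    and perturbed sizes.  False calls arrive as a Poisson process at
    ``fp_per_mb`` with sizes and types drawn like truth events.  Returns
    the sorted call set and a parallel list of labels (truth SV id or
    ``FALSE``).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    contig_names = sorted(set(config.contigs) | {c.contig for c in truth.calls})
    lengths = {c: config.contigs.get(c, max((t.end for t in truth.calls if t.contig == c),
                                            default=1_000_000)) for c in contig_names}
    pairs: list[tuple[SVCall, str]] = []
    for i, t in enumerate(truth.calls):
        p = profile.sensitivity_for(t.svtype, size_bin(t.svlen, t.svtype))
        if rng.random() < p:
            pairs.append((_perturb(rng, t, profile, profile.name), f"sv{i}"))
    genome_mb = sum(lengths.values()) / 1e6
    n_false = int(rng.poisson(profile.fp_per_mb * genome_mb))
    names = sorted(lengths)
    lens = np.array([lengths[c] for c in names], dtype=float)
    weights = lens / lens.sum()
    fp_config = SimulationConfig(contigs=dict(lengths), n_true=0,
                                 type_mix=dict(config.type_mix),
                                 size_range=config.size_range,
                                 profiles={}, seed=0)
    made = 0
    while made < n_false:
        contig, pos, svlen, svtype = _draw_event(rng, fp_config, names, weights)
        if pos < 1:
            continue
        end = pos if svtype == "INS" else pos + svlen
        genotype = "0/1" if rng.random() < config.het_fraction else "1/1"
        pairs.append((SVCall(contig=contig, pos=pos, end=end, svtype=svtype, svlen=svlen,
                             caller=profile.name,
                             qual=round(float(rng.uniform(20, 60)), 1),
                             genotype=genotype), FALSE_LABEL))
        made += 1
    pairs.sort(key=lambda p: (p[0].contig, p[0].pos, p[0].end, p[0].svtype))
    callset = CallSet(caller=profile.name, sample=truth.sample,
                      calls=[c for c, _ in pairs])
    return callset, [label for _, label in pairs]


def simulate_ensemble(config: SimulationConfig) -> SimulatedEnsemble:
    """Truth plus one labeled call set per configured caller.

    Per-caller randomness uses seeds derived from the master seed and a
    stable hash of the caller name, so runs are end-to-end deterministic
    and adding a caller does not perturb the others' streams.
    """
    if not config.profiles:
        raise ValueError("simulate_ensemble requires at least one caller profile")
    truth = simulate_truth(config)
    callsets: dict[str, CallSet] = {}
    labels: dict[str, list[str]] = {}
    for name in sorted(config.profiles):
        cs, lab = simulate_caller_output(truth, config.profiles[name],
                                         caller_seed(config.seed, name), config)
        callsets[name] = cs
        labels[name] = lab
    return SimulatedEnsemble(truth=truth, callsets=callsets, labels=labels)


def load_config(path: str) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML file.

    Schema: ``contigs`` (name -> bp), ``n_true``, ``type_mix``,
    ``size_range`` ([lo, hi]), ``exclusion_buffer``, ``seed`` and
    ``callers`` (name -> profile fields as in :class:`CallerProfile`).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    profiles = {
        name: CallerProfile(name=name, **(spec or {}))
        for name, spec in (raw.pop("callers", {}) or {}).items()
    }
    if "size_range" in raw:
        raw["size_range"] = tuple(raw["size_range"])
    return SimulationConfig(profiles=profiles, **raw)
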