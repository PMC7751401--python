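import numpy as np
import pytest

from consensv.model import CallSet, ConsensusCall, SVCall
from consensv.simulate import CallerProfile, SimulationConfig, simulate_ensemble

SV_TYPES_SIZED = ("DEL", "DUP", "INS", "INV")


def random_svcall(rng: np.random.Generator, callers=("A", "B", "C"),
                  contigs=("chr1", "chr2"), span=200_000, max_size=5000,
                  types=SV_TYPES_SIZED + ("BND",)) -> SVCall:
    svtype = types[rng.integers(len(types))]
    contig = contigs[rng.integers(len(contigs))]
    pos = int(rng.integers(1, span))
    svlen = int(rng.integers(50, max_size))
    kwargs = dict(contig=contig, pos=pos, svtype=svtype,
                  caller=callers[rng.integers(len(callers))])
    if svtype == "BND":
        return SVCall(end=pos, svlen=0,
                      mate_contig=contigs[rng.integers(len(contigs))],
                      mate_pos=int(rng.integers(1, span)), **kwargs)
    if svtype == "INS":
        return SVCall(end=pos, svlen=svlen, **kwargs)
    return SVCall(end=pos + svlen, svlen=svlen, **kwargs)


def random_calls(rng: np.random.Generator, n: int, **kwargs) -> list[SVCall]:
    return [random_svcall(rng, **kwargs) for _ in range(n)]


def random_consensus(rng: np.random.Generator, n: int,
                     callers=("manta", "delly", "lumpy")) -> list[ConsensusCall]:
    out = []
    for _ in range(n):
        base = random_svcall(rng, callers=callers)
        support = frozenset(
            np.random.default_rng(rng.integers(2**31)).choice(
                callers, size=int(rng.integers(1, len(callers) + 1)), replace=False))
        out.append(ConsensusCall(
            contig=base.contig, pos=base.pos, end=base.end, svtype=base.svtype,
            svlen=base.svlen, support=support, qv=float(np.round(rng.uniform(0, 40), 2)),
            genotype="0/1" if rng.random() < 0.5 else None,
            mate_contig=base.mate_contig, mate_pos=base.mate_pos))
    return out


def standard_profiles(jitter: bool = True) -> dict[str, CallerProfile]:
    """Five caller error profiles shaped like the usual short-read ensemble:
    a precise low-recall breakpoint caller, two split-read callers, a
    read-pair caller, and a noisy read-depth caller blind to insertions
    and to events below its bin resolution."""
    j = 1.0 if jitter else 0.0
    return {
        "breakseq": CallerProfile("breakseq", sensitivity=0.15, fp_per_mb=0.05,
                                  jitter_sd=2 * j, size_error=0.01 * j),
        "manta": CallerProfile("manta", sensitivity=0.75, fp_per_mb=0.2,
                               jitter_sd=5 * j, size_error=0.02 * j),
        "delly": CallerProfile("delly", sensitivity=0.55, fp_per_mb=0.5,
                               jitter_sd=10 * j, size_error=0.03 * j),
        "lumpy": CallerProfile("lumpy", sensitivity=0.50, fp_per_mb=0.8,
                               jitter_sd=15 * j, size_error=0.03 * j),
        "cnvnator": CallerProfile("cnvnator", sensitivity=0.35, fp_per_mb=2.0,
                                  jitter_sd=80 * j, size_error=0.10 * j,
                                  sensitivity_by={"INS:UNSIZED": 0.0,
                                                  "DEL:SMALL": 0.0,
                                                  "DUP:SMALL": 0.0,
                                                  "INV:SMALL": 0.0}),
    }


@pytest.fixture(scope="session")
def small_ensemble():
    """A 300-truth-SV, 3-caller ensemble with realistic jitter."""
    profiles = {k: v for k, v in standard_profiles().items()
                if k in ("manta", "delly", "cnvnator")}
    config = SimulationConfig(contigs={"chr1": 12_000_000, "chr2": 8_000_000},
                              n_true=300, profiles=profiles, seed=20229)
    return config, simulate_ensemble(config)


@pytest.fixture(scope="session")
def recovery_ensemble():
    """The calibration-recovery experiment: 5 callers, 2,000 truth SVs,
    exact breakpoints (jitter and size error off) so that each caller
    combination's precision is fixed by the configured sensitivities and
    false-call rates alone."""
    config = SimulationConfig(
        contigs={"chr1": 25_000_000, "chr2": 20_000_000, "chr3": 15_000_000},
        n_true=2000, profiles=standard_profiles(jitter=False), seed=4101)
    return config, simulate_ensemble(config)
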