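"""Matching contract, metrics, combination breakdowns and concordance."""

import numpy as np
import pytest

from consensv.benchmark import (MatchParams, combination_breakdown, concordance, f1,
                                match_calls, population_af)
from consensv.calibration import assign_qualities, build_calibration_table
from consensv.merge import MergeParams, SizeBin, merge_callsets
from consensv.model import CallSet, ConsensusCall, SVCall
from consensv.simulate import (CallerProfile, SimulationConfig, simulate_caller_output,
                               simulate_truth)
from oracles import compat_matrix, max_matching_size


def _cand(pos, end, svtype="DEL", contig="chr1", support=("manta",), qv=0.0):
    return ConsensusCall(contig=contig, pos=pos, end=pos if svtype == "INS" else end,
                         svtype=svtype, svlen=end - pos if svtype != "INS" else end - pos,
                         support=frozenset(support), qv=qv)


def _truth_set(records):
    calls = []
    for rec in records:
        contig, p, e, t = rec if len(rec) == 4 else (("chr1",) + rec)
        calls.append(SVCall(contig=contig, pos=p, end=p if t == "INS" else e,
                            svtype=t, svlen=e - p, caller="truth"))
    return CallSet(caller="truth", sample="s", calls=calls)


class TestF1:
    def test_harmonic_mean_of_equals(self):
        assert f1(0.75, 0.75) == pytest.approx(0.75)

    def test_zero_edge(self):
        assert f1(0.0, 0.0) == 0.0

    def test_between_harmonic_bounds(self):
        rng = np.random.default_rng(2)
        for p, r in rng.uniform(0.01, 1.0, size=(200, 2)):
            v = f1(p, r)
            assert min(p, r) >= 0 and min(p, r) <= v <= max(p, r)


class TestMatchCalls:
    def test_within_refdist_matches(self):
        cands = [_cand(5000, 5500)]
        truth = _truth_set([(6500, 7000, "DEL")])
        rep = match_calls(cands, truth, MatchParams(passonly=False))
        assert rep.tp == 1 and rep.fp == 0 and rep.fn == 0

    def test_type_mismatch_never_matches(self):
        cands = [_cand(5000, 5500)]
        truth = _truth_set([(5000, 5500, "INV")])
        rep = match_calls(cands, truth, MatchParams(passonly=False))
        assert rep.tp == 0 and rep.fp == 1 and rep.fn == 1

    def test_size_ratio_gate(self):
        cands = [_cand(5000, 5100)]  # size 100 vs truth 500 -> ratio 0.2
        truth = _truth_set([(5000, 5500, "DEL")])
        rep = match_calls(cands, truth, MatchParams(passonly=False, pctsize=0.7))
        assert rep.tp == 0
        rep = match_calls(cands, truth, MatchParams(passonly=False, pctsize=0.2))
        assert rep.tp == 1

    def test_one_to_one_assignment(self):
        # two candidates, one truth: only one may claim it
        cands = [_cand(5000, 5500), _cand(5050, 5550)]
        truth = _truth_set([(5000, 5500, "DEL")])
        rep = match_calls(cands, truth, MatchParams(passonly=False))
        assert (rep.tp, rep.fp, rep.fn) == (1, 1, 0)

    def test_nearest_first_tie_to_lower_truth_pos(self):
        cands = [_cand(5000, 5500)]
        truth = _truth_set([(4000, 4500, "DEL"), (6000, 6500, "DEL")])
        rep = match_calls(cands, truth, MatchParams(passonly=False))
        assert rep.matched_pairs == [(0, 0)]

    def test_passonly_drops_filtered_records(self):
        lowq = SVCall(contig="chr1", pos=5000, end=5500, svtype="DEL", svlen=500,
                      caller="manta", filter=("LowQual",))
        truth = _truth_set([(5000, 5500, "DEL")])
        rep = match_calls([lowq], truth, MatchParams(passonly=True))
        assert rep.evaluated_candidates == [] and rep.fn == 1
        rep = match_calls([lowq], truth, MatchParams(passonly=False))
        assert rep.tp == 1

    def test_bnd_excluded_from_metrics(self):
        bnd = ConsensusCall(contig="chr1", pos=100, end=100, svtype="BND", svlen=0,
                            support=frozenset({"manta"}), mate_contig="chr2", mate_pos=5)
        rep = match_calls([bnd], _truth_set([(5000, 5500, "DEL")]),
                          MatchParams(passonly=False))
        assert rep.evaluated_candidates == [] and rep.fp == 0

    def test_include_bed_restricts_both_sides(self):
        cands = [_cand(5000, 5500), _cand(50_000, 50_500)]
        truth = _truth_set([(5000, 5500, "DEL"), (50_000, 50_500, "DEL")])
        params = MatchParams(passonly=False, include_bed=(("chr1", 4000, 6000),))
        rep = match_calls(cands, truth, params)
        assert (rep.tp, rep.fp, rep.fn) == (1, 0, 0)

    def test_stratified_counts_tile_totals(self, small_ensemble):
        config, ens = small_ensemble
        consensus = merge_callsets(ens.callsets.values())
        rep = match_calls(consensus, ens.truth, MatchParams(passonly=False))
        strata = rep.per_stratum.values()
        assert sum(r.tp + r.fn for r in strata) == rep.tp + rep.fn
        assert sum(r.tp + r.fp for r in strata) == rep.tp + rep.fp

    def test_empty_truth_all_fp(self):
        cands = [_cand(5000, 5500)]
        rep = match_calls(cands, _truth_set([]), MatchParams(passonly=False))
        assert (rep.tp, rep.fp, rep.fn) == (0, 1, 0)


class TestGreedyVsOptimal:
    @pytest.mark.parametrize("seed", range(25))
    def test_never_exceeds_and_within_one_of_optimal(self, seed):
        config = SimulationConfig(contigs={"chr1": 2_000_000}, n_true=12,
                                  profiles={}, seed=seed)
        truth = simulate_truth(config)
        profile = CallerProfile("c", sensitivity=0.7, fp_per_mb=2.0, jitter_sd=150,
                                size_error=0.1)
        calls, _ = simulate_caller_output(truth, profile, seed + 10_000, config)
        params = MatchParams(passonly=False)
        cands = [c for c in calls.calls]
        rep = match_calls(cands, truth, params, _stratify=False)
        opt = max_matching_size([cands[i] for i in rep.evaluated_candidates],
                                [t for t in truth.calls], params)
        assert opt - 1 <= rep.tp <= opt

    def test_exact_on_unique_compatibility_instances(self):
        for seed in range(15):
            config = SimulationConfig(contigs={"chr1": 3_000_000}, n_true=10,
                                      exclusion_buffer=5000, profiles={}, seed=seed)
            truth = simulate_truth(config)
            profile = CallerProfile("c", sensitivity=0.8, fp_per_mb=1.0, jitter_sd=10,
                                    size_error=0.02)
            calls, _ = simulate_caller_output(truth, profile, seed + 99, config)
            params = MatchParams(passonly=False)
            cands = [c for c in calls.calls if c.svtype != "BND"]
            compat = compat_matrix(cands, list(truth.calls), params)
            assert compat.sum(axis=1).max(initial=0) <= 1  # unique by construction
            rep = match_calls(cands, truth, params, _stratify=False)
            assert rep.tp == max_matching_size(cands, list(truth.calls), params)


class TestCombinationBreakdown:
    def test_single_combination_half_true(self):
        truth = _truth_set([(i * 10_000, i * 10_000 + 200, "DEL") for i in range(1, 6)])
        cands = [_cand(i * 10_000, i * 10_000 + 200) for i in range(1, 6)]
        cands += [_cand(i * 10_000 + 5000, i * 10_000 + 5200) for i in range(50, 55)]
        df = combination_breakdown(cands, truth, MatchParams(passonly=False))
        assert len(df) == 1
        assert df.iloc[0]["precision"] == pytest.approx(0.5)

    def test_percentages_sum_to_100(self, small_ensemble):
        config, ens = small_ensemble
        consensus = merge_callsets(ens.callsets.values())
        df = combination_breakdown(consensus, ens.truth, MatchParams(passonly=False))
        assert df["pct_calls"].sum() == pytest.approx(100.0)
        evaluated = [c for c in consensus if c.svtype != "BND"]
        assert df["n_calls"].sum() == len(evaluated)

    def test_error_free_multicaller_combinations_are_precise(self):
        # calls supported by >=2 callers drawn straight from truth records
        truth = _truth_set([(i * 10_000, i * 10_000 + 500, "DEL") for i in range(1, 21)])
        cands = [_cand(t.pos, t.end, support=("manta", "delly")) for t in truth.calls[:10]]
        cands += [_cand(900_000 + i * 10_000, 900_000 + i * 10_000 + 500,
                        support=("cnvnator",)) for i in range(8)]
        df = combination_breakdown(cands, truth, MatchParams(passonly=False))
        by_combo = df.set_index("combination")
        assert by_combo.loc["delly,manta", "precision"] == 1.0
        assert by_combo.loc["cnvnator", "precision"] == 0.0


class TestConcordance:
    def test_identical_sets(self):
        calls = [_cand(i * 10_000, i * 10_000 + 300) for i in range(1, 10)]
        rep = concordance(calls, list(calls))
        assert rep.jaccard == 1.0

    def test_disjoint_sets(self):
        a = [_cand(i * 50_000, i * 50_000 + 300) for i in range(1, 6)]
        b = [_cand(i * 50_000 + 20_000, i * 50_000 + 20_300) for i in range(1, 6)]
        rep = concordance(a, b, MatchParams(refdist=1000))
        assert rep.jaccard == 0.0

    def test_quality_filter_removes_private_noise(self):
        shared = [_cand(i * 10_000, i * 10_000 + 300, qv=30.0) for i in range(1, 30)]
        noise_a = [_cand(i * 10_000 + 4000, i * 10_000 + 4300, qv=1.0) for i in range(30, 45)]
        noise_b = [_cand(i * 10_000 + 4000, i * 10_000 + 4300, qv=1.0) for i in range(50, 65)]
        raw = concordance(shared + noise_a, shared + noise_b)
        filt = concordance(shared + noise_a, shared + noise_b, qv_threshold=3.0)
        assert filt.jaccard > raw.jaccard
        assert filt.jaccard == 1.0


class TestPopulationAF:
    def test_single_carrier_without_genotypes(self):
        per_sample = {f"s{i}": [] for i in range(100)}
        per_sample["s0"] = [_cand(10_000, 10_500)]
        df = population_af(per_sample)
        assert len(df) == 1
        assert df.iloc[0]["af"] == pytest.approx(0.01)
        assert df.iloc[0]["carriers"] == 1

    def test_fixed_homozygous_variant(self):
        per_sample = {}
        for i in range(10):
            call = _cand(10_000, 10_500)
            call.genotype = "1/1"
            per_sample[f"s{i}"] = [call]
        df = population_af(per_sample)
        assert df.iloc[0]["af"] == pytest.approx(1.0)
        assert df.iloc[0]["carriers"] == 10

    def test_rare_heavy_spectrum_decreases(self):
        # geometric carrier counts: each SV present in k samples, P(k) ~ (1/2)^k
        rng = np.random.default_rng(23)
        n_samples, n_svs = 40, 300
        per_sample = {f"s{i}": [] for i in range(n_samples)}
        for j in range(n_svs):
            k = min(int(rng.geometric(0.5)), n_samples)
            carriers = rng.choice(n_samples, size=k, replace=False)
            for i in carriers:
                per_sample[f"s{i}"].append(_cand(100_000 * (j + 1), 100_000 * (j + 1) + 400))
        df = population_af(per_sample)
        hist, _ = np.histogram(df["af"], bins=[0, 0.05, 0.1, 0.2, 0.4, 1.0])
        assert list(hist) == sorted(hist, reverse=True)
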