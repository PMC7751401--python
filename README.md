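# consensv

Ensemble consensus calling for structural variants (SVs), with
precision-calibrated Phred quality values and a size-stratified
benchmarking protocol.

Short-read SV callers disagree: split-read, read-pair, read-depth and
breakpoint-library methods each see a different slice of the true
variation, with very different false-discovery rates across SV types
and size regimes. A practical remedy is to run several callers on the
same sample, cluster their calls into consensus events, and score each
event by how reliable its particular *combination of supporting
callers* has historically been for that event type and size. `consensv`
implements that computational core for anyone building or evaluating a
multi-caller SV workflow:

- **merge** — calls from different callers are clustered by breakpoint
  distance (single-linkage over pairs whose start and end breakpoints
  both lie within `max_dist`, default 1,000 bp, same contig and SVTYPE);
  each cluster becomes one consensus event with lower-median
  representative breakpoints and a support set of distinct callers.
- **calibrate** — consensus events are labeled TP/FP against a truth
  set and grouped by (caller combination, SV type, size bin), where the
  bins are 50–300 bp, 300–1,000 bp and >1 kb; each category with more
  than two calls gets an empirical precision and the Phred-encoded
  quality

  `QV = min(40, -10 * log10(1 - precision))`

  so `QUAL` in the output VCF directly encodes the expected
  false-discovery rate of the event's category.
- **evaluate / combos / concordance / popaf** — truth matching in the
  style of the standard SV comparison protocol (breakpoints within
  `refdist` = 2,000 bp, size ratio ≥ 0.7, no sequence similarity,
  one-to-one greedy assignment), reported overall and per size stratum;
  per-combination precision breakdowns; Jaccard concordance between
  replicates before/after quality filtering; and cross-sample merging
  with allele frequencies.
- **simulate** — a synthetic-ensemble generator (ground-truth SVs plus
  per-caller outputs with configurable sensitivity per type and size
  bin, breakpoint jitter, size error and false-call rate) so the whole
  pipeline is testable without any external data.

Inputs are ordinary single-sample SV VCFs (symbolic ALTs or
SVTYPE/SVLEN/END INFO fields, breakend notation for translocations);
events shorter than 50 bp are not SVs and are dropped at ingest.

## Worked example

Simulate a three-caller ensemble over a 20 Mb toy genome (400 true SVs;
a precise split-read caller, a mid-tier read-pair caller, and a noisy
read-depth caller that is blind to insertions and small events), then
merge, calibrate, and filter:

```sh
consensv simulate --sim-config sim.yaml -o sim
consensv merge manta=sim/manta.vcf delly=sim/delly.vcf cnvnator=sim/cnvnator.vcf \
    -o consensus.vcf
consensv calibrate consensus.vcf sim/truth.vcf -o qv_table.tsv --no-passonly
consensv qualify consensus.vcf qv_table.tsv -o qualified.vcf --threshold 3
consensv evaluate consensus.vcf sim/truth.vcf --no-passonly
consensv evaluate qualified.vcf sim/truth.vcf --no-passonly
```

The calibration table is a TSV keyed by combination, type and size bin
— the read-depth caller's solo calls earn low qualities:

```
#combination	svtype	size_bin	n_calls	precision	qv
cnvnator	DEL	LARGE	21	0.3333333333333333	1.76
cnvnator	DUP	LARGE	10	0.1	0.46
cnvnator	INS	UNSIZED	16	0.0	0.00
```

Evaluating the raw consensus against the simulated truth:

```
stratum	tp	fp	fn	precision	recall	f1
ALL	350	81	50	0.8121	0.8750	0.8424
```

and after keeping only events with QV > 3:

```
stratum	tp	fp	fn	precision	recall	f1
ALL	316	16	84	0.9518	0.7900	0.8634
```

Filtering on the calibrated quality removes 65 of the 81 false calls at
the cost of 34 true events: precision rises from 0.81 to 0.95 and the
F1 score improves — the trade-off knob the quality values exist to
provide. Every command is also available as a library function
(`merge_callsets`, `build_calibration_table`, `assign_qualities`,
`match_calls`, `concordance`, `population_af`, `simulate_ensemble`).

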