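# Methods

## Data model and coordinates

All records use VCF conventions: 1-based inclusive `pos` and `end`, so
breakpoint distances are plain integer differences and no coordinate
conversion ever happens internally. Event sizes are non-negative
(`|SVLEN|`); insertions satisfy `end == pos` with the size carried in
`svlen`; breakends (BND) carry an explicit mate breakpoint and have
size 0. At ingest, `svlen` is taken from `|SVLEN|` when present and
otherwise from `END − POS`; `END` is taken from INFO and otherwise
reconstructed as `POS + |SVLEN|`. When a record carries both and they
disagree, both are stored as given — no caller-specific reconciliation
rule is assumed. Translocation records (BND ALT syntax or
Delly-style `SVTYPE=TRA` with `CHR2`/`END`) are normalized to BND, and
only the lexicographically smaller breakend of a pair is kept as the
record anchor so a rearrangement is counted once. Records below 50 bp
are dropped at ingest (configurable): events of at least 50 bp are
what the SV definition covers, and the benchmarking protocol assumes
the same floor.

## Merging

Consensus candidates are the connected components of the graph whose
vertices are all input calls and whose edges join pairs on the same
contig, of the same SVTYPE (unless type matching is disabled), with
both the start–start and end–end breakpoint distances within
`max_dist`. BND pairs additionally require equal mate contigs and mate
positions within `max_dist`, and a BND never merges with a sized call.
Single-linkage (transitive) clustering is deliberate: it is the
semantics of the standard SV merging tools this stage emulates, and it
subsumes intra-caller duplicate collapsing and cross-caller merging in
one pass. The implementation is a sorted sweep with union–find —
within each (contig, type) group, only pairs whose start breakpoints
are within `max_dist` are examined, which covers every possible edge —
and the test suite pins it against an independent dense-adjacency +
`scipy` connected-components oracle.

Representative breakpoints are the lower median of the member
coordinates (lower, so a representative is always an observed member
coordinate even for even-sized clusters); `svlen` is recomputed from
the representatives, except for insertions where it is the lower
median of member sizes. A caller contributing several calls to one
component counts once in the support set. `max_dist` defaults to
1,000 bp — the common default of the merging tools in this space; the
original pipeline's exact setting is not published — and is exposed on
the command line. `min_support` defaults to 1 so that single-caller
events survive to be down-weighted by calibration rather than
discarded.

## Size bins

Calibration and benchmarking share half-open strata: SMALL = [50, 300),
MEDIUM = [300, 1000), LARGE = [1000, ∞). The prose convention
"50–300, 300–1,000, >1 kb" double-books the boundary values; half-open
intervals are the unambiguous resolution, and because both modules use
the same bins, per-stratum TP+FN counts tile the unstratified totals
exactly. Breakends are UNSIZED. Insertions are also mapped to UNSIZED:
the quality ruleset stratifies by size for deletions only, so
insertions form a single collapsed category per caller combination.

## Quality calibration

Consensus calls are labeled TP/FP against a truth set with the
matching contract below, grouped by (caller combination, SVTYPE, size
bin), and each category's empirical precision is Phred-encoded:
`QV = min(40, −10·log10(1 − precision))`, capped at 40 (a perfect
category would otherwise be infinite) and rounded to two decimals. QV
is a real number, not an integer — VCF QUAL permits floats, and the
conventional filtering threshold "QV > 3" (precision ≈ 0.5) needs the
granularity. Categories with fewer than three calls are dropped: two
observations cannot support a precision estimate (`min_category_count`
is configurable).

At assignment time the lookup never fails: exact key first; then the
same combination and size bin with the type replaced by DEL — the
deletion-trained ruleset applied to types for which no truth data
exists, e.g. inversions; finally `default_qv` (0), so never-seen
combinations sort last. Quality filtering keeps calls with QV
*strictly* greater than the threshold.

The package ships no pre-built table: truth-derived quality values are
a property of the truth set and sequencing context, so tables are
built per project (`consensv calibrate`) and persisted as TSV with the
provenance recorded in `#` header lines. Precision is serialized at
full float precision so the round trip is bit-exact.

## Benchmarking

A candidate and a truth record are compatible when they share contig
and SVTYPE, both breakpoint displacements are within `refdist`
(default 2,000 bp) and the size ratio `min/max` is at least `pctsize`
(default 0.7 — the published default of the standard comparison tool;
the protocol this mirrors fixes only the 2,000 bp distance and
disables sequence similarity). Assignment is greedy one-to-one:
candidates in coordinate order each take the nearest compatible
unmatched truth record, with distance `|Δpos| + |Δend|` and ties
broken toward the lower truth position. Greedy is deterministic and,
on the instance sizes tested, within one pair of the maximum bipartite
matching (exact when compatibilities are unique) — that bound is
asserted against a `scipy` matching oracle in the suite. `passonly`
drops records whose FILTER is neither PASS nor '.'; an optional BED of
high-confidence regions restricts both sides to records fully inside a
region; size strata are applied to both sides as half-open `[lo, hi)`
bounds before matching. Breakends are excluded from precision/recall
(truth protocols cover deletions and insertions); they still merge and
receive qualities.

Per-combination breakdowns use one global matching and then group
evaluated calls by exact support set, so combination call counts sum
to the evaluated total and recall contributions are fractions of one
shared truth denominator. Concordance between two call sets is the
Jaccard index `matches / (|a| + |b| − matches)` under the same
matching contract (the metric choice is stated in the output, and both
sets' raw counts and the match count are reported alongside, since an
asymmetric overlap fraction is an equally defensible reading).
Cross-sample aggregation reuses the merge engine with samples in place
of callers; allele frequency is the alternate-allele count over 2N
when member genotypes are present, else carriers/N.

## Simulator

The generator emulates one sample observed by several imperfect
callers: `n_true` ground-truth SVs with types from a configurable mix
(default 40% DEL, 40% INS, 10% DUP, 10% INV — deletion- and
insertion-dominated, as real single-sample call sets are), log-uniform
sizes on [50 bp, 100 kb], positions uniform with contigs weighted by
length, and a 2 kb exclusion buffer (twice the default merge distance)
so distinct truth events can never be clustered together. Each caller
detects each truth SV independently with a sensitivity that may vary
by (type, size bin) — e.g. a read-depth caller blind to insertions and
sub-bin-size events; detections get independent rounded-Gaussian
breakpoint jitter at both ends (callers err at each breakpoint
independently) plus a multiplicative size error, clamped to the 50 bp
floor; false calls arrive as a Poisson process per megabase with sizes
and types drawn like truth events. Every simulated call carries a
label (origin truth id or FALSE), so precision can be bookkept exactly
without any matcher; the suite cross-checks that matcher-based and
label-based precision agree closely (the residual is the matcher's
refdist/size-ratio slack). Per-caller random streams are seeded as
`master_seed + crc32(caller_name)`, so adding a caller leaves the
other callers' outputs byte-identical.

What the simulator does not model: read-level evidence, coverage
fluctuations, reference bias, correlated errors between callers
sharing evidence types, clustered/complex SVs, and genotyping error.
Passing tests therefore demonstrate the correctness of the merging,
calibration and evaluation machinery under a known error model — not
caller performance on real sequencing data.

## Test and experiment sizes

The suite's standard fixtures are a 300-SV, 3-caller ensemble on a
20 Mb genome (general pipeline checks) and a 2,000-SV, 5-caller
ensemble on a 60 Mb genome for the calibration-recovery experiment. In
that experiment jitter and size error are set to zero so that each
caller combination's precision is fixed by the configured
sensitivities and false-call rates alone — the parameter being
recovered must be well-defined to be recoverable. Each retained
category's table precision is required to agree with its label-derived
precision within three binomial standard errors plus `1/n`, the
one-pair slack the greedy assignment contract permits; in aggregate
the plain three-standard-error bound must hold. Merge-oracle
equivalence runs on 1,000 random instances of up to 200 calls;
matcher-optimality on 500 simulated instances of up to ~30 calls;
format round trips on 100 random call sets. The full suite runs in
well under a minute on one CPU.

## Known limitations

- Merge representatives are coordinate medians; no caller weighting or
  confidence-interval (CIPOS/CIEND) handling.
- The matcher is greedy, not optimal; its TP count can undercount the
  maximum matching by one pair in ambiguous clusters (bounded and
  tested, and reported metrics state greedy counts).
- Inversion merging uses type identity only; breakend strand
  orientation is not modeled.
- Genotypes are carried as annotations and never influence merging,
  calibration or matching.
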