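# Methods

This note documents the models and procedures implemented in `synqtl`,
the parameters that matter, the design choices made where several
reasonable options existed, and what the synthetic benchmarks do and do
not demonstrate about real data.

## Coordinates and units

All genomic intervals are 0-based half-open (BED arithmetic: span =
end − start, two intervals touch when `a.end == b.start`). GFF3 and BLAST
coordinates are converted once at the parser boundary. Identity and
coverage are stored as fractions in [0, 1]; policy files may declare
`units: percent`. When the query axis of an analysis is a genetic map,
query coordinates are centimorgans and every span-based threshold applies
to the physical (target) genome only.

## Hit filtering and deduplication

A `FilterPolicy` holds up to five thresholds: minimum identity, minimum
coverage, minimum aligned length, minimum matching bp, maximum
mismatching bp. All thresholds are *inclusive*, so a dataset filtered at
"80% identity" retains a hit at exactly 0.80 — the convention that makes
printed cut-offs reproducible. Six presets cover the standard Solanaceae
datasets: CDS-to-genome alignments in either direction (0.80 / 0.75 /
200 bp), same-species marker placement (0.98 identity, ≥200 match bp,
≤50 mismatch bp), eggplant-marker self-alignment (0.75, ≥100 match bp,
≤50 mismatch bp) and cross-genus marker alignment (0.75 identity, 0.40
coverage, 200 bp). Tabular BLAST carries no query coverage, so BLAST hits
have unknown coverage and fail any policy with a coverage floor; the
policies meant for BLAST input use match/mismatch counts instead.

Multi-hit queries resolve to the hit with the lexicographically largest
(match bp, identity, coverage); remaining ties break deterministically on
target chromosome name, then position. Co-located queries — several
distinct queries aligned to one locus, typically paralogs collapsing onto
one orthologous gene — are the connected components of the relation "same
chromosome and interval gap ≤ tolerance" (default 25 bp; a 50 bp variant
is common for CDS screens). Gap distance is measured between interval
hulls rather than midpoints, so partial alignments still group. Because
the relation lives on one axis, the components are computed by a
coordinate sweep; an O(n²) union-find oracle verifies the equivalence in
the tests. Whether a grouped query is a true paralog or an alignment
artifact is not decidable from coordinates; the module reports groups and
leaves interpretation to the analyst.

## Primer anchoring

A COSII-style marker is retained when some (forward, reverse) hit
combination shares a chromosome, sits on opposite strands (standard PCR
geometry; can be disabled) and spans — outer edge to outer edge — within
a slack window around the expected amplicon length. Because intron sizes
drift between genera, slack is relative by default (±25%, configurable,
or an absolute ±bp). Among valid combinations the span closest to the
expected length wins; unpaired markers carry a reason code
(`no-common-chrom`, `strand-incompatible`, `no-span-match`).

## Synteny blocks

Chaining is greedy single-linkage per (query chromosome, target
chromosome) pair: anchors sorted by target position extend the current
run while target gap ≤ `max_gap_bp` (default 3 Mb), query gap ≤
`max_gap_query` (defaults to `max_gap_bp`; set it in cM for map-based
queries, default 30 cM in the map workflow) and the query-order direction
set by the run's first step is preserved. Defaults were chosen for anchor
densities of a few hundred anchors per chromosome — the scale at which
~20k genome-wide anchors land on a ~12-chromosome genome — so that
background chromosomes chain into a handful of long blocks.

Two repair passes follow, both motivated by failure modes the greedy rule
provably has:

* **Boundary refinement.** The first anchor of a reversed or displaced
  run can legally join the *preceding* block (the jump to it satisfies
  gap and direction rules); the anchor then inflates that block's query
  hull and shaves the true block below the reporting span. An edge anchor
  moves to the adjacent block when its query position is strictly closer
  to that block's query hull than to its own next-door anchor and the
  move preserves the recipient's direction rule.
* **Edge trimming.** A spurious hit whose random query position lands
  within the gap window can cap a run and stretch its hull by megabases.
  An edge anchor is dropped when its query step exceeds five times the
  block's median query-per-target step ratio over that distance — a
  scale-free test that works identically on bp and cM query axes.

Blocks with fewer than `min_anchors` (default 3) anchors are dropped but
returned, so anchors are conserved: every input anchor is in exactly one
block or in the dropped set. Orientation is the sign of the Kendall rank
correlation between query and target positions; the direction rule makes
it exactly ±1, and the scipy computation is kept as a cross-check.

## Rearrangement classification

Calls are made per block against the behaviour of its chromosome pair,
and reported only when the block's target span reaches `min_span_bp`
(default 0.5 Mb — the conventional floor for declaring inversions and
translocations between these genomes). The span filter applies at
reporting time only, so lowering it never removes a call.

* **Chromosome orthology** is the plurality map: each target chromosome
  is assigned the query chromosome contributing most of its anchors. The
  accompanying same-chromosome fraction (anchors on plurality pairs /
  all anchors) mirrors how such screens summarize chromosome-level
  conservation.
* **Translocation** — block's query chromosome differs from the
  orthologous partner of its target chromosome. A reciprocal arm exchange
  therefore yields one call on each receiving chromosome.
* **Inversion** — chromosomes agree, but the block's orientation opposes
  the pair's dominant orientation, computed anchor-weighted so a large
  inversion on a small chromosome cannot flip the reference.
* **Transposition** — chromosomes and orientation agree, but the block's
  query interval deviates from the colinear diagonal through its flanking
  anchors by more than the chaining query-gap limit (any smaller jump
  would have been chained through rather than split off). Flanks are
  taken from *trusted* blocks only — unclassified, outside duplication
  groups, and holding at least a quarter of the largest block's anchors —
  because a displaced segment must not anchor the rank test for its own
  neighbours.
* **Duplication** — two blocks on one query chromosome whose target
  intervals are disjoint while the larger block's anchors mirror at least
  half of the smaller block's anchors across its query interval
  (threshold configurable). Anchor-level support is what separates a
  duplication from a transposition: after a duplication the backbone
  still carries anchors over the duplicated query segment (the source
  copy); after a transposition the backbone's query *hull* spans the
  vacated segment but holds no anchors there. An interval-overlap test on
  hulls cannot make this distinction, which is why the criterion is
  anchor-based. The call is reported at the smallest-span group member —
  the displaced copy — and duplication-group members are exempt from the
  transposition rule, since their displacement is explained by the
  duplication itself.

Swapping which genome is "query" preserves inversion and translocation
calls up to chromosome relabeling (verified by a test). Duplication
signatures are intrinsically asymmetric — one query interval maps to two
target intervals — and are not preserved by the swap.

Centromeric regions are not masked by default; small calls near assembly
anchoring artifacts can be excluded by pre-filtering the input hits with
a mask if desired.

## Genetic-to-physical projection

The local conversion rate between neighbouring anchored markers is
|Δbp| / ΔcM; co-segregating pairs (ΔcM = 0) and pairs spanning different
target chromosomes are rejected. Before projection the anchor scaffold of
a linkage group is cleaned: anchors disagreeing with the linkage group's
majority target chromosome are excluded (they sit on translocated
segments and would corrupt the interpolant — the synteny analysis is the
right tool for them), co-segregating duplicates keep the first anchor,
and residual non-monotone placements are resolved by the longest monotone
subsequence in the dominant direction, keeping the cM→bp interpolant a
function. All exclusions are reported.

Two projection modes:

* `local_rate` (default): the QTL peak is interpolated inside its
  flanking anchor pair and the confidence interval is placed around the
  peak using that single local rate, so the physical CI width equals
  (hi − lo) cM × rate exactly. The CI is anchored at the projected peak
  rather than re-centred, preserving asymmetric support intervals.
* `piecewise`: peak and both CI bounds are interpolated independently
  through the whole monotone scaffold — more faithful when the
  recombination rate varies across a wide interval (e.g. near
  centromeres), at the cost of not preserving the exact width relation.

Positions outside the anchored range use the terminal segment's rate and
are flagged `extrapolated`. Multi-environment QTL studies report one
support interval per trial environment; these are averaged element-wise
before projection, generalizing the two-environment mean to any count.
Intervals are clipped at 0 and, when a chromosome length is supplied, at
the chromosome end; output coordinates are rounded to integer bp.

## QTL orthology

Physical QTL from two species on one reference genome are compared after
a major-QTL filter (PVE ≥ 10%, inclusive). A pair is emitted when the two
intervals share a chromosome, their traits are declared related in an
explicit user-supplied equivalence table (symmetric closure applied at
load; never string matching — trait grouping is expert judgment), and the
interval gap is at most `proximity_bp`. The default proximity and merge
gap of 1 Mb sit at the scale of the narrowest QTL clusters such screens
report; both are flags. Candidate retrieval uses an interval tree; the
tests check the result against a brute-force all-pairs oracle.
Clustering is single-linkage over all QTL of both species (gap ≤
`merge_gap_bp`), realized as a coordinate sweep and verified against a
connected-components oracle. Clusters with members from both species are
flagged orthologous; one-species clusters are first-class output — the
co-localization of several same-trait QTL with no counterpart in the
other species is a finding, not a failure.

## Synthetic data

The generator produces the three kinds of inputs the pipeline consumes,
with exact ground truth.

**Genome pairs.** Twelve 50 Mb chromosomes with 400 disjoint anchors each
(~125 kb spacing) — the same anchors-per-event order of magnitude as a
~20k-anchor comparison of ~1–3 Gb genomes, at desk-scale cost. Events are
planted on disjoint chromosomes (translocations use two), with intervals
chosen as the hull of a run of at least 4 consecutive anchors spanning
0.6–2.5 Mb by default and endpoints placed in anchor gaps, so every
planted event is detectable by construction — the standard design for
ground-truth rearrangement benchmarks. Inversions reflect coordinates and
flip strands (an involution, tested as such); reciprocal translocations
exchange distal arms with breakpoints at 55–75% of the chromosome so the
plurality orthology stays put; transpositions cut and reinsert a segment
at least 8 Mb away (beyond the default chaining gap, so the copy cannot
chain through); duplications insert a copy whose anchors carry new query
ids over the same query interval — modelling distinct query genes that
match both target copies, which is what survives single-best-hit
filtering in real data, where a same-id second hit would simply be
discarded as a multi-hit.

Noise defaults — the generator's documented operating point — are 5%
spurious uniform hits, 5% missing anchors, 1% paralogous extra hits (the
copy's alignment quality is drawn below its source so best-hit selection
resolves it), ±5 kb positional jitter, and 5% of anchors with
sub-threshold alignment quality to give the filter stage real work.
Anchor accounting reconciles exactly per seed: output = placed − deleted
+ paralog copies + spurious.

**Maps and QTL.** Each linkage group spans 100 cM with 51 markers on a
regular 2 cM grid, mapped through a monotone cM→bp function — linear, or
a logistic sigmoid (steepness 8) whose high central bp/cM mimics
centromeric recombination suppression. QTL carry true physical intervals
computed through the same function; per-environment CIs are symmetric
perturbations whose mean is the true CI. A second species' QTL set shares
a configurable fraction of loci under related traits. A separate planted
cluster generator lays out a configurable number of two-species and
one-species QTL clusters (default 8 + 6) with centres spaced far beyond
the merge gap.

**What passing these benchmarks shows — and does not.** The simulations
validate the geometry and logic of every stage: filters equal their
predicate, components equal their oracles, planted events are recovered
perfectly without noise and with ≥0.9 pooled precision and recall at the
default noise level, projections are exact where mathematics says they
must be. They do not model assembly fragmentation, scaffold
mis-anchoring, repeat-driven anchor clustering, centromeric anchor
deserts, or genome-size asymmetry between the two species; on real data
the chaining gap and minimum-anchor parameters need tuning to anchor
density, and small calls in pericentromeric regions deserve skepticism.

## Numerical choices

* Floats are serialized with `%.17g` and parsed with pandas'
  `round_trip` precision, so tabular outputs round-trip bit-exactly and
  identical seeds give byte-identical files.
* Physical QTL coordinates are integers (rounded once, at output); the
  linear-map exactness checks therefore assert agreement to ≤1 bp.
* Deterministic tie-breaks everywhere: best-hit ties by (chromosome,
  position); orthology-plurality ties by chromosome name; primer-pair
  span ties by genomic position; cluster ids by sweep order. All
  simulator randomness flows from one `numpy.random.Generator` seeded
  from a single integer; no global RNG state is touched.
* Benchmark sizes (100 histories for rearrangement recovery, 100 QTL for
  projection, 20 seeds for the oracle sweeps) were chosen to keep the
  full validation under a minute on one core while leaving event counts
  per condition in the hundreds.

## Known limitations

* Breakpoints are resolved only to the anchor hull, never to base pairs.
* No statistical significance model for blocks or clusters (no Poisson
  block test, no cluster enrichment test); the calls are geometric.
* The transposition rule needs at least one trusted flanking block; a
  chromosome consisting almost entirely of one displaced block is
  reported as colinear.
* Nested or overlapping rearrangements on one chromosome are not
  modelled by the simulator and not guaranteed to classify cleanly.
* `local_rate` projection with a rate taken at the peak can misplace very
  wide CIs on strongly non-linear maps; `piecewise` mode exists for
  exactly that case.
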