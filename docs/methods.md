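# Methods

## Coordinates and gene models

All intervals are 0-based, half-open, matching the UCSC refGene convention
(txStart 0-based, txEnd exclusive). The TSS of a minus-strand transcript is
`txEnd − 1`. Transcripts are collapsed to genes by symbol (refGene `name2`),
because induced-gene lists are symbol-keyed; the gene's TSS set is the union
of its transcripts' strand-aware TSSs and the **canonical TSS is the 5′-most
one** (minimum coordinate on +, maximum on −). The canonical TSS drives
distances and clustering; the full TSS set drives promoter binding. Genes
whose transcripts disagree on chromosome or strand are resolved to the
longest transcript's placement and logged — silently dropping them would
bias symbol matching, and there are too few to justify failure.

Promoter windows include the TSS base on both sides: "±1 kb" is the
half-open interval `[TSS − 1000, TSS + 1001)`. This choice is arbitrary at
the biology's scale but is fixed and documented so peak-overlap results are
bit-stable. The motif window (−1250/+750) is placed strand-aware by default,
since its asymmetry is meant relative to the direction of transcription;
a flag disables this for strand-agnostic tracks.

## Interval primitives

Nearest-TSS distances follow an ignore-overlap nearest-feature contract:
for each 1-bp TSS point, the minimum |a − b| over other points on the same
chromosome, skipping points at the identical coordinate; genes alone on
their chromosome are excluded and counted. Distances are point-to-point
|a − b| rather than an edge-gap with a −1 correction: the analysis reasons
in TSS-to-TSS distances and the off-by-one is immaterial at kb scale, but
one convention had to be fixed for determinism. Overlap counting uses
half-open ≥1 bp overlap semantics. Both primitives run on per-chromosome
sorted arrays with binary search and are tested against O(n·m) brute-force
scans and against the `bedtools` CLI on random fixtures.

## Proximity statistics

The deviation score compares induced and random nearest-neighbour distance
distributions through K = 1000 quantiles at pₖ = (k − ½)/K with linear
interpolation: each Q–Q point's signed Euclidean distance to the identity
line is (q_induced − q_random)/√2 and the score is the sum, negative when
induced genes are closer than random. The quantile rule and the aggregation
(sum vs mean) were open choices; both variants are reported and the default
unit is kb, configurable to bp — published magnitudes for this kind of score
are not unit-annotated, so the package documents its scale rather than
asserting one. The score is exactly 0 for identical samples and exactly
antisymmetric under argument swap; a constant shift c of one sample gives
the closed form −K·c/√2, used as a test oracle.

The random null draws genes uniformly without replacement from the
protein-coding universe, size-matched to the induced set, from an explicit
seed (no hidden global state). An optional expression-matched sampler
(quantile-bin matching on a supplied expression column) is provided for
datasets where expression confounding matters.

The distribution summit is the mode of a Gaussian KDE (Scott's bandwidth)
over log₁₀(distance), evaluated on a 512-point grid spanning the data —
distances span orders of magnitude and their distributions are examined on
log axes, so the mode is estimated on that scale. It is refused below 10
distances, where a mode is meaningless. The within-threshold fraction uses
an inclusive ≤ at the 100 kb default threshold.

## Clustering

Distance clustering chains genes along each chromosome whenever the gap
between consecutive canonical TSSs is **strictly** below `max_gap`
(default 100 kb, per the "less than 100 kb" rule); maximal chains of ≥ 2
genes become clusters. On a line this single-linkage chaining equals the
connected components of the pairwise < max_gap graph, which is the test
oracle. Cluster ids are deterministic
(`<dataset>:<method>:<chrom>:<index by leftmost TSS>`), and output is
independent of input order.

TAD clustering assigns each gene to every TAD containing its canonical TSS
(half-open containment, no distance limit inside a TAD). Nested or
overlapping TADs may produce overlapping clusters; whether the original
analyses deduplicated those is unknowable from the outside, so both
behaviours are exposed (`smallest_only` restricts each gene to the smallest
containing TAD, off by default).

Method comparison matches distance clusters to TAD clusters greedily by
descending gene-set intersection size with deterministic tie-breaks. The
"common cluster" rule is a package decision — intersection on gene symbols
is the simplest rule that is invariant to coordinate conventions.

## Epromoter calling

Per-gene binding flags are OR-combined across the dataset's key TFs (a
heat-shock dataset has HSF1 and HSF2; either binding counts as recruitment)
before classification. Categories: `unbound` (n_bound = 0), `all_bound`
(n_bound = n), `epromoter_regulated` (1 ≤ n_bound < n). The distance-method
criterion is `fewer_than_n`; the TAD-method default is `exactly_one`, which
demotes clusters with 2 ≤ n_bound < n to a `partial_multi` subcategory
rather than guessing whether multiple bound promoters share the Epromoter
role. The four categories always partition the cluster list (asserted on
construction). Bidirectional promoters are handled at gene level: two genes
whose windows overlap one peak both count as bound, keeping counts
reproducible without a promoter-unit merge step.

Non-redundant merging across datasets links Epromoter-regulated clusters
sharing ≥ 1 gene symbol within a genome build (union-find over symbols);
connected components are the non-redundant clusters and builds never merge.
Symbol-based merging was chosen over coordinate overlap because the
pipeline's cluster identity is symbol-keyed end to end.

Peak-location profiling extends the cluster span (leftmost to rightmost
TSS) by ±100 kb and splits overlapping peaks into proximal — ≥ 1 bp overlap
with the ±1 kb window of **any** annotated gene's TSS, induced or not — and
distal/intergenic.

## Synthetic data

The generator produces what a processed stress dataset provides, with known
truth. `make_genome` places gene TSSs by a uniform-with-exclusion process
(sorted uniforms plus a spacing floor, default 10 kb), random strands, and
1–3 TSSs per gene with alternatives within 5 kb downstream of the canonical
one — downstream so that the canonical TSS remains the 5′-most, exactly as
after transcript collapsing, which makes fixtures round-trip through the
refGene writer/parser unchanged.

`plant_clusters` re-places selected genes along each chromosome rather than
hoping the random layout contains usable neighbourhoods: planted clusters
and induced singletons are blocks separated by 400–600 kb of clear space,
intra-cluster gaps are drawn from 20–80 kb (safely below the 100 kb rule and
around the distance-distribution summits seen in real stress data), one
planted Epromoter per cluster receives a 200 bp peak centred on its
canonical TSS, TADs span each cluster with 150 kb margins (short of the
neighbouring blocks, so TAD and distance clustering agree by construction),
and the remaining genes become background filling the space after the last
block. Optional distal peaks sit mid-way inside the first intra-cluster
gap, ≥ 5 kb from every TSS and therefore outside every promoter window.
Infeasible geometry (too many/large blocks for the chromosome) raises an
error naming the failing block rather than silently bending the constraints.

`simulate_proximity` drives the statistics tests: uniform subsamples for
null calibration, or clumped draws (anchor gene plus nearest neighbours
within 50 kb, clumps of 3 by default) emulating co-induced neighbourhoods.

What the fixtures deliberately do **not** emulate: realistic gene-density
heterogeneity, peak-strength variation, noisy or missing peak calls,
alternative-TSS-specific induction, and annotation errors. Passing the
planted-truth tests therefore demonstrates that the rules are implemented
exactly as specified, not that the rules are robust to noisy real data —
robustness there is bounded by the quality of the input peak calls and
differential-expression lists, which this package consumes as given.

## Numerical and operational choices

* All randomness flows through `numpy.random.default_rng` from explicit
  integer seeds; identical seed ⇒ byte-identical outputs (tested).
* TSV outputs use fixed column order, UTF-8, and 6-significant-digit
  floats; summary JSONs are key-sorted.
* Chromosome naming ("chr1" vs "1") is normalised against the annotation's
  convention when reading peak/TAD/motif BEDs.
* Empty categories or empty call lists yield NaN fractions, never division
  errors; an empty peak file yields a valid, empty Epromoter table.
* K-S testing uses `scipy.stats.ks_2samp` (two-sided, exact/asymptotic per
  scipy's default switching).

## Problem sizes

Tests and the acceptance script use toy genomes of 2–5 chromosomes with
200–400 genes each (10–20 Mb per chromosome), 5–50 planted clusters, and
100–200 repeated draws for power/null calibration. These sizes give exact
planted-truth recovery and stable Monte-Carlo estimates in seconds; all
algorithms are O((n + m) log n) in the number of features and scale to real
genome annotations (~25k genes, ~10⁴–10⁵ peaks) without modification.

## Known limitations

* The 100 kb threshold is global; an adaptive, stress-specific threshold
  (or 3D-contact-based grouping) may capture clusters this rule misses.
* TAD clustering uses static TAD calls; stress-specific topology is not
  inferred.
* When several promoters in a cluster are bound, the package reports them
  all as candidate Epromoters (or `partial_multi` under `exactly_one`)
  rather than scoring which one is causal.
* Motif analysis consumes precomputed occurrence tracks; there is no PWM
  scanning, and multiple motif tracks are pooled by summing counts.
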