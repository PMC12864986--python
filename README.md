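# epromoters

Identification of **Epromoter-regulated clusters** of stress-induced genes.

Acute cellular stress (heat shock, cytokines, serum, hypoxia, ...) triggers
rapid transcriptional reprogramming driven by a small number of key
transcription factors (HSF1/HSF2, NF-κB, STAT1, SRF, ...). Co-induced genes
are often found in close genomic proximity, and in many such neighbourhoods
only **one** promoter actually recruits the key TF — an *Epromoter*, a
regulatory element with both promoter and enhancer function that drives its
neighbours' induction. This package implements the computational side of
that analysis for people working with processed stress datasets (an induced
gene list with fold changes, TF ChIP-seq peaks, a UCSC refGene annotation):

* **Proximity statistics** — for an induced gene set *I*, the
  nearest-neighbour TSS distances d(g) = min(|TSS(g) − TSS(g′)|, g′ ∈ I\{g},
  same chromosome) are compared to a size-matched random gene set by a
  two-sample Kolmogorov–Smirnov test and a signed Q–Q **deviation score**

  &nbsp;&nbsp;&nbsp;&nbsp;D = Σₖ (q_I(pₖ) − q_R(pₖ)) / √2,&nbsp;&nbsp;
  pₖ = (k − ½)/K, K = 1000,

  which is negative when induced genes sit closer together than random
  genes. The distribution summit (mode on a log₁₀ scale) and the fraction of
  genes within 100 kb of another induced gene are reported alongside.
* **Clustering** — induced genes are clustered either by chaining
  consecutive TSSs less than 100 kb apart, or by co-membership in a
  topologically associating domain (TAD); clusters need ≥ 2 genes.
* **Epromoter calling** — a promoter is TF-bound when any peak overlaps the
  ±1 kb window around any of the gene's TSSs (alternative TSSs included). A
  cluster is *epromoter_regulated* when at least one but fewer than all of
  its genes are bound; *all_bound* and *unbound* otherwise. Bound genes are
  the candidate Epromoters, unbound ones the co-induced genes. Dataset
  summaries, cross-dataset aggregation and non-redundant merging (clusters
  sharing a gene symbol, per genome build) are included.
* **Motif density** — TF-motif occurrences (precomputed BED tracks, e.g.
  JASPAR scans) counted in −1250/+750 bp promoter windows, binned
  0 / 1 / 2–3 / >3 per promoter category (Epromoter, co-induced, other
  induced TF+/TF−, random).
* **Peak location** — peaks in the cluster span ± 100 kb split into
  TSS-proximal (within 1 kb of any annotated TSS) versus distal/intergenic.
* **Synthetic fixtures** — seeded toy genomes with planted clusters,
  Epromoters, TADs and motif tracks, so the whole pipeline is testable with
  known ground truth and no downloads.

## Worked example

```python
import epromoters as ep

genome = ep.make_genome(n_chrom=2, genes_per_chrom=300, chrom_len=20_000_000,
                        min_gene_spacing=10_000, seed=7)
truth = ep.plant_clusters(genome, n_clusters=5, genes_per_cluster=3,
                          n_singletons=10, chrom_len=20_000_000, seed=7)
clusters = ep.cluster_by_distance(truth.induced_genes)
calls = ep.classify_clusters(clusters, {"TF": list(truth.peaks)})
for call in calls:
    print(call.cluster.cluster_id, call.category,
          "epromoter:", ",".join(call.epromoter_genes),
          "coinduced:", ",".join(call.coinduced_genes))
summary = ep.summarize_dataset(calls, "demo")
print(f"{summary.n_epromoter_clusters}/{summary.n_clusters} clusters "
      f"epromoter-regulated (freq {summary.freq_epromoter:.2f})")
```

prints

```
dataset:distance:chr1:0 epromoter_regulated epromoter: g1_0002 coinduced: g1_0000,g1_0001
dataset:distance:chr1:1 epromoter_regulated epromoter: g1_0003 coinduced: g1_0004,g1_0005
dataset:distance:chr1:2 epromoter_regulated epromoter: g1_0006 coinduced: g1_0007,g1_0008
dataset:distance:chr2:0 epromoter_regulated epromoter: g2_0001 coinduced: g2_0000,g2_0002
dataset:distance:chr2:1 epromoter_regulated epromoter: g2_0005 coinduced: g2_0003,g2_0004
5/5 clusters epromoter-regulated (freq 1.00)
```

Every planted cluster is recovered with its planted Epromoter; the
co-induced genes are the cluster members whose promoters carry no peak. The
proximity statistics on the same toy genome, with induced genes drawn in
clumps of 3 within 50 kb:

```python
induced = ep.simulate_proximity(genome, 150, clump_size=3, clump_spread=50_000, seed=7)
report, qq = ep.proximity_report(induced, genome, seed=7)
print(f"deviation score {report.deviation_score:.1f} kb, "
      f"K-S p = {report.ks_pvalue:.2e}, "
      f"summits {report.summit_induced_kb:.1f} vs {report.summit_random_kb:.1f} kb")
```

```
deviation score -67090.8 kb, K-S p = 7.29e-30, summits 15.9 vs 127.2 kb
```

The strongly negative deviation score and the summit shift (16 kb vs 127 kb)
say the clumped genes sit far closer together than a random draw — the
signature real stress datasets show.

## Command line

The same steps are exposed as subcommands (`epromoters --help`):
`simulate`, `run`, `cluster`, `call`, `proximity`, `motif-density`,
`peak-location`, `aggregate`. A full run needs three inputs — annotation,
induced list, peaks — and writes the per-gene binding table, the
Epromoter-cluster table, a summary JSON, the bubble-grid occupancy table,
and a log:

```bash
epromoters simulate --n-clusters 5 --seed 7 --outdir fixture/
epromoters run --dataset-id demo \
    --annotation fixture/annotation.refGene.txt \
    --induced fixture/induced.tsv \
    --peak HSF1=fixture/peaks.bed \
    --tads fixture/tads.bed \
    --method distance --method tad \
    --seed 7 --outdir out/
```

Outputs are deterministic: the same config and seed reproduce byte-identical
files.

## Layout

```
src/epromoters/
  annotation.py   refGene parsing, gene collapsing, promoter windows
  intervals.py    nearest-point / overlap-count / extend primitives
  proximity.py    distance distributions, K-S, deviation score, summit
  clustering.py   distance and TAD clustering, method comparison
  calling.py      promoter binding, cluster categories, summaries, peak location
  motifs.py       promoter categories and motif-count binning
  simulate.py     synthetic genomes and planted ground truth
  pipeline.py     run configuration and orchestration
  cli.py          click command line
```

See `docs/methods.md` for the modelling choices and their rationale.
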