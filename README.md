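# ecordkit

Detection of **coordinately repressed gene clusters (ECORDs)** from
differential-expression tables and TAD annotations, **broad H3K9me2 domain
calling** from ChIP/Input coverage tracks, and **domain-constrained
peak/gene enrichment statistics** — the downstream analyses used to
characterise how loss of the H3K9me2 methyltransferase EHMT2 derepresses
clustered, TAD-confined gene programs in mouse embryonic stem cells.

It is written for computational genomicists who already have upstream
outputs in hand — a DESeq2-style table per contrast, gene annotation
(GTF/BED), TAD intervals (BED), binned coverage (bedGraph, optionally
BigWig), peaks and repeat annotation — and want the bespoke downstream
statistics as a tested, scriptable library plus CLI.  A synthetic-data
module generates all inputs with known ground truth, so the full pipeline
runs and is validated without any download.

## The core algorithm

Genes are walked along the linear genome in TSS order.  With adjusted-p
threshold α = 0.05 and fold threshold L = 1, each gene is a DEG
(`padj < α`, `|log2FC| ≥ L`), a *breaker* (`padj < α`, `|log2FC| < L`),
*static* (`padj ≥ α`) or *unexpressed* (`padj` = NA).  Maximal runs of
consecutive same-direction DEGs are interrupted by (1) an
opposite-direction significant gene — no fold cutoff, so breakers count —
or (2) a TAD change; statics and unexpressed genes are skipped.  A
cluster with k member DEGs and s static genes intersecting its span has
static fraction s/(s+k); **ECORDs** are clusters with k ≥ 4 (bulk; 5 for
sorted cells) and static fraction < 0.5.  A shuffle null (random DEG
re-labelling of expressed genes) gives the probability that clusters of a
given size arise by chance.

H3K9me2 domains are called on smoothed log2(ChIP/Input) bins: bins above
the genome-wide 80th percentile seed domains that extend until signal
drops below the 30th percentile.  A two-component Gaussian mixture fitted
to the same distribution estimates the genome fraction in the signal
component (λ₂), which also anchors inter-sample scaling.  Enrichment of
gene categories at peak classes is tested by permuting labels 1000× while
holding domain-constrained gene→peak assignments fixed.

## Worked example

```python
from ecordkit import synthetic_data as sd, reporting
from ecordkit.ecord_detection import (call_clusters, filter_ecords,
                                      shuffle_probability_curve)

genes, tads = sd.make_genome(seed=1)           # 5 chroms, 100 TADs, 2000 genes
specs = [sd.ClusterSpec("chr1_tad4", k=6, n_static=1),
         sd.ClusterSpec("chr3_tad11", k=4, n_static=0),
         sd.ClusterSpec("chr5_tad2", k=9, n_static=2)]
degs, truth = sd.make_deg_table(genes, tads, specs,
                                background_deg_rate=0.01, seed=2)

clusters = call_clusters(genes, degs, tads, direction_filter="UP")
ecords = filter_ecords(clusters, min_degs=4, max_static_fraction=0.5)
for e in ecords:
    print(f"{e.cluster_id}: {e.chrom}:{e.start}-{e.end} ({e.tad_id}) "
          f"n={e.deg_count} static_fraction={e.static_fraction:.2f}")
print(reporting.ecord_summary(ecords, degs))

curve = shuffle_probability_curve(genes, tads, n_deg=30,
                                  n_iterations=500, seed=0)
print("null fraction at n>=4:", curve.fraction_passing[3])
```

prints

```
cluster_2: chr1:355492-388608 (chr1_tad4) n=6 static_fraction=0.14
cluster_13: chr3:1016500-1034839 (chr3_tad11) n=4 static_fraction=0.00
cluster_20: chr5:131196-182668 (chr5_tad2) n=9 static_fraction=0.18
{'n_ecords': 3, 'n_member_degs': 19, 'mean_degs_per_ecord': 6.3, 'percent_degs_in_ecords': 61.3}
null fraction at n>=4: 0.0
```

All three planted clusters are recovered with their planted sizes and
static fractions, 61.3% of upregulated DEGs fall inside ECORDs, and random
re-labelling of 30 genes essentially never produces a qualifying 4-DEG
cluster — the separation that distinguishes coordinate derepression from
chance clustering.

The same workflows are available from the shell:

```
ecordkit simulate --outdir ws --seed 1
ecordkit call-ecords --genes ws/genes.gtf --degs ws/degs.tsv \
    --tads ws/tads.bed --out ws/ecords.bed
ecordkit k9-domains --chip ws/chip.bedgraph --input ws/input.bedgraph \
    --out ws/domains.bed
ecordkit demo --outdir ws --seed 1      # end-to-end with truth scoring
```

`ecordkit --help` lists the remaining subcommands (shuffle-curve,
mixture-fit, scale-tracks, repeat-overlap, assign-peaks, bootstrap-enrich,
domain-overlap, nearest-distance).

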