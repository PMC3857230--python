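# chromnet

Network-based inference of spatial genome organization from chromatin
interaction calls.

Chromosome conformation capture assays (3C, Hi-C, ChIA-PET) report pairs
of genomic loci that touch in the nucleus. `chromnet` treats those calls
as what they are — a graph — and reads the spatial organization of the
genome from the graph's architecture. It is aimed at genomicists who
have fragment-level interaction tables with significance scores (for
example HindIII-fragment pairs with FDR values) and want to ask: which
loci form stable multi-chromosome hubs, how does the genome partition
into spatial compartments, is that partition stronger than chance, and
which genomic features concentrate in which compartment. In a
budding-yeast-like genome this recovers the rosette configuration:
clustered centromeres, arms radiating outward in strata, and a distinct
telomere cluster.

## What it computes

Mappable restriction fragments are nodes; interactions with
FDR ≤ threshold are edges of weight 1; the network is one interaction
class (inter, intra, or complete) restricted to its largest connected
component.

- **Maximal cliques** (Bron–Kerbosch with pivoting). Each fragment gets
  its *maximum clique size* — in an inter-chromosomal network, the
  number of distinct chromosomes it stably meets — and continuous
  signals (cohesin enrichment, replication timing) are summarised per
  size class with a Spearman trend over the class means.
- **Communities** by hierarchical Louvain maximisation of Newman
  modularity
  `Q = (1/2m) Σ_ij [A_ij − k_i k_j / 2m] δ(c_i, c_j)`,
  with recorded levels (level 0 finest, top level final), a <10-node
  community filter, and second-round partitioning of each community's
  subnetwork.
- **Null calibration**: the observed modularity as a standard score
  against 10,000 (configurable) G(n, m) random graphs of equal order
  and size, each partitioned the same way.
- **Recapitulation**: robustness to the edge threshold, as the fraction
  of each stringent-threshold community contained in a single
  lenient-threshold community.
- **Enrichment**: two-tailed Fisher's exact tests of feature-vs-
  community membership over the network universe, with
  Benjamini–Hochberg correction across factor families.
- **Synthetic rosette generator**: a planted multi-chromosome genome
  with centromere/stratum/telomere contact classes and nested FDR tiers,
  so the entire pipeline is testable without external data.

## Worked example

`examples/` contains one short script per capability. From
`examples/01_network_and_cliques.py` (synthetic rosette, seed 0):

```
inter-chromosomal network: 398 nodes, 1352 edges
  clique size 2:  214 fragments, mean cohesin log2 ratio -0.43
  clique size 3:  136 fragments, mean cohesin log2 ratio +0.16
  clique size 4:   43 fragments, mean cohesin log2 ratio +0.69
  clique size 5:    5 fragments, mean cohesin log2 ratio +1.17
Spearman (mean enrichment vs clique size): 1.00
```

The cohesin-like signal rises monotonically with the number of
chromosomes a fragment contacts — fragments in large inter-chromosomal
cliques are stable hubs. From `examples/02_communities_and_hierarchy.py`
on the same draw:

```
3 hierarchical levels; modularity per level: ['0.497', '0.614', '0.620']
  community 0: 30 nodes (7.5%), mostly planted 'tel' (30/30)
  community 1: 142 nodes (35.7%), mostly planted 'arm1' (142/142)
  community 2: 170 nodes (42.7%), mostly planted 'arm2' (166/170)
  community 3: 56 nodes (14.1%), mostly planted 'cen' (56/56)
```

The partition recovers the planted rosette strata, and
`examples/03_null_calibration.py` shows the structure is far beyond
chance (`observed Q = 0.620` vs `0.359 ± 0.005` over 200 G(n, m) nulls,
`Z = 52.0`). `examples/04_recapitulation.py` finds a 98% mean
recapitulation between the 0.01%- and 1%-FDR networks, and
`examples/05_enrichment.py` pins the planted factor and the centromeres
to the centromeric community (p ≈ 3e-18 and 1e-7) and telomeres to the
telomere community.

## Command line

A thin CLI mirrors the library:

```sh
chromnet simulate --seed 0 --outdir sim/
chromnet build --fragments sim/fragments.bed --interactions sim/interactions.tsv \
    --cls inter --fdr 0.01 --out net.tsv
chromnet communities --fragments sim/fragments.bed --interactions sim/interactions.tsv \
    --cls inter --seed 1 --out partition.tsv
chromnet run --config run.yaml       # full pipeline with a run manifest
```

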