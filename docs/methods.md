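# Methods

## The model

The package treats a set of chromatin–chromatin interaction calls as a
simple, unweighted graph. Mappable restriction fragments (e.g. HindIII
fragments) are nodes; a fragment pair whose interaction call achieves an
FDR at or below the chosen threshold contributes an edge of weight 1.
Interaction significance is taken as given — the scores in the input
table are produced upstream by whatever probability model scored the
assay — and this package never recomputes it. Networks are built from
one interaction class at a time: inter-chromosomal pairs only,
intra-chromosomal pairs only (pooled across chromosomes into one graph),
or their union (the "complete" network). After class and threshold
filtering the graph is restricted to its largest connected component;
ties between equal-sized components break to the component containing
the lexicographically smallest node id, so construction is
deterministic. Because thresholding only removes edges, the
stringent-threshold network is always a subnetwork of the lenient one —
the property the recapitulation analysis exploits.

Two architectural summaries are computed on these graphs.

**Maximal cliques.** Large cliques are very unlikely to assemble by
chance in a sparse graph, so a fragment's *maximum clique size* — the
cardinality of the largest maximal clique containing it — measures how
strongly embedded it is in a block of mutually interacting loci. In an
inter-chromosomal network every member of a clique lies on a different
chromosome, so clique size counts distinct chromosomes meeting at one
spatial position. Cliques are enumerated with Bron–Kerbosch with
pivoting; candidates are visited in sorted-id order and the pivot is the
candidate covering the most remaining candidates (ties to the smallest
id), making the enumeration order reproducible. Continuous signals are
summarised per clique-size class as the unweighted mean over nodes, with
IQR as dispersion, and the trend statistic is Spearman's rank
correlation computed on one (size, mean) pair per distinct observed
size — not per node — because the question is whether the class means
order with size. Classes with fewer than three nodes are retained; the
correlation is reported as missing when fewer than three classes carry
signal or all class means tie.

**Communities.** Partition quality is Newman modularity,

    Q = (1/2m) Σ_ij [A_ij − k_i k_j/(2m)] δ(c_i, c_j),

with m the total edge weight and k_i the degree of node i. Communities
are found with an in-package Louvain implementation: phase 1 sweeps
nodes in a seeded-shuffle order (one shuffle per level) and relocates
each node to the neighbouring community with the largest modularity
gain, ties breaking to the lowest community id, until a full sweep makes
no move; phase 2 collapses communities into nodes, summing
inter-community weights and banking intra-community weight as
self-loops. Each aggregation round is recorded as one hierarchical
level; level 0 is the finest partition and the top level is the
solution. With the default `min_gain = 0` a move requires strictly
positive improvement, so the recorded modularity sequence is
non-decreasing and termination is guaranteed (Q is bounded). Community
ids are renumbered 0, 1, 2, … in order of first appearance at each
level; all downstream comparisons are label-invariant. Louvain is a
heuristic — exact modularity maximisation is NP-complete — but the test
suite verifies it attains the exhaustively-enumerated optimum on small
benchmark graphs and recovers planted stochastic-block partitions with
mean adjusted Rand index above 0.99.

Louvain tends to produce a few very small, chain-like communities at
network edges; communities under 10 nodes (configurable) are filtered
out, their members reported as unassigned rather than discarded.
Hierarchical structure below the top level is probed by *subcommunity*
detection: each retained community's induced subnetwork (restricted to
its own largest connected component) is treated as an independent
network and re-partitioned, with per-community seed `seed + parent_id`.

## Null calibration and robustness

A modularity value has no intrinsic meaning, so each observed partition
is compared to an ensemble of G(n, m) graphs — uniform simple graphs
with the observed node and edge counts. Each replicate is partitioned
with the same Louvain procedure (replicate r seeds its graph draw and
its node shuffle with `seed + 1 + r`) and the observed top-level Q is
summarised as a standard score z = (Q_obs − mean)/sd (sample sd, ddof 1)
together with the empirical exceedance fraction. Connectivity is *not*
enforced on null draws: the ensemble is defined purely by order and
size, and Louvain handles disconnected graphs natively (each component
partitions independently). Degree-preserving (configuration-model) nulls
are deliberately out of scope — the calibration here fixes only n and m.

Threshold robustness is the mean *recapitulation*: for each community C
of the stringent-threshold network (after size filtering), r_C is the
largest fraction of C's members lying inside a single lenient-threshold
community, and the mean over stringent communities is unweighted.
Stringent nodes absent from the lenient partition (lost to its largest
connected component or to the size filter) are dropped from the
denominators with a logged count.

## Feature mapping and enrichment

Binary annotations are assigned to fragments by a non-zero-overlap
criterion on half-open intervals: one shared base pair labels the
fragment, and [a, b) adjacent to [b, c) shares none. Gene-style
assignment instead requires the transcription start coordinate to lie
inside the fragment. Continuous tracks map to fragments as the
unweighted mean of overlapping interval values (an interval spanning two
fragments contributes to both; fragments with no overlap are missing).
ChIP enrichment per fragment is log2((chip·s + ε)/(control + ε)) with
pseudocount ε = 0.5 and, by default, library-size scaling
s = total(control)/total(chip); unnormalised ratios confound sequencing
depth, so normalisation is on unless disabled.

Community–feature association uses the two-tailed Fisher's exact test on
the 2×2 table (in community × has feature) with the probability-mass
two-sided convention: the p-value sums hypergeometric probabilities of
all same-margin tables no more probable than the observed one. The
universe is the analysed network's fragment set, including nodes left
unassigned by the size filter (the test contrasts one community against
the rest of the network); a zero margin reports p = 1 with a degenerate
flag. Families of factor tests within one community are corrected with
Benjamini–Hochberg; single chromosomal features (centromeres, telomeres,
tRNAs) report raw p. Because Fisher's test is exact and discrete it is
mildly conservative; the calibration test checks that the permutation
type-I rate at a 400-fragment universe sits inside the 99% binomial band
around 0.05.

## The synthetic rosette generator

The generator plants the organization the method is meant to detect: a
genome of 8 chromosomes × 50 fragments of 4 kb, centromeres
mid-chromosome, fragments within 3 of the centromere forming the
centromeric stratum, arm strata at distances 4–12 and 13+, and 2
fragments at each chromosome end forming the telomere cluster. Every
unordered fragment pair is an independent Bernoulli draw with a
class-specific probability: cross-chromosome centromeric contacts at
p_cen = 0.25, same-stratum arm contacts at p_stratum = 0.06 attenuated
by a factor 0.5 per stratum away from the centromere (rosette contact
density falls off along the arms; without the decay the two arm strata
produce clique-size classes with indistinguishable mean replication),
cross-chromosome telomeric contacts at 0.15, linear-neighbour contacts
at 0.6, and uniform background noise at 0.002. Each realized edge draws
an FDR label from its class's tier mix (60% of structural edges, 10% of
noise edges, score below 10⁻⁴; the rest between 10⁻⁴ and 10⁻²), so the
10⁻⁴ network is nested inside the 10⁻² network on every draw. FDR values
are tier labels, not outputs of a contact model — the package's scope
starts downstream of significance calling.

Tracks are generated from the planted truth: replication percentage
80 − 12·stratum + N(0, 2.5²) (centromere-proximal loci replicate early);
ChIP counts Poisson with rate 10 + 3·(cross-chromosome degree) emulating
a cohesin-like factor against a flat Poisson(20) control; point-like
centromere and telomere intervals at the planted positions; and a
planted factor placed inside centromeric-community fragments at rate 0.6
versus 0.05 elsewhere.

What the generator does *not* emulate: distance-dependent contact decay
within arms, restriction-fragment length heterogeneity, mappability
artifacts, the differing probability models behind inter- and
intra-chromosomal significance calls, and polymer constraints. Passing
the end-to-end tests therefore demonstrates that the algorithms recover
planted block structure of this kind at realistic sparsity — not that
any particular biological dataset will show it.

## Problem sizes and numerical choices

The validation experiments use: 100 random graphs (n ≤ 30) for the
modularity oracle at 10⁻¹² tolerance; 50 random graphs (n ≤ 15) against
subset-enumeration clique oracles; the 6-node bridged-triangle graph
whose 203 partitions are enumerated exhaustively (optimum Q = 5/14);
4-block stochastic block models (25 nodes/block, p_in = 0.3,
p_out = 0.01) over 20 seeds; null self-consistency at n = 60, m = 150
with 50 trials × 500 replicates; exact Fisher enumeration over all 2×2
tables with total ≤ 40; and 20 fixed-seed rosette replicates for the
end-to-end recovery statistics. These sizes were chosen so the whole
suite completes in a few minutes on one CPU while keeping every check at
full strength.

Tie-breaks and degenerate inputs are fixed throughout: equal-gain
Louvain moves go to the lowest community id; equal-sized components to
the one with the smallest member; unordered duplicate interaction
records collapse to the minimum FDR; self-interactions are rejected; an
empty post-filter edge set raises an explicit error rather than
returning an empty network; a degenerate null (sd = 0) reports z as
missing; Spearman trends with fewer than three classes or all-tied means
report as missing.

## Known limitations

Louvain output depends on sweep order; the seed fixes it, but different
seeds can yield slightly different partitions of weakly structured
graphs (the recapitulation and ARI statistics quantify this). Modularity
has a resolution limit — communities small relative to the network can
be absorbed — which subcommunity repartitioning mitigates but does not
remove. The G(n, m) null does not preserve degree sequences. Edge
weighting schemes (significance- or frequency-weighted networks) and
overlapping-community methods are out of scope.
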