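# Methods

This note documents the models and procedures `taxonet` implements, the
parameters that matter, the numerical choices that were genuinely open,
and what the synthetic benchmark does and does not establish.

## Quality control

**Decontamination by negative controls.** Each DNA-extraction batch
contributes a set of environmental samples and a set of negative-control
samples. For a feature with any reads in a batch's controls, let

    A_env  = (sum of counts over the batch's environmental samples) / n_env
    A_ctrl = (sum of counts over the batch's controls) / n_ctrl

The feature is a contaminant in that batch iff `A_env < fold × A_ctrl`
(default `fold = 10`, i.e. the environmental signal fails to exceed the
control signal by an order of magnitude); its counts are then zeroed in
every sample of that batch. Features never seen in controls are untouched
regardless of abundance. Two readings were possible for the control
denominator; we normalise controls by the number of controls (the
symmetric, per-sample-mean reading) and expose `control_norm="env"` for
the alternative. Removal is per batch by default (`scope="global"` zeroes
everywhere) because contamination is a property of an extraction batch.
Control columns are dropped afterwards, as are all-zero feature rows.

**Singletons.** A singleton is a feature whose total count across all
samples is 1 — the conventional, stricter reading. `mode="samples"`
instead drops features detected in exactly one sample.

**Rarefaction.** Each sample is subsampled to exactly `depth` reads
*without replacement* (multivariate hypergeometric draw on the count
vector), so per-feature means follow the hypergeometric expectation
`depth × count/total`. Samples below the target depth are dropped and
logged. The default depth of 9,957 reads suits amplicon libraries of a
few thousand to ~150k reads; the draw is seeded and deterministic.

**Pipeline order** is fixed: decontaminate → drop singletons → rarefy →
normalise. Decontamination must see raw counts and controls; rarefaction
must see a cleaned table so contaminant reads do not consume depth.

## Diversity

Shannon index uses the natural log (`base=2` available). Bray-Curtis and
Manhattan distances are computed between sample columns (scipy `pdist`)
and returned as `skbio.DistanceMatrix`. Sample dendrograms use complete
(maximum) linkage, written as an O(n³) agglomeration rather than scipy's
`linkage`: the spec of the method requires order-invariant output, so
equal-height merges are broken toward the lexicographically smallest
(left-representative, right-representative) leaf pair — scipy offers no
tie-break control. On tie-free inputs the merge heights match scipy
exactly (tested). Log₁₀ compositions replace zeros with half the smallest
non-zero proportion in the table ("auto"), a standard compositional
pseudo-count, overridable via `pseudo=`; the half-minimum keeps the
transform strictly increasing.

## Network construction

Nodes are taxa (relative abundance, in [0,1]) and metadata variables
(percent of observed range, in [0,100]; missing values preserved, never
imputed). For each unordered pair:

1. **Observational threshold.** A taxon is observed where its value is
   positive (an optional `min_detect` raises the floor); a metadata
   variable where it is non-missing. Pairs jointly observed in fewer than
   `min_obs = 5` samples are discarded *before* any correlation is
   computed, suppressing spurious correlations from sparse joint support.
2. **Correlation.** Spearman ρ = Pearson correlation of midranked values
   over exactly the jointly observed samples (pairwise-complete, matching
   the per-pair threshold); two-sided p from
   t = ρ√((n−2)/(1−ρ²)) on n−2 df, p = 0 at |ρ| = 1. Pairs with zero
   rank variance are skipped.
3. **Filter.** An edge requires |ρ| > `rho_min` (0.6) AND p < `p_max`
   (0.05), both strict, so boundary values are excluded. No
   multiple-testing correction by default (a raw-p filter); an optional
   Benjamini–Hochberg flag adjusts candidate p-values first. Nodes left
   without edges are excluded from the network — a variable that
   correlates with nothing simply does not appear.

Metadata–metadata edges are allowed by default (both are nodes on the
common scale); this is an interpretation, and taxa-only networks are a
flag away by omitting metadata.

## Edge-betweenness clustering

Edge betweenness is the number of all-pairs shortest paths through an
edge, with fractional credit when a pair has several equally short paths
(networkx, `normalized=False`). The Girvan–Newman loop removes one
highest-betweenness edge at a time, recomputing betweenness after every
removal, and records the component partition at each step; the returned
partition maximises Newman–Girvan modularity

    Q = Σ_c ( e_c/m − (d_c/2m)² )

evaluated on the *original* graph, where e_c is the intra-cluster edge
count, d_c the degree sum of cluster c, and m the total edge count.
Betweenness and modularity treat the graph as unweighted and ignore edge
sign: a correlation magnitude is not a path distance, and weighting would
change the method being implemented; the signed ρ is retained for
reporting. Determinism: betweenness values are rounded to 10 decimals
before the argmax so float noise cannot reorder ties, ties go to the
lexicographically smallest (u,v) edge, modularity ties to the partition
with fewest clusters and then the earliest in the removal sequence.
Cluster labels are 1..k ordered by each cluster's smallest node id.
Components of the input are never merged, so disconnected subnetworks are
distinct clusters by construction.

## Cluster summaries

Cluster abundance sums member-taxon proportions per sample; metadata
nodes contribute nothing; the remainder goes to an "unassigned" row so
the rows partition each sample's total. Prevalence is
100 × (#samples with ≥1 member detected)/(#samples), counting a sample
once however many members it holds, with all samples of the input table
as the denominator. Group contrasts use Welch's unequal-variance t-test
(Welch–Satterthwaite df) by default — the robust choice when only
"t-test" is specified — with a pooled-variance Student flag. Degenerate
inputs (both groups constant, equal means) return t = 0, p = 1.

## Synthetic benchmark

Per sample s and planted cluster c, a latent factor f_{c,s} ~ N(0,1);
taxon t in cluster c has log-abundance

    log a_{t,s} = base_t·ln10 + loading · f_{c,s} + ε,   ε ~ N(0, noise_sd)

with base_t log-uniform over two orders of magnitude (realistic
unevenness) and background taxa carrying independent noise only. The
per-sample expectation is softmax-normalised and counts are drawn
multinomially at depth ~ Poisson(depth_mean) — deliberately, so the
tables carry the compositional negative-correlation bias of real
relative-abundance data, which the network stage must tolerate. Coupled
metadata variables are f_{c,s} + N(0, 0.2); by default one gradient per
planted cluster plus one uncoupled variable. Contaminants get high
control counts (uniform 150–400) and trace environmental counts
(Poisson(3)), placing them far inside the tenfold removal rule.
Defaults (60 samples; 4 clusters × 8 taxa; loading 1.5 vs noise 0.5;
depth 20,000; 20 background taxa; 5 contaminants; 3 batches) describe a
moderate survey in which planted structure is recoverable but not
trivial: compositional closure induces inter-cluster correlations of
roughly −0.3 and background–background correlations near the 0.6
threshold.

What passing the benchmark shows: the pipeline's stages compose
correctly, the filters behave as specified, and planted covariance
blocks of realistic strength survive rarefaction and compositional
closure to be recovered (ARI ≥ 0.9 in ≥18/20 seeds at these settings).
What it does not show: robustness to real-world features the generator
omits — phylogenetic correlation among taxa, batch effects beyond
contamination, heavy-tailed depth variation, structured missingness in
metadata, or true ecological interactions that are not monotone
pairwise associations.

## Problem sizes and degenerate inputs

Default analyses in the tests and the acceptance script use 30–60
samples, ~30–60 features, and rarefaction depths of 1,500–10,000;
oracle comparisons use 200 random vector pairs and 100–140 random graphs
of ≤10 nodes — sizes at which the brute-force oracles are exact and fast.
Degenerate inputs fail loudly: empty tables, duplicate ids, negative or
non-integer counts, zero-total samples, all-shallow rarefaction, constant
metadata (dropped with a warning), zero-variance correlation pairs
(skipped), and edgeless graphs (modularity undefined) all raise or warn
with the offending row/column named.
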