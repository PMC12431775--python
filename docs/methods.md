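# Methods

`crelink` implements the downstream regulatory-genomics computations of a
single-cell multiome study of GABAergic/glutamatergic lineage bifurcation:
feature-to-gene linking within topologically associating domains (TADs),
conservation-weighted motif-site scoring, multi-evidence regulator and
target inference, corroboration of footprints against CUT&Tag peaks, and
apical–basal image-profile quantification. Everything is exercised end to
end on a synthetic multiome generator with planted ground truth.

## Coordinate conventions

All genomic coordinates are 0-based half-open (BED convention); GTF-style
inputs must be converted on read. Overlap between two intervals requires at
least `min_bp` shared bases (default 1). The TSS of a − strand gene is the
annotated gene end − 1 when derived from span annotation; the gene-table
reader expects an explicit `tss` column so downstream code never re-derives
it. When TADs overlap, a gene is assigned to the smallest TAD containing its
TSS — the analysis assumes one TAD per gene and this tie-break makes the
assignment deterministic. Conservation positions absent from a sparse
bedGraph score 0.

## Feature-to-gene linking and cCRE calling

For a gene *g* and a feature *f* inside *g*'s TAD, the observed statistic is
the Spearman correlation ρ_obs between *f*'s per-cell accessibility and
*g*'s per-cell log1p expression over the cells shared by the two matrices
(at least 30 required). ρ_obs is standardized against a matched background:

    z = (ρ_obs − mean(ρ_bg)) / sd(ρ_bg),   p = 2 Φ(−|z|)

where ρ_bg are the correlations of 200 background features with the same
gene. Background features come from the query feature's chromosome, ranked
by decile distance in mean accessibility and in width (closest first, seeded
random tie-break). GC-content matching is not attempted — it would require
sequence, which the pipeline deliberately does not consume. Features passing
|z| > 2 AND p < 0.05 (both strict) inside the TAD are the gene's candidate
cis-regulatory elements (cCREs); target calling uses the stricter p < 0.01.
The normal-tail p is paired with the z-score rather than a permutation p,
matching the joint z/p thresholds the statistic is used with.

## Conservation

A base is *conserved* when its phastCons-style score is ≥ 0.5. Enrichment of
conserved bases inside a region class is a Fisher's exact test
(two-sided, minimum-likelihood) on the full 2×2 base-count table of one
chromosome; overlapping regions are flattened first so no base is counted
twice, and the four cells always sum to the chromosome length. A motif
site's conservation is the weighted mean Σ w_j c_j / Σ w_j with w_j the
maximum nucleotide probability of PWM column j and c_j the per-base score;
for − strand sites the weight order is reversed (complementing is
unnecessary because only column maxima enter). The score is invariant to
uniform weight rescaling and bounded by the per-base min and max.

## Regulator identification

A TF is a regulator of a selector gene in a cell group when, simultaneously:

1. the TF has a bound footprint (score strictly > 0) at a motif site inside
   one of the gene's cCREs;
2. the site's weighted conservation is > 0.5;
3. the TF gene's mean log1p expression over the group's cells is > 1.2.

"Bound" is strictly positive, so an exactly-zero footprint score never
qualifies. Per-group mean expression is the arithmetic mean of log1p values.
An optional fourth filter (feature accessibility > 0.06) is exposed but off
by default: it belongs to the footprint dot-plot display filter, not the
regulator conditions. Each call carries its full evidence (cCRE ids, site
ids, conservation values, TF group mean, minimum supporting link p).

Regulator sets of several selector genes are compared through their full
intersection partition. For each TF in the common intersection, the reported
significance is the maximum over genes of the minimum link p among that
gene's supporting cCREs. The overlap itself is tested by permutation: each
iteration draws one uniform without-replacement set per selector (same
sizes) from the candidate-TF universe and records the intersection size;
the empirical p is the proportion of iterations reaching the observed
intersection, and when none does, the upper bound 1/(N+1) is reported with a
flag. N defaults to 1,000,000; the test is vectorized in chunks of 20,000
iterations (boolean membership matrices, argpartition sampling) and runs the
default configuration in under a minute on one CPU. The candidate universe
is an explicit input — the analysis does not guess which TFs were eligible.

## Target identification and characterization

A gene is a target of a selector TF when some feature in the gene's TAD
satisfies all four of: (i) a motif site of the TF in the feature carries a
bound footprint in GA1_2 or GL1_2; (ii) the feature is linked to the gene
with |z| > 2 and p < 0.01; (iii) the site's weighted conservation is > 0.5;
(iv) a CUT&Tag consensus peak of the TF overlaps the feature by ≥ 1 bp.
Every condition can be disabled independently, and disabling is monotone:
the called set can only grow (asserted on synthetic bundles).

Differential expression between GA1_2 and GL1_2 uses a two-sided Wilcoxon
rank-sum test per gene (exact enumeration for small tie-free groups, normal
approximation with tie correction otherwise);
log2FC = log2((mean(expm1 A)+1)/(mean(expm1 B)+1)) on the de-logged scale
with a +1 pseudocount; Bonferroni adjustment by default (Benjamini–Hochberg
by flag). Targets are GABA-specific when log2FC > 0.5, GA1_2 mean > 0.5 and
GL1_2 mean < 0.5 (log1p), glut-specific under the mirrored rule, otherwise
unclassified. Characterization reports feature counts by link sign, gene
counts by nearest TSS-feature distance (nearest feature edge, 0 inside) in
half-open bins [0, 5 kb), [5 kb, 50 kb), [50 kb, ∞) — the printed bin labels
do not state boundary rules, so half-open at 5 and 50 kb is the package's
choice — and per-bin expression variability, defined as the standard
deviation of per-cell-group mean expression (the variability metric is not
pinned down by its source; SD of group means is this package's definition,
CV and variance were the alternatives).

The GSEA uses the classic unweighted running sum (hits +1/|S∩R|, misses
−1/(n−|S∩R|)) over the GA1_2-vs-GL1_2 log2FC axis, restricted upstream to
genes with adjusted p < 0.01 and an expressing fraction ≥ 0.1 in either
group. Because both ends of the axis are meaningful, two leading edges are
reported: edge A = set members at or before the running-sum maximum
(GA-side), edge B = members at or after the minimum (GL-side). The
unweighted statistic was chosen for determinism and exact hand-verifiable
arithmetic; a weighting exponent would be a one-line change.

Cross-modality cluster matching filters each modality's cluster markers to
adjusted p < 0.05 and the top 25 by log2FC, takes the shared gene-name pool
of the two modalities as the universe N, and scores each cluster pair by the
hypergeometric upper tail P[X ≥ k] of the marker overlap k.

## Footprint / CUT&Tag corroboration

Per TF: number of consensus peaks, number of bound motif sites (positive
footprint in ≥ 1 cell group), percentage of peaks overlapping ≥ 1 bound
site, percentage of bound sites overlapping ≥ 1 peak (min 1 bp overlap; a
site counts once however many groups bind it or peaks contain it). The
position density places each (peak, contained site) pair at
(site midpoint − peak start)/peak width, clipped to [0, 1]; a site inside
two overlapping peaks contributes one position per peak but still counts
once in the percentages. The midpoint stands in for "footprint position",
which is otherwise undefined for a multi-base site.

## Laminar (apical–basal) quantification

The ventricular surface (VS) is the circle through three manually picked
points (circumcircle via a 3×3 linear solve; collinear points are an error).
Each cell's distance from the VS is (|centroid − centre| − radius) divided
by the average cell diameter, estimated as the mean equivalent-circle
diameter 2√(area/π) over all ROIs. Cells apical to the circle get negative
distances and are kept (flagged by sign) rather than dropped. Per channel
and image, signals at or below the 0.25 quantile are set to 0 — zeroed, not
dropped, so cell counts agree across channels. Channels are divided by their
replicate means (making per-replicate means exactly 1); trends along the
distance axis use a centred sliding mean of window 12 that shrinks at the
boundaries (window 1 is the identity). The mean-normalization realizes the
replicate "normalize and align" step, which has no quantitative definition
in its source; LOESS bands are display-layer smoothing and are replaced by
the sliding-mean series.

## Synthetic data generator

The generator emulates the statistical shape of the real inputs at desk
scale; its defaults are the package's study conditions:

| parameter | default | rationale |
|---|---|---|
| chromosomes | 2 × 400 kb | two chromosomes exercise per-chromosome logic |
| TADs | 12 per chromosome (33 kb) | enough TADs to give each linked gene its own |
| genes / features | 60 / 600 | ~25 features per TAD, TAD-scale feature density |
| cells | 8 groups × 40 | the merged lineage groups PRO1_2 … GL5 |
| TFs | 8 (3 selector TFs with CUT&Tag) | mirrors a three-selector design |
| planted links | ~30–40 (4 per selector) | a minority of features carry signal |
| accessibility | Gamma(2, 0.15) per cell + 1.5 activation | positive, right-skewed, clear on/off contrast |
| expression | 4·σ((d−0.9)/0.4) of the signed mean link drive + N(0, 0.25) noise, clipped ≥ 0 | log1p-scale values in 0–4; strictly monotone in each link |
| conservation | Beta(1, 8) 25-bp tiles; Beta(24, 6) at functional sites | background mean ≈ 0.11, site mean 0.8 |
| footprints | bound ⇒ 0.05 + Gamma(2, 0.4); else 0 w.p. 0.3 or −Gamma(2, 0.3) | exact zeros exercise the strict > 0 rule |
| CUT&Tag | sensitivity 0.9, 5 false peaks/Mb, ±150 bp peaks | most but not all bound sites corroborated |

Negative-effect links subtract their accessibility term inside the logistic
drive and activate in the complementary lineage branch, so accessibility and
expression move in opposite directions. Decoy motif sites exercise every
filter: they are unbound, or bound with per-base conservation capped below
0.45 (deliberately sub-threshold, so "non-functional" is unambiguous).
Linked genes occupy dedicated TADs: with several group-structured genes
sharing a TAD, a feature planted for one gene genuinely correlates with its
neighbours and the planted truth would stop being identifiable — a design
constraint of the generator, not a property of the inference.

`GroundTruth` (planted links, regulator sets per selector × group, target
sets per selector TF, bound sites per group) is derived by applying the
evidence rules to the realized planted evidence with plain loops,
independent of the analysis modules, so recovery tests compare two separate
routes. A `noiseless` configuration (expression noise 0, CUT&Tag sensitivity
1, no false peaks) defines the exact-recovery conditions under which the
regulator and target calls must equal the planted sets exactly.

What the generator does **not** emulate: read-level sampling noise and
dropout structure, sequence content (no GC composition, no real motif
matches), chromatin-state autocorrelation along the genome, doublets and
batch effects, or correlated genes sharing regulatory elements across TADs.
Passing recovery tests therefore demonstrates correctness of the inference
logic under the stated generative model, not performance on real multiome
data.

## Numerical choices and degenerate inputs

* Strict inequalities throughout (|z| > 2, p < 0.05/0.01, conservation
  > 0.5, expression > 1.2, footprint > 0), following the printed rules.
* Constant accessibility or expression vectors raise a
  degenerate-correlation error (skipped with a warning inside batch runs);
  a zero-variance background is an error, never a silent z = ∞.
* Fisher's odds ratio with a zero cell is flagged undefined (NaN); the p
  value is still returned.
* The permutation p is never 0: the 1/(N+1) bound replaces it.
* Pipeline outputs avoid timestamps and absolute paths, and all randomness
  descends from the configured seed, so two runs with the same config are
  byte-identical (checked by sha256 manifest).

## Problem sizes

The default bundle (60 genes × 600 features × 320 cells) links all genes in
about two seconds; the 20-seed recovery study and the 10⁶-iteration
permutation test each run in about a minute on one CPU. These sizes were
chosen so the full test suite and the acceptance computation complete in a
few minutes while every statistic still operates far from small-sample
degeneracy.

## Known limitations

* The background-matching scheme for link z-scores (chromosome + decile
  matching on mean accessibility and width) is a self-contained surrogate
  for the matched-background z-scoring of established peak-to-gene linkers;
  it does not reconstruct any specific tool's covariates.
* Links are computed across all cells, not per group; group-specific
  regulation enters through the footprint and expression conditions only.
* The hypergeometric cluster-matching treats marker lists as unordered
  sets; rank information within the top-25 lists is discarded.
* Image segmentation itself is out of scope: the laminar module starts from
  an ROI table and trusts its areas and centroids.
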