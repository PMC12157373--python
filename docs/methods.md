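# Methods

This note documents the models, parameters and numerical choices behind
`neolung`, and what its synthetic-data validation does and does not
establish about real tissue data.

## Data model and quality control

A transcript record carries a feature (gene symbol or one of the two
control classes, "Negative codeword" for decoding errors and "Negative
probe" for chemistry background), x/y coordinates in µm, a phred-like
quality value `qv`, a cell assignment (`cell_id`, or `"UNASSIGNED"`), and
an `overlaps_nucleus` flag. Cells are segmented nuclei: a transcript is
assigned to a cell when it overlaps the nuclear boundary, so the retained
expression signal is nuclear-anchored. Transcript filtering keeps
`qv >= 20`, assigned, nuclear-overlapping records; we treat the nuclear
overlap flag as a *keep* condition because expression matrices are built
from transcripts partitioned into segmented nuclei — the package exposes
`drop_controls` so control records can be carried into cell-level QC,
where they belong, and dropped before expression analysis.

Cell filters are strict inequalities as printed in the upstream QC recipe:
more than 10 transcripts, more than 5 unique genes, nuclear area under
75 µm², under 15% negative codewords, exactly 0% negative probes. Control
transcripts count toward each cell's total (denominator of the control
percentages) but not toward unique gene counts.

Developmental stages follow gestational age at birth: early canalicular
16–18 wk, late canalicular 21–24 wk, saccular 25–35 wk (a documented
switch moves the lower bound to 26, an alternative grouping in use),
alveolar ≥36 wk. Gaps (e.g. 19–20 wk) return an explicit `unstaged` label
rather than a silent assignment; rare-disease samples are always their own
group. All distances are 2-D; any z coordinate is ignored.

## Cell-type proximity enrichment

Every cell is an anchor; all cells within a 60 µm radius are recorded with
distance and angular orientation (angles are emitted for completeness; no
downstream statistic consumes them). Two proximity definitions are
supported: `nearest_one` (default) marks a candidate cell proximal to type
A when it is the single nearest neighbor of at least one A anchor;
`all_within_radius` marks every within-radius candidate. The default
matches the operational definition used for the per-pair odds ratios
(enrichment of B as the *single nearest neighbors* of A); the radius rule
is provided as an option.

For an ordered pair (A, B) the unit of analysis is the candidate cell
(every cell not of type A, counted once per group): rows are
proximal/non-proximal, columns are B/not-B. Fisher's exact test admits no
covariates, so "using cell type as a covariate" is realized as
stratification — one 2×2 test per ordered pair. The two-sided p-value is
the exact hypergeometric tail probability (scipy); the log odds ratio uses
the Haldane–Anscombe 0.5 correction whenever a cell is zero, with a Woolf
logit 95% CI on the corrected table, and a degeneracy flag for zero
margins. Tests are run within each developmental stage (sections pooled;
neighbor pairs never cross section boundaries, as tissue cores are
physically separate) and within each rare-disease sample separately;
Benjamini–Hochberg FDR is computed across all pair × group tests of one
screen. Pairs present in all four stages and significant (FDR < 0.1) in at
least one are binarized by the sign of the logOR per stage (an exact zero
binarizes to "+" and is flagged; it has probability zero for continuous
data) and grouped by exact sign vector via hierarchical clustering on the
binary (Hamming) distance matrix cut at zero — at most 16 patterns.
Pattern ids follow the descending stepwise order: "+" sorts before "−",
earliest stage most significant. Ties for "single nearest neighbor" break
deterministically by smallest neighbor cell id.

## Niche detection

**Cell-based.** Each cell's neighborhood is the cell-type count vector of
its 10 nearest neighbors (the cell itself included by default;
configurable), computed per section. k-means (k-means++ initialization, 10
restarts, fixed seed) with 11 clusters partitions the cohort jointly. The
composition matrix is sorted by cell id before fitting so labels cannot
depend on input row order.

**Transcript-based.** After removing low-quality (qv < 20) and control
transcripts — unassigned transcripts stay, the method is
segmentation-free — transcripts become nodes of a per-tissue graph with
edges between transcripts within 3 µm; connected components smaller than
10 nodes are pruned as likely background. Per tissue, min(5000, n) root
nodes are sampled without replacement, their 3-hop neighborhoods
collected, and all existing edges among selected nodes induced; tissues
are disjoint-unioned into one training graph. The encoder is a 2-layer
GraphSAGE-style network with both hidden sizes 50 and fan-outs 20 and 10:
node inputs are one-hot gene identities (the only per-transcript covariate
available without segmentation), and each layer pools a fan-out sample of
neighbors with softmax-normalized learned attention scores (a learned
query vector over projected neighbor features) before adding the node's
own projection. Training is unsupervised binary edge prediction: sampled
true edges against uniform negative pairs (1:1), scored by the sigmoid of
the embedding inner product, binary cross-entropy loss, Adam (default
learning rate 0.01, 30 epochs, up to 20,000 positive edges per epoch).
Forward and backward passes are written directly on NumPy arrays; all
sampling is seeded, so training and inference are deterministic given the
seed. A non-learned fallback embedding — exp(−d/5 µm)-weighted gene
composition of transcripts within 10 µm, L1-normalized — exercises
everything downstream of the embedding deterministically.

Embeddings are clustered with a full-covariance Gaussian mixture (seeded,
`reg_covar` 1e-5, hard labels by maximum posterior) into 11 niches (the
cluster count is a configuration input; nothing in the pipeline selects
it). Labels are summarized on a pointy-top hexagonal lattice of
flat-to-flat width 5 µm; bins with fewer than 10 transcripts are excluded;
each retained bin takes the modal transcript label with ties broken by the
lowest label id. Cell centroids inherit the label of their closest
retained bin; centroids farther than 3 bin-widths from every retained bin
get an explicit unassigned label (−1) rather than a nearest-at-any-distance
transfer across empty tissue. Exact centroid-to-bin distance ties go to
the bin earlier in (q, r) axial order.

## Differential expression

Counts are summed over all cells of an (individual, cell type) — both
technical replicate sections of a sample pool into one column — then
normalized to counts-per-10k per column and log1p-transformed. The count
sum is the standard pseudobulk aggregate; the normalization constant and
transform are configurable in code. Genes are kept per cell type when
detected (count > 0) in strictly more than 20% of that cell type's cells,
pooled across included individuals (a per-individual variant is a
documented alternative). The GA/LS model excludes samples under 21 weeks
gestation and rare-disease samples; fewer than 3 remaining individuals is
a refusal, not a silent fit.

Per (gene, cell type), the covariate model is ordinary least squares of
log-normalized pseudobulk on an intercept plus gestational age and life
span in weeks (or a single disease-severity term, 0–3); coefficients are
reported per unit of the term on natural-log expression, with two-sided
t-tests and BH FDR within each (cell type × term) family (per-cell-type
families match how per-cell-type gene counts are reported). Covariates are
not standardized. Rank-deficient designs raise a collinearity error naming
the cell type; genes constant across individuals report coefficient 0 and
p = 1, flagged. Immune cell types are excluded by default — immune nuclei
are typically surrounded by structural cells and accumulate contaminating
transcripts that masquerade as covariate associations — via a flag, not
hard-coding.

The two-group contrast (e.g. immature AT2 vs AT2) moderates per-gene
variances by empirical Bayes: a scaled inverse-chi-square prior is fitted
to the observed residual variances by moment matching on the log scale
(prior df via trigamma inversion; infinite prior df pools to the mean
variance), posterior variances are the df-weighted blend, and moderated t
statistics use prior + residual df capped at the pooled residual df. The
implementation is validated against the reference R implementation
(limma) to ~1e-9 in a test; the R package is never used as the
implementation.

Two-level FDR intersection: a (gene, cell type) pair overlaps terms T1 and
T2 when it passes FDR < 0.1 in one and FDR < 0.2 in the other; the triple
overlap requires every pair of terms to overlap, which implies membership
in every pairwise overlap set.

## Synthetic cohorts and what the tests show

The generator emulates the cohort design this framework targets: 17
samples (two early-canalicular under 21 wk, eleven spanning 21–40 wk GA
and 0–16 wk life span, four rare-disease including a long-lived explant),
two adjacent sections per sample as technical replicates, a
marker-structured gene panel (base + custom, e.g. 246 + 97 disjoint = 343
symbols), and a 40-type / 4-lineage taxonomy scalable down to 4 types for
fast tests.

Per section, the square tissue area is tiled into rectangular regions with
their own cell-type composition and optional per-gene log-expression
boosts (spatial niches); cell centroids are uniform within their region.
Planted attraction displaces each type-B cell toward its nearest type-A
cell by the factor e^(−c) (repulsion for c < 0) — simple and monotone in
c. Per-cell counts are negative-binomial (NB is the standard overdispersed
count model; dispersion 0.3 by default, Poisson at 0) with log-mean linear
in GA (centered at 30 wk), LS and DX, plus a per-(sample, gene) lognormal
biological noise shared across a sample's replicates (SD 0.05).
Transcripts scatter uniformly in a disc of the nuclear radius around the
centroid with qv in 25–45. QC artifacts are additive records at binomial
fractions of the clean count: low-QV (4%), unassigned (5%), negative
codewords (0.8%), negative probes (0 by default, since any assigned
negative probe disqualifies its host cell). Ground truth records every
cell's type and region, every record's artifact class, and the planted
plans.

Benchmark conditions (`neolung.benchmarks`) are fixed once: attraction
coefficient 3 (the attracted cell lands ~20× closer to its anchor);
regression effects ±0.06/wk (GA) and ±0.08/wk (LS), which is 3× the
pseudobulk residual SD (~0.14 on log expression) over the covariate
spread, planted on structural cell types; an 11-region
composition-distinct section for the cell-niche stage; and a ~50k
transcript, 4-region gene-composition section (disjoint 4-gene blocks
boosted +2.5) for the transcript-niche route. Problem sizes are desk
scale — hundreds of cells per section and tens of thousands of transcripts
— chosen so the full validation runs on a single CPU; the statistical
structure, not the data volume, is what the recovery tests probe.

What the synthetic data does *not* emulate: segmentation errors and
doublets, irregular tissue geometry and holes, spatial expression
gradients within a region, cell-type-dependent nuclear sizes, optical
crowding, or contamination from neighboring cells (immune-contamination
handling is therefore exercised only as a configuration, not
diagnosed). Passing recovery tests show the estimators are correct and
calibrated under the generative model, not that real-tissue effect sizes
will be detectable at these sample sizes.

## Numerical and design notes

- Fisher p-values are validated against an exhaustive fixed-margins
  hypergeometric enumeration (log-gamma arithmetic) on all 2×2 tables with
  total ≤ 40, to 1e-12.
- k-means and mixture seeds, subgraph and negative-edge sampling, and all
  generator draws derive from explicit integer seeds; the pipeline
  orchestrator derives per-stage seeds from one global seed, and reruns
  are byte-identical (hash-checked manifests).
- Embedding training at full study scale (tens of millions of nodes) is
  out of scope; the encoder trains at reduced scale on sampled subgraphs.
- Niche label ids are arbitrary; all downstream summaries (proportions,
  concordance) are invariant to relabeling.
- The CLI (`neolung simulate|qc|proximity|cniche|tniche|de|overlap|run|report`)
  is a thin layer over the library; exit behavior distinguishes validation
  errors (raised before compute) from stage failures (named in the
  manifest).
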