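# Methods

This note documents the models and procedures implemented in `igrn`,
the defaults and why they were chosen, what the synthetic generator
does and does not emulate, and the numerical conventions that make runs
reproducible.

## Quality control and normalization

Cells are retained when all three gates pass: mitochondrial fraction
≤ `max_mito_fraction` (default 0.20, genes identified by the `MT-`
symbol prefix, configurable), total UMI within [`umi_min`, `umi_max`]
(defaults 200 and 60 000, inclusive), and detected genes strictly
greater than `min_genes` (default 200). The gene-count bound is read as
exclusive and the UMI bounds as inclusive; filtering is idempotent.
These defaults assume a genome-scale panel (~20 000 genes). On targeted
or synthetic panels of a few hundred genes the detected-gene and UMI
floors must be scaled down through the run config — the packaged test
bundles use `umi_min = 50`, `min_genes = 50`.

Normalization is `ln(1 + count × scale_factor / cell_total)` with
`scale_factor = 10 000`; an all-zero cell maps to zeros, and the zero
pattern is preserved exactly. Per-gene z-scaling is a separate, optional
step so downstream stages can choose their input scale.

Highly variable genes are ranked by standardized variance: a quadratic
trend of log10 variance on log10 mean (over expressed genes) supplies
the expected spread at each gene's mean; per-cell z-scores against that
expectation are clipped at √n_cells, and genes are ranked by the
variance of the clipped scores. Ties break lexicographically so the
ranking is deterministic.

## Differential expression

One-vs-rest Wilcoxon rank-sum within a compartment (the receiver
subclusters plus the reference epithelium, in the pipeline). The
two-sided p-value uses the exact null distribution whenever there are
no ties and the pooled sample size is ≤ 25, otherwise the normal
approximation with tie and continuity corrections; a statistic exactly
at the null center returns p = 1. Fold change is the natural-log ratio
of back-transformed group means with pseudocount 1
(`ln(mean(e^v − 1) + 1)` per group), the convention under which the
screening threshold 0.15 is defined. The screen keeps genes with raw
p < 0.05 and ln-FC > 0.15; the threshold applies to the raw p-value
(matching the upstream tool's parameter semantics) while BH-adjusted
p-values are reported alongside.

## CNV profiling and malignancy calls

The residual pipeline, in order: drop genes whose mean raw expression
across all cells is below `cutoff` (default 0.1); log-normalize; order
genes by (declared chromosome order, start); center each gene on the
reference-cell mean; clamp to ±3; moving-average smooth over `window`
genes (default 101, odd) strictly within each chromosome, the window
shrinking at chromosome ends; re-center each cell on its own median;
and subtract the reference cells' mean smoothed profile, which pins the
reference mean residual at exactly zero. Chromosome order is the order
of first appearance in the gene-position table, never alphabetic.

The per-cell CNV score is the cumulative squared residual Σᵍ r(c,g)²
over the whole profile. Squared (rather than absolute) deviation is the
standard choice for expression-derived CNV burden; no sub-profile
"region" is singled out because segment boundaries are not part of the
model. A subcluster is called malignant when a one-sided rank-sum test
(subcluster scores greater than reference scores) gives p < α (default
0.05) *and* its median score exceeds the reference median — the claim
is directional, so the test is one-sided. Profiling and calling are
restricted to the epithelial compartment (candidate malignant
subclusters plus the normal-epithelium reference); immune populations
are not CNV-scored, since cell-type expression programs would confound
dosage inference.

Note one inherent asymmetry: because reference cells participate in the
mean they are centered on, observation-cell residuals carry slightly
more sampling variance than reference residuals (a factor ≈ (1 + 1/n)
vs (1 − 1/n)), making the null call rate mildly anticonservative at
small n. The null-calibration runs bound this empirically.

Subcluster similarity is the Spearman correlation between subcluster
mean residual profiles; a constant mean profile yields a missing value
rather than an error.

## Spatial statistics

`kdist` is the mean Euclidean distance from a query unit to its k
nearest reference units (default k = 10), in native coordinate units;
distance ties break by reference unit-ID order so results are
deterministic, and k is truncated with a warning when it exceeds the
reference size. Spot composition scores are marker-set means of
log-normalized expression, z-scored across spots per cell type.

The invasive front is operationalized statistically: a malignant
subcluster is "front" when its per-cell kdist-to-immune values are
significantly lower (one-sided rank-sum, α = 0.05) than the pooled
values of all other malignant subclusters. With a single subcluster
there is nothing to compare and calls are reported as undefined. This
is a deliberate, testable replacement for visual front identification;
externally supplied trajectory-state labels can be used to restrict the
candidate set before calling.

## Regulons and activity

TF–target co-expression is |Spearman| across the receiver subcluster's
cells, computed by rank-transforming once and taking normalized dot
products; constant genes score 0; pairs below `min_score` (default 0.1)
are dropped. Rank correlation was chosen over boosting-based importance
for determinism and adequacy at this scale — an importance scorer is a
clean plug-in point. Scored pairs are then intersected with
motif-supported TF–target priors and grouped into regulons.

Per-cell activity is the area under the target recovery curve within
the top ⌈`top_fraction` × n_genes⌉ ranks of the cell's expression
(default 0.05), normalized by the best achievable area, so activity is
1 when the regulon's targets fill the top ranks and 0 when none enters
the window. Ranking ties break lexicographically by symbol. The
statistic depends only on within-cell ranks, hence is invariant to any
rank-preserving rescaling. A regulon is *active* in the receiver when
more than `min_fraction_active` (default 0.25) of receiver cells exceed
the regulon's own threshold, mean + 2·sd of its activity across all
cells — the standard binarization family for this statistic.

## Ligand–receptor scoring and network assembly

For each prior (ligand, receptor) pair passing the expression gate
(ligand expressed in > `pct_min` of sender cells and receptor in
> `pct_min` of receiver cells, default 0.10), the interaction score is
the mean of the two population means. Significance comes from jointly
permuting the sender/receiver split of the pooled cells `n_perm` times
(default 1000): p = (1 + #{permuted ≥ observed}) / (n_perm + 1), so the
smallest attainable p is 1/(n_perm + 1). All permutations derive from a
single seed.

The preliminary network is assembled layer by layer: ligands with
permutation p < 0.05; their prior receptors expressed in the receiver;
prior TFs of those receptors expressed in the receiver; prior targets
of those TFs. A symbol takes exactly one layer role. Every validated
network is then restricted to *path support*: a node survives only if
it lies on at least one complete ligand → receptor → TF → target path
(forward reachability from the ligand layer intersected with backward
reachability from the target layer — in this strictly layered DAG the
intersection is exactly the set of on-path nodes).

Pruning keeps a TF only if it heads an active regulon, and a TF–target
edge only if the pair is in that regulon *and* the target passed the
receiver DEG screen, followed by the same path-support cleanup. Pruned
edges are a subset of preliminary edges by construction, asserted on
every run. "Signal" counts are reported per layer as edge counts
(nodes and paths are also derivable via `extract_paths`); networks are
built per (sender population × receiver subcluster).

## Synthetic data generator

The generator emulates a tumor single-cell study with a matched spatial
section. Counts are negative binomial (variance μ + αμ², dispersion
α = 0.3) with lognormal gene means (σ_log = 0.5, median 1) and a
lognormal cell size factor (σ_log = 0.3). Default conditions: 600 genes
over 6 chromosomes; populations macrophage and T cells (senders, 150
cells each), malignant subclusters m1 and m2 (receivers, 150 each) and
normal epithelium (reference, 150); 5 planted cascades with effect
ln-FC 1.0 (3 targets each); 20 decoy prior chains whose genes carry no
signal; a 1.8× copy-number gain over 60 contiguous position-ordered
genes in each of m1 and m2; and a disc/annulus/ring layout — m1 in the
tumor core, m2 in the front annulus, immune cells in a surrounding
ring, reference epithelium in the outer stroma.

Design choices that matter for recoverability, fixed once:

* **Planted genes are scattered** across the genome with a golden-ratio
  coprime stride (outside CNV segments). Signaling genes are not
  genomically collinear, and a contiguous block of co-shifted genes
  would masquerade as a focal copy-number gain.
* **Cascade co-expression is an on/off latent activity**: the TF and
  its targets are jointly boosted in a fixed fraction (50%) of the
  receiver subcluster's cells, with the boost calibrated so the
  subcluster-mean ln-FC equals the stated effect. This induces strong
  rank correlation for regulon scoring and a cleanly bimodal activity
  distribution for the mean + 2·sd binarization — the behaviour of a
  pathway that is switched on in a cell subpopulation.
* **Planted-gene baseline mean is 1.5** (a solidly detected gene), so a
  boosted cell reliably pulls cascade genes into the top of its
  ranking.
* The ligand is up-shifted in its sender population; the receptor is
  up-shifted uniformly in the receiver subcluster (it gates and scores
  but does not participate in the latent correlation).

The canonical **null configuration** removes every planted structure —
no cascades, no CNV segments, no marker programs, and an exchangeable
spatial layout where both receiver subclusters span the same band — so
each screening stage is genuinely under its null; decoy priors remain
as the unsignaled pairs whose p-values should be uniform.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects, cell-cycle structure, realistic Visium spot gridding, genuine
motif databases, or the gene-gene correlation structure of real
transcriptomes. Passing recovery tests therefore demonstrates that the
pipeline's statistics detect the signals they model at realistic noise
levels and respect their null calibration — not that real-data gene
lists would be reproduced.

## Problem sizes and runtime

Recovery runs use the default conditions above (600 genes × 750 cells,
five seeds); null calibration uses a reduced bundle (300 genes, 60
cells per population, permutation count 199 — p-value granularity
1/200, sufficient to resolve the 0.05 level) over twenty seeds. The
full acceptance script completes in well under a minute on one CPU; the
test suite in well under a minute as well.

## Reproducibility conventions

A single integer seed governs every stochastic component; per-stage
seeds are derived from it by hashing stage names (always below 2³¹).
Identical inputs and seed give byte-identical network files. All
tie-breaks (HVG ranking, activity ranking, kdist neighbors, path
ordering) are lexicographic and documented at the function level.

## Known limitations

* Gene symbols are harmonized by uppercasing only; no alias resolution.
* The CNV score sums the whole profile; focal events in a large quiet
  genome dilute accordingly, and the malignancy test is mildly
  anticonservative at small reference sizes (see above).
* The front rule compares malignant subclusters against each other; it
  cannot label a lone subcluster, and "front" is relative to the
  supplied immune coordinates.
* The L-R permutation test permutes population labels only within the
  sender ∪ receiver pool, matching the score's ingredients; covariates
  (sample, batch) are not modeled.
* Regulon inference uses marginal rank correlation, not conditional
  (multivariate) importance; indirect correlations can inflate regulons
  when priors are permissive.
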