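# igrn — intercellular gene regulatory networks from single-cell data

`igrn` builds and prunes **intercellular gene regulatory networks**:
directed multilayer networks that chain a *sender* cell population's
ligand to a *receiver* population's receptor, transcription factor (TF)
and target genes,

```
ligand  --L-R-->  receptor  --R-TF-->  TF  --TF-target-->  target
(sender)          (receiver)
```

It is aimed at tumor-microenvironment studies — for example, how
macrophages or T cells at the invasive front signal into malignant
epithelial subclusters — but every stage is generic single-cell
machinery:

* **QC and normalization** — cell filters on mitochondrial fraction
  (≤ 20%), total UMI (200–60 000) and detected genes (> 200);
  ln(1 + CP10k) normalization; variance-stabilized HVG ranking.
* **CNV-based malignancy calling** — smoothed, reference-centered
  expression residuals along genomic position; per-cell cumulative CNV
  score Σ residual²; one-sided rank-sum calls against a
  normal-epithelium reference; Spearman similarity of subcluster
  profiles.
* **Spatial front inference** — `kdist`, the mean Euclidean distance
  from each cell to its k nearest cells of a reference population; a
  malignant subcluster is called *front* when its kdist-to-immune
  distribution is significantly lower than its peers'.
* **Ligand–receptor scoring** — score = (mean ligand expression in
  sender + mean receptor expression in receiver)/2 over expression-gated
  prior pairs, with a label-permutation p-value
  p = (1 + #{perm ≥ obs})/(n_perm + 1).
* **Regulons** — TF–target co-expression (|Spearman|), motif-prior
  pruning, per-cell AUC activity (area under the target recovery curve
  in the top 5% of each cell's ranking), and mean + 2·sd binarization.
* **Network assembly and pruning** — a preliminary three-layer network
  from priors and screens (DEG screen: Wilcoxon rank-sum p < 0.05,
  ln-fold-change > 0.15), then pruning to active-regulon TFs and DEG
  targets. Pruned edges are always a subset of preliminary edges, and
  every retained node lies on a complete four-layer path.

A deterministic synthetic-data generator (`igrn.synth`) produces every
input the pipeline needs — counts, cell annotations, gene positions,
priors, spatial coordinates — with planted cascades, copy-number gains
and spatial geometry as ground truth for parameter-recovery testing.

## Worked example

Run the whole pipeline in memory on the packaged small bundle
(200 genes, 480 cells, two planted cascades, one planted copy-number
gain in subcluster `m2`, `m2` placed at the tumor front):

```python
import igrn
from igrn import network
from igrn.cli import run_bundle

bundle = igrn.fixture_small()
res = run_bundle(bundle, seed=1, n_perm=999)

print(res["malignancy"])
#  subcluster  median_score      p_value  is_malignant
#          m1     13.657935 5.741380e-01         False
#          m2     31.099496 1.295537e-14          True

print(res["front"])
#  subcluster  median_kdist      p_value  is_front
#          m1      4.153850 1.000000e+00     False
#          m2      1.801594 1.533974e-34      True

pre, pruned = res["networks"][("T cells", "m2")]
print(network.count_signals(pre))     # {'L-R': 1, 'R-TF': 1, 'TF-target': 3, 'total': 5}
print(network.extract_paths(pruned))
# [('G0142', 'G0039', 'G0176', 'G0010'),
#  ('G0142', 'G0039', 'G0176', 'G0073'),
#  ('G0142', 'G0039', 'G0176', 'G0147')]
```

The malignancy table shows only `m2` — the subcluster carrying the
planted 1.8× gain — called malignant (its cumulative CNV score
distribution sits far above the normal-epithelium reference). The front
table shows `m2`'s median distance to the nearest immune cells is ~1.8
spatial units versus ~4.2 for the core subcluster, so `m2` is the
unique front call. The extracted paths are exactly the planted
T-cell → m2 cascade: ligand `G0142` → receptor `G0039` → TF `G0176` →
its three targets.

The same pipeline runs from the shell on files:

```sh
igrn synth --seed 1 --outdir bundle --small
igrn run --config config.json     # paths + thresholds + seed
igrn cnv --counts bundle/counts --cells bundle/cells.tsv \
    --gene-positions bundle/gene_positions.tsv \
    --reference-subcluster "normal epi" --window 31 --outdir out
```

`igrn run` writes every intermediate table, preliminary and pruned
edge lists (TSV + JSON), per-layer signal counts and a run manifest
with the config hash and seed; identical config + seed reproduces all
network files byte-identically.

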