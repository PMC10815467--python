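"""Expression-derived copy-number profiling and malignancy calling.

Large chromosomal gains and losses leave a footprint in expression:
averaging reference-centered log expression over windows of
position-adjacent genes smooths away gene-level noise and leaves the
dosage signal. Cells are scored by the cumulative squared deviation of
their smoothed profile, and subclusters whose score distribution sits
significantly above a normal-epithelium reference are called malignant.

The residual pipeline, in order: drop low-expressed genes (mean raw
expression < cutoff, default 0.1); log-normalize; center each gene on
the reference-cell mean; clamp to [-3, 3]; moving-average smooth within
each chromosome (window default 101 genes, shrinking at chromosome
ends); re-center each cell on its own median; subtract the reference
cells' mean smoothed profile, which pins the reference mean residual at
exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .de import rank_sum_test
from .io import CountMatrix, GenePositions
from .qc import normalize

logger = logging.getLogger("igrn")

DEFAULT_WINDOW = 101
DEFAULT_CUTOFF = 0.1
DEFAULT_ALPHA = 0.05


@dataclass
class CNVProfile:
    """Cells x position-ordered-genes smoothed residual matrix."""

    cells: list[str]
    genes: list[str]           # sorted by (chromosome rank, start)
    chromosomes: list[str]     # per gene, parallel to ``genes``
    residuals: np.ndarray      # cells x genes
    window: int
    cutoff: float
    reference_cells: set[str]

    def __post_init__(self) -> None:
        if self.residuals.shape != (len(self.cells), len(self.genes)):
            raise ValueError("residual matrix shape inconsistent with labels")
        if not np.isfinite(self.residuals).all():
            raise ValueError("non-finite residuals")


def moving_average_by_chromosome(values: np.ndarray, chromosomes: list[str],
                                 window: int) -> np.ndarray:
    """Centered moving average along genes, never crossing a chromosome.

    ``values`` is cells x genes with genes position-ordered. The window
    shrinks near chromosome ends (mean over the genes that fall inside
    both the window and the chromosome).
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return values.copy()
    half = window // 2
    out = np.empty_like(values, dtype=float)
    chrom_arr = np.asarray(chromosomes)
    for chrom in dict.fromkeys(chromosomes):
        idx = np.flatnonzero(chrom_arr == chrom)
        block = values[:, idx]
        csum = np.concatenate(
            [np.zeros((values.shape[0], 1)), np.cumsum(block, axis=1)], axis=1)
        n = block.shape[1]
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        out[:, idx] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    return out


def build_cnv_profile(m: CountMatrix, positions: GenePositions,
                      reference_cells, window: int = DEFAULT_WINDOW,
                      cutoff: float = DEFAULT_CUTOFF) -> CNVProfile:
    """Run the residual pipeline for every cell in ``m``."""
    reference_cells = set(reference_cells)
    if not reference_cells:
        raise ValueError("empty reference cell set")
    missing_ref = reference_cells - set(m.barcodes)
    if missing_ref:
        raise ValueError(f"{len(missing_ref)} reference barcodes absent from matrix")
    if not (set(m.barcodes) - reference_cells):
        raise ValueError("no observation cells outside the reference")

    pos = positions.table.set_index("gene")
    located = [g for g in m.genes if g in pos.index]
    if len(located) < 0.5 * len(m.genes):
        raise ValueError(
            f"positions known for only {len(located)}/{len(m.genes)} genes")

    rank = positions.chrom_rank()
    order = sorted(located,
                   key=lambda g: (rank[pos.at[g, "chromosome"]], pos.at[g, "start"], g))
    gi = m.gene_index()
    rows = [gi[g] for g in order]
    raw = np.asarray(m.counts[rows, :].todense(), dtype=float)

    keep = raw.mean(axis=1) >= cutoff
    genes = [g for g, k in zip(order, keep) if k]
    chroms = [str(pos.at[g, "chromosome"]) for g in genes]
    logger.info("cnv: %d/%d positioned genes pass cutoff %.3g",
                len(genes), len(order), cutoff)

    sub = CountMatrix(genes, list(m.barcodes),
                      m.counts[[gi[g] for g in genes], :])
    expr = np.asarray(normalize(sub).values.todense()).T  # cells x genes

    ref_idx = np.array([i for i, b in enumerate(m.barcodes) if b in reference_cells])
    centered = expr - expr[ref_idx].mean(axis=0, keepdims=True)
    centered = np.clip(centered, -3.0, 3.0)
    smoothed = moving_average_by_chromosome(centered, chroms, window)
    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    residuals = smoothed - smoothed[ref_idx].mean(axis=0, keepdims=True)

    return CNVProfile(cells=list(m.barcodes), genes=genes, chromosomes=chroms,
                      residuals=residuals, window=window, cutoff=cutoff,
                      reference_cells=reference_cells)


def cnv_score(profile: CNVProfile) -> pd.DataFrame:
    """Cumulative squared deviation per cell (columns: cell, score)."""
    scores = (profile.residuals ** 2).sum(axis=1)
    return pd.DataFrame({"cell": profile.cells, "score": scores})


def call_malignant(scores: pd.DataFrame, cells: pd.DataFrame,
                   reference_cells, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Per-subcluster malignancy call against the reference score pool.

    One-sided rank-sum (subcluster scores greater than reference); a
    subcluster is malignant when p < alpha and its median score exceeds
    the reference median. Returns columns (subcluster, median_score,
    p_value, is_malignant).
    """
    reference_cells = set(reference_cells)
    s = scores.set_index("cell")["score"]
    ref_scores = s.loc[[c for c in s.index if c in reference_cells]].to_numpy()
    if ref_scores.size == 0:
        raise ValueError("no reference cells among scored cells")
    ref_median = float(np.median(ref_scores))

    rows = []
    for sub, grp in cells.groupby(cells["subcluster"].astype(str), observed=True):
        in_ref = grp["barcode"].isin(reference_cells)
        if in_ref.all():
            continue  # the reference cluster itself is not tested
        if in_ref.any():
            raise ValueError(f"subcluster {sub} overlaps the reference")
        if len(grp) < 3:
            raise ValueError(f"subcluster {sub} has {len(grp)} cells (< 3)")
        vals = s.loc[grp["barcode"]].to_numpy()
        p = float(scipy.stats.mannwhitneyu(vals, ref_scores,
                                           alternative="greater",
                                           method="asymptotic").pvalue)
        med = float(np.median(vals))
        rows.append({"subcluster": sub, "median_score": med, "p_value": p,
                     "is_malignant": bool(p < alpha and med > ref_median)})
    return pd.DataFrame(rows, columns=["subcluster", "median_score",
                                       "p_value", "is_malignant"])


def cluster_similarity(profile: CNVProfile, cells: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation between subcluster mean residual profiles.

    Symmetric with unit diagonal; a constant mean profile yields NaN for
    its pairs (undefined correlation, reported as missing).
    """
    sub_labels = cells.set_index("barcode")["subcluster"].astype(str)
    ci = {c: i for i, c in enumerate(profile.cells)}
    means: dict[str, np.ndarray] = {}
    for sub, grp in cells.groupby(sub_labels.values, observed=True):
        idx = [ci[b] for b in grp["barcode"] if b in ci]
        if idx:
            means[sub] = profile.residuals[idx].mean(axis=0)
    subs = sorted(means)
    if len(subs) < 2:
        raise ValueError("need at least 2 subclusters")
    mat = pd.DataFrame(np.eye(len(subs)), index=subs, columns=subs)
    for i, a in enumerate(subs):
        if np.ptp(means[a]) == 0:
            mat.loc[a, a] = np.nan
        for b in subs[i + 1:]:
            if np.ptp(means[a]) == 0 or np.ptp(means[b]) == 0:
                rho = np.nan
            else:
                rho = float(scipy.stats.spearmanr(means[a], means[b]).statistic)
            mat.loc[a, b] = mat.loc[b, a] = rho
    return mat


__all__ = ["CNVProfile", "build_cnv_profile", "cnv_score", "call_malignant",
           "cluster_similarity", "moving_average_by_chromosome", "rank_sum_test"]
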