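"""Cell quality filtering, library-size normalization, HVG selection.

Quality gates follow the standard 10x single-cell workflow: cells are
kept when their mitochondrial-read fraction is at most 20%, their total
UMI count lies in [200, 60000], and they express strictly more than 200
genes. Normalization is ln(1 + CP10k); highly variable genes are ranked
by a variance-stabilized dispersion statistic (standardized variance
after a mean-variance trend fit, clipped z-scores).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import CountMatrix, NormalizedMatrix

logger = logging.getLogger("igrn")


@dataclass
class QCThresholds:
    """Cell-level quality bounds.

    ``min_genes`` is an exclusive bound (a cell must detect strictly more
    genes); the UMI bounds are inclusive.
    """

    max_mito_fraction: float = 0.20
    umi_min: int = 200
    umi_max: int = 60000
    min_genes: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")
        if self.umi_min > self.umi_max:
            raise ValueError("umi_min > umi_max")


def filter_cells(m: CountMatrix, thresholds: QCThresholds | None = None,
                 mito_prefix: str = "MT-") -> CountMatrix:
    """Drop cells failing any quality gate; the gene set is unchanged.

    Mitochondrial genes are identified by symbol prefix. Raises if no
    cell survives, naming the most binding criterion.
    """
    thresholds = thresholds or QCThresholds()
    counts = sp.csc_matrix(m.counts)
    total = np.asarray(counts.sum(axis=0)).ravel()
    n_detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito_rows = np.array([g.startswith(mito_prefix) for g in m.genes])
    if mito_rows.any():
        mito_total = np.asarray(counts[mito_rows, :].sum(axis=0)).ravel()
    else:
        mito_total = np.zeros_like(total, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1), 0.0)

    pass_mito = mito_frac <= thresholds.max_mito_fraction
    pass_umi = (total >= thresholds.umi_min) & (total <= thresholds.umi_max)
    pass_genes = n_detected > thresholds.min_genes
    keep = pass_mito & pass_umi & pass_genes

    removed = {
        "mito_fraction": int((~pass_mito).sum()),
        "umi_bounds": int((~pass_umi).sum()),
        "min_genes": int((~pass_genes).sum()),
    }
    logger.info("filter_cells: kept %d/%d cells; failures per criterion %s",
                int(keep.sum()), len(keep), removed)
    if not keep.any():
        binding = max(removed, key=removed.get)
        raise ValueError(f"no cells survive quality filtering "
                         f"(most binding criterion: {binding})")
    keep_idx = np.flatnonzero(keep)
    return CountMatrix(list(m.genes),
                       [m.barcodes[i] for i in keep_idx],
                       sp.csr_matrix(counts[:, keep_idx]))


def normalize(m: CountMatrix, scale_factor: float = 10000.0) -> NormalizedMatrix:
    """ln(1 + count * scale_factor / cell_total); zero-total cells map to zeros."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    counts = sp.csc_matrix(m.counts, dtype=np.float64)
    total = np.asarray(counts.sum(axis=0)).ravel()
    inv = np.zeros_like(total)
    nz = total > 0
    inv[nz] = scale_factor / total[nz]
    scaled = counts @ sp.diags(inv)
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(list(m.genes), list(m.barcodes), sp.csr_matrix(scaled))


def select_hvg(m: NormalizedMatrix, n: int = 2000,
               clip: float | None = None) -> list[str]:
    """Rank genes by standardized variance and return the top ``n``.

    A quadratic trend of log variance on log mean (over expressed genes)
    supplies the expected spread at each gene's mean; values are z-scored
    against that expectation, clipped at sqrt(n_cells) to bound the
    influence of single cells, and genes are ranked by the variance of
    the clipped z-scores. Ties break lexicographically by symbol.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(m.genes):
        raise ValueError(f"n={n} exceeds gene count {len(m.genes)}")
    x = m.dense()
    n_cells = x.shape[1]
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1) if n_cells > 1 else np.zeros_like(mean)

    expected_var = np.zeros_like(var)
    fit_mask = (var > 0) & (mean > 0)
    if fit_mask.sum() >= 3:
        lm, lv = np.log10(mean[fit_mask]), np.log10(var[fit_mask])
        coef = np.polyfit(lm, lv, deg=min(2, fit_mask.sum() - 1))
        expected_var[fit_mask] = 10 ** np.polyval(coef, lm)
    else:
        expected_var[fit_mask] = var[fit_mask]

    std_var = np.zeros(len(m.genes))
    clip = np.sqrt(n_cells) if clip is None else clip
    for i in np.flatnonzero(fit_mask):
        sd = np.sqrt(expected_var[i])
        z = np.clip((x[i] - mean[i]) / sd, -clip, clip)
        std_var[i] = z.var(ddof=1)

    order = sorted(range(len(m.genes)), key=lambda i: (-std_var[i], m.genes[i]))
    return [m.genes[i] for i in order[:n]]


def scale_genes(m: NormalizedMatrix, max_value: float = 10.0) -> np.ndarray:
    """Per-gene z-score of the normalized values, clipped at ``max_value``.

    Returned dense (genes x cells); used only by stages that request
    scaled input — normalization and scaling are deliberately separate.
    """
    x = m.dense()
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return np.clip((x - mu) / sd, -max_value, max_value)
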