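"""Wilcoxon rank-sum differential expression with log-fold-change screen.

This is the marker machinery behind ligand/receptor/target selection:
one-vs-rest contrasts with defaults p < 0.05 on the raw rank-sum p-value
and natural-log fold change > 0.15, mirroring the conventional
single-cell marker workflow. BH-adjusted p-values are reported alongside
but do not gate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import NormalizedMatrix

DEFAULT_PVAL = 0.05
DEFAULT_LOGFC = 0.15

# exact null enumeration is cheap and exact up to this pooled size
_EXACT_MAX_N = 25

DE_COLUMNS = ["gene", "log_fc", "p_value", "adj_p", "pct_in", "pct_out"]


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when there are no ties and the
    pooled sample is small; otherwise the normal approximation with tie
    and continuity corrections. Degenerate inputs (pooled values all
    equal, or a statistic exactly at the null center) return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (no_ties and pooled.size <= _EXACT_MAX_N) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                                   use_continuity=True)
    # U at the null center means a perfectly balanced rank split
    if res.statistic == x.size * y.size / 2:
        return 1.0
    return float(min(res.pvalue, 1.0))


def log_fold_change(m: NormalizedMatrix, in_cells, out_cells, gene: str) -> float:
    """Natural-log fold change of back-transformed means with pseudocount 1.

    log_fc = ln(mean_in(e^v - 1) + 1) - ln(mean_out(e^v - 1) + 1), the
    convention under which the 0.15 screening threshold is defined.
    """
    gi = m.gene_index()
    if gene not in gi:
        raise KeyError(f"gene absent from matrix: {gene}")
    in_cells, out_cells = list(in_cells), list(out_cells)
    if not in_cells or not out_cells:
        raise ValueError("empty cell set")
    if set(in_cells) & set(out_cells):
        raise ValueError("cell sets overlap")
    bi = m.barcode_index()
    row = np.asarray(m.values[gi[gene], :].todense()).ravel()
    v_in = row[[bi[b] for b in in_cells]]
    v_out = row[[bi[b] for b in out_cells]]
    return float(np.log(np.expm1(v_in).mean() + 1.0)
                 - np.log(np.expm1(v_out).mean() + 1.0))


def deg_screen(m: NormalizedMatrix, cells: pd.DataFrame, focal: str,
               pval: float = DEFAULT_PVAL, logfc: float = DEFAULT_LOGFC) -> pd.DataFrame:
    """Genes up-regulated in the focal subcluster versus all other cells.

    ``cells`` is the cell table restricted to the compartment of
    interest; the contrast is focal subcluster vs the rest of it. Returns
    a frame with columns (gene, log_fc, p_value, adj_p, pct_in, pct_out)
    filtered to p_value < pval and log_fc > logfc, sorted by p then
    |log_fc| descending.
    """
    sub = cells["subcluster"].astype(str)
    if focal not in set(sub):
        raise ValueError(f"focal subcluster absent: {focal}")
    in_barcodes = cells.loc[sub == focal, "barcode"].tolist()
    out_barcodes = cells.loc[sub != focal, "barcode"].tolist()
    if len(in_barcodes) < 3:
        raise ValueError(f"focal subcluster has {len(in_barcodes)} cells (< 3)")
    if not out_barcodes:
        raise ValueError("no out-group cells")

    bi = m.barcode_index()
    x = m.dense()
    in_idx = np.array([bi[b] for b in in_barcodes])
    out_idx = np.array([bi[b] for b in out_barcodes])
    xin, xout = x[:, in_idx], x[:, out_idx]

    with np.errstate(invalid="ignore"):
        res = scipy.stats.mannwhitneyu(xin, xout, alternative="two-sided",
                                       method="asymptotic", use_continuity=True,
                                       axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    # constant genes (zero rank variance) are uninformative
    p[~np.isfinite(p)] = 1.0
    center = xin.shape[1] * xout.shape[1] / 2
    p[np.asarray(res.statistic) == center] = 1.0

    lfc = (np.log(np.expm1(xin).mean(axis=1) + 1.0)
           - np.log(np.expm1(xout).mean(axis=1) + 1.0))
    adj_p = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({
        "gene": m.genes,
        "log_fc": lfc,
        "p_value": p,
        "adj_p": adj_p,
        "pct_in": (xin > 0).mean(axis=1),
        "pct_out": (xout > 0).mean(axis=1),
    })
    out = out[(out["p_value"] < pval) & (out["log_fc"] > logfc)]
    out = out.sort_values(["p_value", "log_fc"], key=lambda s: s.abs() if s.name == "log_fc" else s,
                          ascending=[True, False], kind="mergesort")
    return out.reset_index(drop=True)


def write_de_results(df: pd.DataFrame, path) -> None:
    df[DE_COLUMNS].to_csv(path, sep="\t", index=False)
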