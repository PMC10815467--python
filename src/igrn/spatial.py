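"""Spot composition scoring, K-distance, and invasive-front calling.

K-distance (kdist) is the mean Euclidean distance from a query unit to
its k nearest units of a reference population, in native coordinate
units. A malignant subcluster is called "front" when its kdist-to-immune
distribution is significantly lower than that of the other malignant
subclusters pooled — an explicit statistical operationalization of the
invasive-front notion (proximity of tumor cells to immune tissue).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.spatial.distance
import scipy.stats

from .io import CountMatrix, SpatialTable
from .qc import normalize

logger = logging.getLogger("igrn")

DEFAULT_K = 10
DEFAULT_ALPHA = 0.05


def score_spot_composition(st_counts: CountMatrix, spatial: SpatialTable,
                           markers: dict[str, list[str]]) -> pd.DataFrame:
    """Signature enrichment of each cell type at each spatial unit.

    Score = mean log-normalized expression of the marker set in the
    spot, z-scored across spots per cell type. Columns:
    (unit_id, cell_type, score).
    """
    expr = np.asarray(normalize(st_counts).values.todense())
    gi = st_counts.gene_index()
    bi = st_counts.barcode_index()
    units = [str(u) for u in spatial.table["unit_id"]]
    cols = np.array([bi[u] for u in units])

    rows = []
    for cell_type in sorted(markers):
        genes = [g.upper() for g in markers[cell_type]]
        present = [g for g in genes if g in gi]
        if not present:
            raise ValueError(f"no marker genes of '{cell_type}' present in matrix")
        raw = expr[np.array([gi[g] for g in present])][:, cols].mean(axis=0)
        sd = raw.std(ddof=0)
        z = np.zeros_like(raw) if sd == 0 else (raw - raw.mean()) / sd
        rows.extend({"unit_id": u, "cell_type": cell_type, "score": s}
                    for u, s in zip(units, z))
    return pd.DataFrame(rows, columns=["unit_id", "cell_type", "score"])


def kdist(query: SpatialTable, reference: SpatialTable, k: int = DEFAULT_K,
          reference_population: str = "reference") -> pd.DataFrame:
    """Mean Euclidean distance from each query unit to its k nearest
    reference units.

    Distance ties are broken by reference unit-ID order so the result is
    deterministic. If k exceeds the reference size it is truncated with
    a warning. Columns: (query_cell, reference_population, k, kdist).
    """
    if len(query.table) == 0 or len(reference.table) == 0:
        raise ValueError("empty query or reference")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_ref = len(reference.table)
    if k > n_ref:
        logger.warning("k=%d exceeds reference size %d; truncating", k, n_ref)
        k = n_ref

    ref = reference.table.sort_values("unit_id", kind="mergesort")
    d = scipy.spatial.distance.cdist(query.coords(),
                                     ref[["x", "y"]].to_numpy(dtype=float))
    # stable sort on distance preserves unit-ID order among ties
    nearest = np.sort(np.take_along_axis(d, np.argsort(d, axis=1, kind="stable"),
                                         axis=1)[:, :k], axis=1)
    return pd.DataFrame({
        "query_cell": [str(u) for u in query.table["unit_id"]],
        "reference_population": reference_population,
        "k": k,
        "kdist": nearest.mean(axis=1),
    })


def call_front(malignant_cells: dict[str, SpatialTable],
               immune_cells: SpatialTable, k: int = DEFAULT_K,
               alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Flag malignant subclusters sitting significantly closer to immune
    cells than their peers.

    For each subcluster, its per-cell kdist-to-immune values are tested
    (one-sided rank-sum, lower) against the pooled kdist of all other
    malignant subclusters. With a single subcluster there is nothing to
    compare: calls are undefined (is_front = NA). Columns:
    (subcluster, median_kdist, p_value, is_front).
    """
    subs = sorted(malignant_cells)
    dists = {s: kdist(malignant_cells[s], immune_cells, k=k,
                      reference_population="immune")["kdist"].to_numpy()
             for s in subs}
    rows = []
    if len(subs) < 2:
        for s in subs:
            rows.append({"subcluster": s,
                         "median_kdist": float(np.median(dists[s])),
                         "p_value": np.nan, "is_front": pd.NA})
        return pd.DataFrame(rows, columns=["subcluster", "median_kdist",
                                           "p_value", "is_front"])
    for s in subs:
        own = dists[s]
        others = np.concatenate([dists[t] for t in subs if t != s])
        pooled = np.concatenate([own, others])
        if np.ptp(pooled) == 0:
            p = 1.0
        else:
            p = float(scipy.stats.mannwhitneyu(own, others, alternative="less",
                                               method="asymptotic").pvalue)
        rows.append({"subcluster": s, "median_kdist": float(np.median(own)),
                     "p_value": p, "is_front": bool(p < alpha)})
    return pd.DataFrame(rows, columns=["subcluster", "median_kdist",
                                       "p_value", "is_front"])
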