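"""Multilayer intercellular network: L-R scoring, assembly, pruning.

The network chains a sender population's ligand to a receiver
subcluster's receptor, transcription factor and target genes across
three prior-knowledge layers (L-R, R-TF, TF-target). Construction runs
in two stages:

* preliminary — ligands that pass a sender expression gate and a
  permutation significance test; receptors/TFs expressed in the
  receiver; targets taken from TF-target priors; everything restricted
  to nodes that lie on a complete 4-layer path.
* pruned — TF nodes restricted to active regulons, TF-target edges to
  (regulon membership AND receiver DEG), followed by the same full-path
  cleanup. Pruned edges are always a subset of preliminary edges; the
  per-layer signal counts quantify the reduction.

The L-R score is (mean ligand expression in sender + mean receptor
expression in receiver) / 2 with a label-permutation p-value, the
scheme popularized by permutation-based ligand-receptor tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import NormalizedMatrix, PriorKnowledge
from .regulon import Regulon

logger = logging.getLogger("igrn")

DEFAULT_N_PERM = 1000
DEFAULT_PCT_MIN = 0.10
DEFAULT_LR_ALPHA = 0.05

LAYERS = ("L-R", "R-TF", "TF-target")
ROLE_BY_LAYER = {
    "L-R": ("ligand", "receptor"),
    "R-TF": ("receptor", "tf"),
    "TF-target": ("tf", "target"),
}


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    layer: str
    score: float | None = None


@dataclass
class IGRN:
    """Directed multilayer network between a sender and a receiver."""

    nodes: dict[str, str]  # symbol -> role in {ligand, receptor, tf, target}
    edges: list[Edge]
    sender: str
    receiver: str
    stage: str = "preliminary"

    def validate(self) -> "IGRN":
        touched: set[str] = set()
        for e in self.edges:
            if e.layer not in ROLE_BY_LAYER:
                raise ValueError(f"unknown layer: {e.layer}")
            src_role, dst_role = ROLE_BY_LAYER[e.layer]
            if self.nodes.get(e.source) != src_role:
                raise ValueError(
                    f"edge {e.source}->{e.target} ({e.layer}): source role "
                    f"{self.nodes.get(e.source)} != {src_role}")
            if self.nodes.get(e.target) != dst_role:
                raise ValueError(
                    f"edge {e.source}->{e.target} ({e.layer}): target role "
                    f"{self.nodes.get(e.target)} != {dst_role}")
            touched.add(e.source)
            touched.add(e.target)
        orphans = set(self.nodes) - touched
        if orphans:
            raise ValueError(f"orphan nodes: {sorted(orphans)}")
        return self

    def sorted_edges(self) -> list[Edge]:
        rank = {l: i for i, l in enumerate(LAYERS)}
        return sorted(self.edges, key=lambda e: (rank[e.layer], e.source, e.target))

    def edge_set(self) -> set[tuple[str, str, str]]:
        return {(e.source, e.target, e.layer) for e in self.edges}

    def is_empty(self) -> bool:
        return not self.edges


def _path_support(nodes: dict[str, str], edges: list[Edge]) -> IGRN | None:
    """Keep only nodes/edges lying on a complete ligand->...->target path.

    In a strictly layered DAG this is the intersection of forward
    reachability from the ligand layer and backward reachability from
    the target layer.
    """
    out_adj: dict[str, set[str]] = {}
    in_adj: dict[str, set[str]] = {}
    for e in edges:
        out_adj.setdefault(e.source, set()).add(e.target)
        in_adj.setdefault(e.target, set()).add(e.source)

    def closure(seeds: set[str], adj: dict[str, set[str]]) -> set[str]:
        seen, frontier = set(seeds), list(seeds)
        while frontier:
            for nxt in adj.get(frontier.pop(), ()):
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
        return seen

    fwd = closure({n for n, r in nodes.items() if r == "ligand"}, out_adj)
    bwd = closure({n for n, r in nodes.items() if r == "target"}, in_adj)
    keep = fwd & bwd
    new_nodes = {n: r for n, r in nodes.items() if n in keep}
    new_edges = [e for e in edges if e.source in keep and e.target in keep]
    touched = {e.source for e in new_edges} | {e.target for e in new_edges}
    new_nodes = {n: r for n, r in new_nodes.items() if n in touched}
    if not new_edges:
        return None
    return IGRN(new_nodes, new_edges, "", "")


def _expr_stats(m: NormalizedMatrix, barcodes: list[str]):
    bi = m.barcode_index()
    idx = np.array([bi[b] for b in barcodes])
    x = np.asarray(m.values[:, idx].todense())
    return x, x.mean(axis=1), (x > 0).mean(axis=1)


def lr_score(m: NormalizedMatrix, cells: pd.DataFrame, sender: str,
             receiver: str, priors: PriorKnowledge,
             n_perm: int = DEFAULT_N_PERM, seed: int = 0,
             pct_min: float = DEFAULT_PCT_MIN) -> pd.DataFrame:
    """Permutation-scored ligand-receptor interactions.

    ``sender``/``receiver`` name cell populations: sender matches
    ``cell_type``, receiver matches ``subcluster`` (falling back to
    ``cell_type`` when no subcluster matches). Pairs must clear the
    expression gate (ligand expressed in > pct_min of sender cells,
    receptor in > pct_min of receiver cells). The p-value permutes the
    sender/receiver split jointly: p = (1 + #{permuted score >=
    observed}) / (n_perm + 1). Deterministic given ``seed``.
    """
    sender_bc = cells.loc[cells["cell_type"] == sender, "barcode"].tolist()
    sub = cells.get("subcluster")
    recv_mask = (sub.astype(str) == receiver) if sub is not None else pd.Series(False, index=cells.index)
    if not recv_mask.any():
        recv_mask = cells["cell_type"] == receiver
    recv_bc = cells.loc[recv_mask, "barcode"].tolist()
    if len(sender_bc) < 10 or len(recv_bc) < 10:
        raise ValueError(
            f"populations too small: sender {len(sender_bc)}, receiver {len(recv_bc)}")

    gi = m.gene_index()
    xs, mean_s, pct_s = _expr_stats(m, sender_bc)
    xr, mean_r, pct_r = _expr_stats(m, recv_bc)

    gated = []
    for lig, rec in sorted(priors.lr_pairs):
        if lig not in gi or rec not in gi:
            continue
        li, ri = gi[lig], gi[rec]
        if pct_s[li] > pct_min and pct_r[ri] > pct_min:
            gated.append((lig, rec, li, ri))
    if not gated:
        logger.warning("lr_score: no prior pair passes the expression gate")
        return pd.DataFrame(columns=["ligand", "receptor", "sender", "receiver",
                                     "score", "p_value"])

    obs = np.array([(mean_s[li] + mean_r[ri]) / 2 for _, _, li, ri in gated])

    # permutation null: reshuffle the sender/receiver split of the pooled cells
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([xs, xr], axis=1)
    lig_rows = np.array([li for _, _, li, ri in gated])
    rec_rows = np.array([ri for _, _, li, ri in gated])
    lig_mat, rec_mat = pooled[lig_rows], pooled[rec_rows]
    n_s = len(sender_bc)
    n_tot = pooled.shape[1]
    exceed = np.zeros(len(gated), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)
        s_idx, r_idx = perm[:n_s], perm[n_s:]
        perm_score = (lig_mat[:, s_idx].mean(axis=1)
                      + rec_mat[:, r_idx].mean(axis=1)) / 2
        exceed += perm_score >= obs
    pvals = (1 + exceed) / (n_perm + 1)

    return pd.DataFrame({
        "ligand": [g[0] for g in gated],
        "receptor": [g[1] for g in gated],
        "sender": sender,
        "receiver": receiver,
        "score": obs,
        "p_value": pvals,
    })


def build_preliminary(m: NormalizedMatrix, cells: pd.DataFrame, sender: str,
                      receiver_subcluster: str, priors: PriorKnowledge,
                      de: pd.DataFrame | None, lr: pd.DataFrame,
                      pct_min: float = DEFAULT_PCT_MIN,
                      lr_alpha: float = DEFAULT_LR_ALPHA) -> IGRN:
    """Assemble the preliminary three-layer network.

    Layer by layer: significant, sender-expressed ligands; their
    receiver-expressed prior receptors; receiver-expressed TFs linked to
    those receptors; prior targets of those TFs. Nodes not on a complete
    4-layer path are removed. The receiver DEG frame ``de`` is accepted
    for interface symmetry with the pruning stage, which is where the
    DEG filter applies.
    """
    gi = m.gene_index()
    sub = cells["subcluster"].astype(str)
    recv_bc = cells.loc[sub == receiver_subcluster, "barcode"].tolist()
    if not recv_bc:
        raise ValueError(f"receiver subcluster absent: {receiver_subcluster}")
    _, _, pct_recv = _expr_stats(m, recv_bc)

    empty = IGRN({}, [], sender, receiver_subcluster, stage="preliminary")
    if lr is None or lr.empty:
        logger.info("build_preliminary: empty L-R layer")
        return empty

    sig = lr[lr["p_value"] < lr_alpha]
    lr_edges: list[Edge] = []
    nodes: dict[str, str] = {}
    for row in sig.itertuples(index=False):
        lig, rec = row.ligand, row.receptor
        if rec not in gi or pct_recv[gi[rec]] <= pct_min:
            continue
        if nodes.get(lig, "ligand") != "ligand" or nodes.get(rec, "receptor") != "receptor":
            continue  # a symbol cannot take two roles
        nodes[lig] = "ligand"
        nodes[rec] = "receptor"
        lr_edges.append(Edge(lig, rec, "L-R", float(row.score)))
    if not lr_edges:
        logger.info("build_preliminary: empty L-R layer after gates")
        return empty

    receptors = {n for n, r in nodes.items() if r == "receptor"}
    rtf_edges: list[Edge] = []
    for rec, tf in sorted(priors.rtf_links):
        if rec in receptors and tf in gi and pct_recv[gi[tf]] > pct_min:
            if nodes.get(tf, "tf") != "tf":
                continue
            nodes[tf] = "tf"
            rtf_edges.append(Edge(rec, tf, "R-TF", None))
    if not rtf_edges:
        logger.info("build_preliminary: empty R-TF layer")
        return empty

    tfs = {n for n, r in nodes.items() if r == "tf"}
    tft_edges: list[Edge] = []
    for tf, tg in sorted(priors.tft_priors):
        if tf in tfs and tg in gi:
            if nodes.get(tg, "target") != "target":
                continue
            nodes[tg] = "target"
            tft_edges.append(Edge(tf, tg, "TF-target", None))
    if not tft_edges:
        logger.info("build_preliminary: empty TF-target layer")
        return empty

    supported = _path_support(nodes, lr_edges + rtf_edges + tft_edges)
    if supported is None:
        return empty
    net = IGRN(supported.nodes, supported.edges, sender, receiver_subcluster,
               stage="preliminary")
    return net.validate()


def prune_igrn(net: IGRN, regulons: list[Regulon], degs: pd.DataFrame) -> IGRN:
    """Restrict the preliminary network to active-regulon TFs and DEG targets.

    A TF node survives iff it heads one of the supplied (active)
    regulons; a TF-target edge survives iff the pair is in that regulon
    AND the target passed the receiver DEG screen. Unreachable and
    orphan nodes are then removed.
    """
    active = {r.tf: r for r in regulons}
    deg_genes = set(degs["gene"]) if degs is not None and len(degs) else set()

    kept: list[Edge] = []
    for e in net.edges:
        if e.layer == "L-R":
            kept.append(e)
        elif e.layer == "R-TF":
            if e.target in active:
                kept.append(e)
        else:  # TF-target
            reg = active.get(e.source)
            if reg is not None and e.target in reg.targets and e.target in deg_genes:
                score = reg.targets[e.target]
                kept.append(Edge(e.source, e.target, e.layer, score))
    supported = _path_support(dict(net.nodes), kept)
    if supported is None:
        return IGRN({}, [], net.sender, net.receiver, stage="pruned")
    out = IGRN(supported.nodes, supported.edges, net.sender, net.receiver,
               stage="pruned")
    out.validate()
    pre = {(e.source, e.target) for e in net.edges}
    assert {(e.source, e.target) for e in out.edges} <= pre
    return out


def extract_paths(net: IGRN) -> list[tuple[str, str, str, str]]:
    """Every ligand->receptor->TF->target path, lexicographically ordered."""
    net.validate()
    by_layer: dict[str, list[Edge]] = {l: [] for l in LAYERS}
    for e in net.edges:
        by_layer[e.layer].append(e)
    rtf_by_rec: dict[str, list[Edge]] = {}
    for e in by_layer["R-TF"]:
        rtf_by_rec.setdefault(e.source, []).append(e)
    tft_by_tf: dict[str, list[Edge]] = {}
    for e in by_layer["TF-target"]:
        tft_by_tf.setdefault(e.source, []).append(e)

    paths = []
    for lr in by_layer["L-R"]:
        for rtf in rtf_by_rec.get(lr.target, ()):
            for tft in tft_by_tf.get(rtf.target, ()):
                paths.append((lr.source, lr.target, rtf.target, tft.target))
    return sorted(paths)


def count_signals(net: IGRN) -> dict[str, int]:
    """Per-layer edge counts and total; total is the sum of the parts."""
    counts = {l: 0 for l in LAYERS}
    for e in net.edges:
        counts[e.layer] += 1
    counts["total"] = sum(counts[l] for l in LAYERS)
    return counts
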