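"""Deterministic synthetic single-cell / spatial data with ground truth.

The generator emulates the structure of a tumor scRNA-seq study with a
matched spatial section: a normal-epithelium reference population,
malignant receiver subclusters carrying planted chromosomal gains,
sender immune populations, planted ligand->receptor->TF->target
cascades (plus decoy priors carrying no signal), and an idealized
disc / annulus / ring spatial layout (tumor core, invasive front,
immune ring, outer stroma).

Counts are negative-binomial with lognormal gene means and a lognormal
per-cell size factor. A planted cascade up-shifts its ligand in the
sender population and its receptor/TF/targets in the receiver
subcluster; within-cell co-expression of the TF and its targets is
induced by a shared on/off latent activity factor that fires in half of
the receiver cells, so rank-based regulon scoring has recoverable
signal. Copy-number segments multiply
expected counts over a contiguous run of position-ordered genes.

Identical (config, seed) always yields byte-identical bundles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (CountMatrix, GenePositions, PriorKnowledge, SpatialTable,
                 validate_cell_table)

logger = logging.getLogger("igrn")

# generator noise family: counts ~ NB(mean mu, var mu + alpha mu^2)
DEFAULT_DISPERSION = 0.3
# lognormal spread of baseline gene means (median 1)
GENE_MEAN_SDLOG = 0.5
# per-cell library size factor spread
CELL_SIZE_SDLOG = 0.3
# the cascade latent activity is on/off: it fires in this fraction of the
# receiver subcluster's cells, with the boost calibrated so the mean ln
# fold change over the subcluster equals the cascade effect
LATENT_ACTIVE_FRACTION = 0.5
# baseline mean of planted cascade / marker genes: solidly detected genes,
# so a boosted cell reliably pulls them into the top of its ranking
PLANTED_BASE_MEAN = 1.5
MARKER_EFFECT = 1.5


@dataclass(frozen=True)
class Cascade:
    """A planted ligand->receptor->TF->targets signaling chain."""

    ligand: str
    receptor: str
    tf: str
    targets: tuple[str, ...]
    sender: str
    receiver_subcluster: str
    effect: float = 1.0  # ln fold change of the planted up-shift

    def edges(self) -> set[tuple[str, str, str]]:
        out = {(self.ligand, self.receptor, "L-R"),
               (self.receptor, self.tf, "R-TF")}
        out |= {(self.tf, t, "TF-target") for t in self.targets}
        return out


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    Defaults describe the standard scenario: 600 genes over 6
    chromosomes; two sender immune populations, two malignant receiver
    subclusters and a normal-epithelium reference (150 cells each); 5
    planted cascades with ln-FC 1.0; 20 decoy prior chains; a 1.8x gain
    over 60 contiguous genes in each malignant subcluster; and a
    core/front/immune-ring/stroma spatial layout whose front subcluster
    is m2.
    """

    n_genes: int = 600
    populations: list[tuple[str, str, int]] = field(default_factory=lambda: [
        ("macrophage", "sender", 150),
        ("T cells", "sender", 150),
        ("m1", "receiver", 150),
        ("m2", "receiver", 150),
        ("normal epi", "reference", 150),
    ])
    n_cascades: int = 5
    cascade_effect: float = 1.0
    targets_per_cascade: int = 3
    decoy_priors: int = 20
    cnv_segments: list[tuple[str, tuple[int, int], float]] = field(
        default_factory=lambda: [("m1", (300, 360), 1.8),
                                 ("m2", (400, 460), 1.8)])
    dispersion: float = DEFAULT_DISPERSION
    genes_per_chromosome: int = 100
    markers_per_population: int = 5
    # spatial geometry (arbitrary planar units): m1 core disc, m2 front
    # annulus, immune ring, normal-epi outer stroma
    core_radius: float = 5.0
    front_outer: float = 7.0
    immune_outer: float = 9.0
    stroma_inner: float = 10.0
    stroma_outer: float = 12.0
    front_subcluster: str = "m2"

    def validate(self) -> "SynthConfig":
        names = [p[0] for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        for sub, (lo, hi), fold in self.cnv_segments:
            if not (0 <= lo < hi <= self.n_genes):
                raise ValueError(f"cnv segment {lo}:{hi} outside gene range")
            if sub not in names:
                raise ValueError(f"cnv segment references unknown subcluster {sub}")
            if fold <= 0:
                raise ValueError("cnv fold must be positive")
        n_planted = (self.n_cascades * (3 + self.targets_per_cascade)
                     + self.decoy_priors * 4
                     + self.markers_per_population * len(self.populations))
        if n_planted > len(self.free_gene_indices()):
            raise ValueError("planted genes exceed genes outside cnv segments")
        return self

    def free_gene_indices(self) -> list[int]:
        """Gene indices outside every cnv segment, available for planting."""
        in_seg = np.zeros(self.n_genes, dtype=bool)
        for _, (lo, hi), _ in self.cnv_segments:
            in_seg[lo:hi] = True
        return [int(i) for i in np.flatnonzero(~in_seg)]


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    cascades: list[Cascade]
    cascade_edges: set[tuple[str, str, str]]
    malignant_subclusters: set[str]
    front_subcluster: str | None
    marker_genes: dict[str, list[str]]
    decoy_edges: set[tuple[str, str, str]]


@dataclass
class Bundle:
    """Everything the pipeline consumes, plus the ground truth."""

    counts: CountMatrix
    cells: pd.DataFrame
    positions: GenePositions
    priors: PriorKnowledge
    spatial: SpatialTable
    truth: GroundTruth
    config: SynthConfig
    seed: int


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def _plan_priors(config: SynthConfig):
    """Lay out planted cascades, decoy chains and population markers.

    Planted genes are spread evenly across the genome (outside cnv
    segments): signaling genes are not genomically collinear, and a
    contiguous block of co-shifted genes would mimic a focal copy-number
    gain.
    """
    senders = [p[0] for p in config.populations if p[1] == "sender"]
    receivers = [p[0] for p in config.populations if p[1] == "receiver"]
    if config.n_cascades and (not senders or not receivers):
        raise ValueError("cascades need at least one sender and one receiver")
    free = config.free_gene_indices()
    n_planted = (config.n_cascades * (3 + config.targets_per_cascade)
                 + config.decoy_priors * 4
                 + config.markers_per_population * len(config.populations))
    # golden-ratio stride, coprime with the slot count, so consecutively
    # allocated genes (one cascade's members) land far apart on the genome
    stride = max(1, int(len(free) * 0.618))
    while np.gcd(stride, len(free)) != 1:
        stride -= 1
    slots = [free[(j * stride) % len(free)] for j in range(n_planted)]
    names = iter(_gene_name(i) for i in slots)

    def take(k: int) -> list[str]:
        return [next(names) for _ in range(k)]

    cascades: list[Cascade] = []
    for c in range(config.n_cascades):
        genes = take(3 + config.targets_per_cascade)
        cascades.append(Cascade(
            ligand=genes[0], receptor=genes[1], tf=genes[2],
            targets=tuple(genes[3:]),
            sender=senders[c % len(senders)],
            receiver_subcluster=receivers[c % len(receivers)],
            effect=config.cascade_effect))
    decoys: list[Cascade] = []
    for d in range(config.decoy_priors):
        genes = take(4)
        decoys.append(Cascade(
            ligand=genes[0], receptor=genes[1], tf=genes[2],
            targets=(genes[3],),
            sender=senders[d % len(senders)] if senders else "",
            receiver_subcluster=receivers[d % len(receivers)] if receivers else "",
            effect=0.0))
    markers: dict[str, list[str]] = {}
    for name, _, _ in config.populations:
        markers[name] = take(config.markers_per_population)
    return cascades, decoys, markers


def generate(config: SynthConfig, seed: int) -> Bundle:
    """Draw one full synthetic bundle for the given study conditions."""
    config.validate()
    rng = np.random.default_rng(seed)
    n_genes = config.n_genes
    genes = [_gene_name(i) for i in range(n_genes)]

    cascades, decoys, markers = _plan_priors(config)

    # --- cells ------------------------------------------------------------
    records = []
    for name, compartment, n_cells in config.populations:
        for i in range(n_cells):
            records.append({
                "barcode": f"{name.replace(' ', '_')}_{i:04d}",
                "sample": "N1" if compartment == "reference" else "T1",
                "group": "normal" if compartment == "reference" else "tumor",
                "cell_type": ("malignant" if compartment == "receiver"
                              else name),
                "subcluster": name,
                "compartment": compartment,
            })
    cells = pd.DataFrame(records)
    n_cells = len(cells)

    # --- expected counts --------------------------------------------------
    base = np.exp(rng.normal(0.0, GENE_MEAN_SDLOG, size=n_genes))
    gi = {g: i for i, g in enumerate(genes)}
    planted_genes = set()
    for c in cascades:
        planted_genes.update([c.ligand, c.receptor, c.tf, *c.targets])
    for d in decoys:
        planted_genes.update([d.ligand, d.receptor, d.tf, *d.targets])
    for gs in markers.values():
        planted_genes.update(gs)
    for g in planted_genes:
        base[gi[g]] = PLANTED_BASE_MEAN

    size = np.exp(rng.normal(0.0, CELL_SIZE_SDLOG, size=n_cells))
    mu = base[:, None] * size[None, :]

    pop_of = cells["subcluster"].to_numpy()
    for c in cascades:
        send = pop_of == c.sender
        boost = np.exp(c.effect)
        mu[gi[c.ligand], send] *= boost
        recv_idx = np.flatnonzero(pop_of == c.receiver_subcluster)
        mu[gi[c.receptor], recv_idx] *= boost
        # shared on/off latent activity: fires in a fixed fraction of
        # receiver cells, scaled so the subcluster-mean ln-FC is c.effect
        on = rng.random(recv_idx.size) < LATENT_ACTIVE_FRACTION
        latent = np.where(on, np.exp(c.effect) / LATENT_ACTIVE_FRACTION
                          * np.exp(rng.normal(0.0, 0.2, size=recv_idx.size)),
                          1.0)
        for g in (c.tf, *c.targets):
            mu[gi[g], recv_idx] *= latent
    for name, gs in markers.items():
        mask = pop_of == name
        for g in gs:
            mu[gi[g], mask] *= np.exp(MARKER_EFFECT)
    for sub, (lo, hi), fold in config.cnv_segments:
        mask = pop_of == sub
        mu[lo:hi, :][:, mask] *= fold

    # --- negative-binomial draw -------------------------------------------
    r = 1.0 / config.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    matrix = CountMatrix(genes, cells["barcode"].tolist(), sp.csr_matrix(counts))

    # --- gene positions ----------------------------------------------------
    per_chrom = config.genes_per_chromosome
    pos = pd.DataFrame({
        "gene": genes,
        "chromosome": [f"chr{i // per_chrom + 1}" for i in range(n_genes)],
        "start": [(i % per_chrom) * 100_000 + 1 for i in range(n_genes)],
        "end": [(i % per_chrom) * 100_000 + 50_000 for i in range(n_genes)],
    })
    positions = GenePositions(pos, list(dict.fromkeys(pos["chromosome"])))

    # --- priors -------------------------------------------------------------
    lr_pairs, rtf_links, tft_priors = set(), set(), set()
    for c in cascades + decoys:
        lr_pairs.add((c.ligand, c.receptor))
        rtf_links.add((c.receptor, c.tf))
        tft_priors.update((c.tf, t) for t in c.targets)
    priors = PriorKnowledge(lr_pairs, rtf_links, tft_priors)

    # --- spatial layout -----------------------------------------------------
    receivers_list = [p[0] for p in config.populations if p[1] == "receiver"]
    has_front = config.front_subcluster in receivers_list
    bands = {}
    for name, compartment, _ in config.populations:
        if compartment == "receiver":
            if not has_front:
                # exchangeable geometry: every receiver spans core + front
                bands[name] = (0.0, config.front_outer)
            elif name == config.front_subcluster:
                bands[name] = (config.core_radius, config.front_outer)
            else:
                bands[name] = (0.0, config.core_radius)
        elif compartment == "sender":
            bands[name] = (config.front_outer, config.immune_outer)
        else:
            bands[name] = (config.stroma_inner, config.stroma_outer)
    xs, ys = np.empty(n_cells), np.empty(n_cells)
    for name, (r0, r1) in bands.items():
        mask = np.flatnonzero(pop_of == name)
        # uniform over the annulus area
        rad = np.sqrt(rng.uniform(r0 ** 2, r1 ** 2, size=mask.size))
        ang = rng.uniform(0.0, 2.0 * np.pi, size=mask.size)
        xs[mask], ys[mask] = rad * np.cos(ang), rad * np.sin(ang)
    spatial = SpatialTable(pd.DataFrame({
        "unit_id": cells["barcode"], "x": xs, "y": ys,
        "label": cells["cell_type"],
    }))

    receivers = {p[0] for p in config.populations if p[1] == "receiver"}
    truth = GroundTruth(
        cascades=cascades,
        cascade_edges=set().union(*[c.edges() for c in cascades]) if cascades else set(),
        malignant_subclusters={s for s, _, _ in config.cnv_segments},
        front_subcluster=(config.front_subcluster
                          if config.front_subcluster in receivers else None),
        marker_genes=markers,
        decoy_edges=set().union(*[d.edges() for d in decoys]) if decoys else set(),
    )
    validate_cell_table(cells, matrix)
    return Bundle(matrix, cells, positions, priors, spatial, truth, config, seed)


def null_config(n_genes: int = 300, n_cells_per_pop: int = 60,
                decoy_priors: int = 12) -> SynthConfig:
    """Study conditions with no planted structure (calibration runs).

    No cascades, no copy-number segments, no marker programs, and an
    exchangeable spatial layout (every receiver subcluster spans the
    same core+front band), so every screening stage is under its null.
    The decoy priors remain: they supply the unsignaled L-R/R-TF/
    TF-target pairs whose p-values should be uniform.
    """
    return SynthConfig(
        n_genes=n_genes,
        populations=[("macrophage", "sender", n_cells_per_pop),
                     ("T cells", "sender", n_cells_per_pop),
                     ("m1", "receiver", n_cells_per_pop),
                     ("m2", "receiver", n_cells_per_pop),
                     ("normal epi", "reference", n_cells_per_pop)],
        n_cascades=0,
        decoy_priors=decoy_priors,
        cnv_segments=[],
        genes_per_chromosome=50,
        markers_per_population=0,
        front_subcluster="",
    )


FIXTURE_SEED = 20240117


def fixture_config() -> SynthConfig:
    """Pinned small-bundle conditions (<= 200 genes, <= 600 cells)."""
    return SynthConfig(
        n_genes=200,
        populations=[("macrophage", "sender", 100),
                     ("T cells", "sender", 80),
                     ("m1", "receiver", 100),
                     ("m2", "receiver", 100),
                     ("normal epi", "reference", 100)],
        n_cascades=2,
        decoy_priors=8,
        cnv_segments=[("m2", (100, 140), 1.8)],
        genes_per_chromosome=50,
    )


def fixture_small() -> Bundle:
    """The packaged test/doc bundle; regenerates byte-identically."""
    return generate(fixture_config(), seed=FIXTURE_SEED)


def write_bundle(bundle: Bundle, outdir) -> None:
    """Write a bundle to disk in the formats the readers accept."""
    from pathlib import Path

    from . import io as io_

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_.write_counts(bundle.counts, outdir / "counts", format="mtx_triplet")
    io_.write_cell_table(bundle.cells, outdir / "cells.tsv")
    io_.write_gene_positions(bundle.positions, outdir / "gene_positions.tsv")
    io_.write_priors(bundle.priors, outdir / "priors_lr.tsv",
                     outdir / "priors_rtf.tsv", outdir / "priors_tft.tsv")
    io_.write_spatial(bundle.spatial, outdir / "spatial.csv")
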