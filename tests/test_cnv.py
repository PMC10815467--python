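"""CNV residual pipeline, cumulative scoring, malignancy calls."""

import numpy as np
import pandas as pd
import pytest

import igrn
from igrn import cnv, qc
from igrn.cnv import CNVProfile, moving_average_by_chromosome
from igrn.io import GenePositions

from conftest import make_cells, make_counts


def positions_for(genes, chrom_of, start_of):
    df = pd.DataFrame({
        "gene": genes,
        "chromosome": [chrom_of[g] for g in genes],
        "start": [start_of[g] for g in genes],
        "end": [start_of[g] + 10 for g in genes],
    })
    return GenePositions(df, list(dict.fromkeys(df["chromosome"])))


def brute_moving_average(values, chromosomes, window):
    half = window // 2
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        lo, hi = j - half, j + half + 1
        idx = [k for k in range(max(lo, 0), min(hi, values.shape[1]))
               if chromosomes[k] == chromosomes[j]]
        out[:, j] = values[:, idx].mean(axis=1)
    return out


class TestMovingAverage:
    def test_window_one_is_identity(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(4, 9))
        chroms = ["a"] * 5 + ["b"] * 4
        np.testing.assert_array_equal(
            moving_average_by_chromosome(v, chroms, 1), v)

    @pytest.mark.parametrize("window", [3, 5, 7])
    def test_matches_brute_force(self, window):
        rng = np.random.default_rng(window)
        for _ in range(5):
            n = rng.integers(5, 21)
            v = rng.normal(size=(3, n))
            split = rng.integers(1, n)
            chroms = ["chr1"] * split + ["chr2"] * (n - split)
            got = moving_average_by_chromosome(v, chroms, window)
            want = brute_moving_average(v, chroms, window)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_never_crosses_chromosome_boundary(self):
        v = np.array([[0.0, 0.0, 0.0, 100.0, 100.0, 100.0]])
        chroms = ["a"] * 3 + ["b"] * 3
        out = moving_average_by_chromosome(v, chroms, 5)
        assert out[0, :3].max() == 0.0 and out[0, 3:].min() == 100.0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average_by_chromosome(np.ones((1, 4)), ["a"] * 4, 4)


class TestBuildProfile:
    def test_identical_cells_give_zero_residuals(self):
        arr = np.tile(np.arange(1, 7).reshape(-1, 1), (1, 8))
        genes = [f"g{i}" for i in range(6)]
        m = make_counts(arr, genes=genes)
        pos = positions_for(genes, {g: "chr1" for g in genes},
                            {g: i * 100 for i, g in enumerate(genes)})
        prof = cnv.build_cnv_profile(m, pos, {"c0", "c1"}, window=3)
        np.testing.assert_allclose(prof.residuals, 0.0, atol=1e-12)

    def test_reference_mean_profile_is_zero(self, bundle):
        ref = set(bundle.cells.loc[bundle.cells["subcluster"] == "normal epi",
                                   "barcode"])
        prof = cnv.build_cnv_profile(bundle.counts, bundle.positions, ref,
                                     window=31)
        ref_rows = [i for i, c in enumerate(prof.cells) if c in ref]
        np.testing.assert_allclose(prof.residuals[ref_rows].mean(axis=0),
                                   0.0, atol=1e-12)

    def test_genes_position_ordered(self, bundle):
        ref = set(bundle.cells.loc[bundle.cells["subcluster"] == "normal epi",
                                   "barcode"])
        prof = cnv.build_cnv_profile(bundle.counts, bundle.positions, ref,
                                     window=31)
        rank = bundle.positions.chrom_rank()
        tab = bundle.positions.table.set_index("gene")
        keys = [(rank[tab.at[g, "chromosome"]], tab.at[g, "start"])
                for g in prof.genes]
        assert keys == sorted(keys)

    def test_planted_gain_visible_in_segment(self, default_bundle):
        b = default_bundle
        cells = b.cells
        ref = set(cells.loc[cells["subcluster"] == "normal epi", "barcode"])
        epi = cells[cells["compartment"].isin(["receiver", "reference"])]
        prof = cnv.build_cnv_profile(b.counts.subset_cells(epi["barcode"]),
                                     b.positions, ref)
        seg_genes = {f"G{i:04d}" for i in range(300, 360)}  # m1 gain
        inside = [i for i, g in enumerate(prof.genes) if g in seg_genes]
        outside = [i for i, g in enumerate(prof.genes) if g not in seg_genes]
        m1 = [i for i, c in enumerate(prof.cells)
              if c.startswith("m1_")]
        r = prof.residuals[m1]
        assert r[:, inside].mean() - r[:, outside].mean() > 0.1
        mid = inside[len(inside) // 2]
        assert r[:, mid].mean() > 0

    def test_empty_reference_rejected(self):
        m = make_counts(np.ones((4, 4), dtype=int))
        pos = positions_for(m.genes, {g: "chr1" for g in m.genes},
                            {g: i for i, g in enumerate(m.genes)})
        with pytest.raises(ValueError):
            cnv.build_cnv_profile(m, pos, set(), window=1)

    def test_mostly_unpositioned_genes_rejected(self):
        m = make_counts(np.ones((4, 4), dtype=int))
        pos = positions_for(["g0"], {"g0": "chr1"}, {"g0": 1})
        with pytest.raises(ValueError, match="positions"):
            cnv.build_cnv_profile(m, pos, {"c0"}, window=1)


class TestScore:
    def make_profile(self, residuals):
        residuals = np.asarray(residuals, dtype=float)
        cells = [f"c{i}" for i in range(residuals.shape[0])]
        genes = [f"g{j}" for j in range(residuals.shape[1])]
        return CNVProfile(cells, genes, ["chr1"] * len(genes), residuals,
                          window=1, cutoff=0.1, reference_cells=set())

    def test_zero_row_scores_zero(self):
        s = cnv.cnv_score(self.make_profile([[0, 0], [0.1, -0.2]]))
        assert s.loc[s["cell"] == "c0", "score"].iloc[0] == 0.0

    def test_hand_value(self):
        s = cnv.cnv_score(self.make_profile([[0.1, -0.2]]))
        assert np.isclose(s["score"].iloc[0], 0.05)

    def test_gene_order_invariant(self):
        rng = np.random.default_rng(1)
        r = rng.normal(size=(5, 7))
        a = cnv.cnv_score(self.make_profile(r))["score"].to_numpy()
        b = cnv.cnv_score(self.make_profile(r[:, ::-1]))["score"].to_numpy()
        np.testing.assert_allclose(a, b)


class TestCallMalignant:
    def frame(self, scores_by_cell):
        return pd.DataFrame({"cell": list(scores_by_cell),
                             "score": list(scores_by_cell.values())})

    def test_identical_distribution_not_malignant(self):
        vals = list(np.linspace(1, 2, 20))
        scores = self.frame({f"r{i}": v for i, v in enumerate(vals)}
                            | {f"o{i}": v for i, v in enumerate(vals)})
        cells = make_cells([f"o{i}" for i in range(20)], ["sub1"] * 20)
        calls = cnv.call_malignant(scores, cells, {f"r{i}" for i in range(20)})
        assert not calls["is_malignant"].any()

    def test_alpha_zero_never_malignant(self, default_bundle):
        b = default_bundle
        cells = b.cells[b.cells["compartment"].isin(["receiver", "reference"])]
        ref = set(cells.loc[cells["subcluster"] == "normal epi", "barcode"])
        prof = cnv.build_cnv_profile(b.counts.subset_cells(cells["barcode"]),
                                     b.positions, ref)
        calls = cnv.call_malignant(cnv.cnv_score(prof), cells, ref, alpha=0.0)
        assert not calls["is_malignant"].any()

    def test_reference_overlap_rejected(self):
        scores = self.frame({"a": 1.0, "b": 2.0, "c": 3.0, "d": 1.0})
        cells = make_cells(["a", "b", "c"], ["s"] * 3)
        with pytest.raises(ValueError, match="overlap"):
            cnv.call_malignant(scores, cells, {"a", "d"})

    def test_planted_gain_called(self, default_bundle):
        b = default_bundle
        cells = b.cells[b.cells["compartment"].isin(["receiver", "reference"])]
        ref = set(cells.loc[cells["subcluster"] == "normal epi", "barcode"])
        prof = cnv.build_cnv_profile(b.counts.subset_cells(cells["barcode"]),
                                     b.positions, ref)
        calls = cnv.call_malignant(cnv.cnv_score(prof), cells, ref)
        called = set(calls.loc[calls["is_malignant"], "subcluster"])
        assert called == b.truth.malignant_subclusters


class TestClusterSimilarity:
    def test_shared_landscape_highly_correlated(self):
        # two subclusters carrying the same clonal gain/loss landscape
        shared = [((60, 120), 1.5), ((160, 220), 0.6),
                  ((300, 360), 1.8), ((400, 460), 1.8)]
        config = igrn.SynthConfig(
            n_cascades=0, decoy_priors=0, markers_per_population=0,
            cnv_segments=[(s, seg, f) for seg, f in shared
                          for s in ("m1", "m2")])
        b = igrn.generate(config, seed=3)
        cells = b.cells[b.cells["compartment"].isin(["receiver", "reference"])]
        ref = set(cells.loc[cells["subcluster"] == "normal epi", "barcode"])
        prof = cnv.build_cnv_profile(b.counts.subset_cells(cells["barcode"]),
                                     b.positions, ref)
        obs = cells[~cells["barcode"].isin(ref)]
        sim = cnv.cluster_similarity(prof, obs)
        assert sim.loc["m1", "m2"] > 0.80
        assert sim.loc["m1", "m1"] == 1.0 and sim.loc["m2", "m2"] == 1.0
        assert np.isclose(sim.loc["m1", "m2"], sim.loc["m2", "m1"])

    def test_exact_negatives_give_minus_one(self):
        residuals = np.vstack([np.sin(np.linspace(0, 3, 30))] * 2
                              + [-np.sin(np.linspace(0, 3, 30))] * 2)
        prof = CNVProfile([f"c{i}" for i in range(4)],
                          [f"g{j}" for j in range(30)], ["chr1"] * 30,
                          residuals, window=1, cutoff=0.1, reference_cells=set())
        cells = make_cells([f"c{i}" for i in range(4)],
                           ["up", "up", "down", "down"])
        sim = cnv.cluster_similarity(prof, cells)
        assert np.isclose(sim.loc["up", "down"], -1.0)

    def test_constant_profile_reported_missing(self):
        residuals = np.vstack([np.zeros(10), np.arange(10.0)])
        prof = CNVProfile(["c0", "c1"], [f"g{j}" for j in range(10)],
                          ["chr1"] * 10, residuals, window=1, cutoff=0.1,
                          reference_cells=set())
        cells = make_cells(["c0", "c1"], ["flat", "ramp"])
        sim = cnv.cluster_similarity(prof, cells)
        assert np.isnan(sim.loc["flat", "ramp"])


def test_gain_magnitude_monotonicity():
    """A stronger planted gain never lowers the affected subcluster's
    median CNV score (three magnitudes, fixed seed)."""
    medians = []
    for fold in (1.2, 1.5, 1.8):
        config = igrn.SynthConfig(
            n_genes=300, genes_per_chromosome=50,
            populations=[("macrophage", "sender", 40),
                         ("T cells", "sender", 40),
                         ("m1", "receiver", 60),
                         ("m2", "receiver", 60),
                         ("normal epi", "reference", 60)],
            cnv_segments=[("m1", (200, 240), fold)])
        b = igrn.generate(config, seed=4)
        cells = b.cells[b.cells["compartment"].isin(["receiver", "reference"])]
        ref = set(cells.loc[cells["subcluster"] == "normal epi", "barcode"])
        prof = cnv.build_cnv_profile(b.counts.subset_cells(cells["barcode"]),
                                     b.positions, ref, window=31)
        calls = cnv.call_malignant(cnv.cnv_score(prof), cells, ref)
        medians.append(calls.set_index("subcluster").at["m1", "median_score"])
    assert medians[0] <= medians[1] <= medians[2]
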