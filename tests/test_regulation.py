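"""Clustering, group curves, LRC maps and +1/TATA analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nucconsensus.profiles import GeneMatrix
from nucconsensus.regulation import (
    ClusterAssignment,
    assign_plus_one,
    cluster_genes,
    group_density_test,
    group_frequency_curves,
    lrc_map,
    occupancy_feature_matrix,
    subset_window_size,
    tata_contrast,
)
from nucconsensus.tracks_io import BinaryTrack, GenomeAnnotation, NucleosomeCallSet


def matrix(values, flank=800, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"g{i}" for i in range(values.shape[0])]
    return GeneMatrix(values, np.arange(-flank, flank), ids, "tss")


class TestFeatureMatrix:
    @pytest.fixture
    def annotation(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["a", "b", "edge"],
                "chrom": ["chrI"] * 3,
                "strand": ["+", "-", "+"],
                "tss": [2000, 5000, 700],
                "tts": [3000, 4000, 1500],
                "tata": [False, True, False],
                "gene_class": ["unknown"] * 3,
            }
        )
        return GenomeAnnotation(genes, {"chrI": 8000})

    def test_window_gives_exact_columns(self, annotation):
        track = BinaryTrack({"chrI": np.zeros(8000, dtype=np.uint8)})
        m = occupancy_feature_matrix(track, annotation, window=1600)
        assert m.values.shape[1] == 1600
        assert m.offsets[0] == -800 and m.offsets[-1] == 799

    def test_boundary_gene_dropped(self, annotation):
        track = BinaryTrack({"chrI": np.zeros(8000, dtype=np.uint8)})
        m = occupancy_feature_matrix(track, annotation, window=1600)
        assert m.gene_ids == ["a", "b"] and m.n_dropped == 1

    def test_odd_window_rejected(self, annotation):
        track = BinaryTrack({"chrI": np.zeros(8000, dtype=np.uint8)})
        with pytest.raises(ValueError, match="even"):
            occupancy_feature_matrix(track, annotation, window=1601)


def planted_features(n_per=50, seed=0):
    """Four well-separated archetype rows + small noise."""
    rng = np.random.default_rng(seed)
    archetypes = np.zeros((4, 1600))
    for i, bands in enumerate([(0, 1, 2, 3), (0, 1), (0, 2), (3,)]):
        for b in bands:
            archetypes[i, 800 + b * 160 : 800 + b * 160 + 140] = 1.0
    rows, labels = [], []
    for a in range(4):
        for _ in range(n_per):
            rows.append(np.clip(archetypes[a] + rng.normal(0, 0.3, 1600), 0, 2))
            labels.append(a + 1)
    return matrix(np.array(rows)), np.array(labels)


class TestClustering:
    def test_recovers_planted_archetypes(self):
        from sklearn.metrics import adjusted_rand_score

        feats, truth = planted_features()
        assign = cluster_genes(feats, k=4, seed=0)
        assert adjusted_rand_score(truth, assign.labels.to_numpy()) >= 0.8

    def test_deterministic_given_seed(self):
        feats, _ = planted_features()
        a = cluster_genes(feats, k=4, seed=3)
        b = cluster_genes(feats, k=4, seed=3)
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_k1_inertia_is_total_variance(self):
        rng = np.random.default_rng(5)
        x = rng.random((30, 10))
        assign = cluster_genes(matrix(x, flank=5), k=1, seed=0)
        assert assign.inertia == pytest.approx(((x - x.mean(axis=0)) ** 2).sum())

    def test_degenerate_duplicate_rows_rejected(self):
        x = np.tile(np.arange(10.0), (5, 1))
        with pytest.raises(ValueError, match="distinct rows"):
            cluster_genes(matrix(x, flank=5), k=3)

    def test_groups_numbered_by_plus_one_occupancy(self):
        feats, truth = planted_features()
        assign = cluster_genes(feats, k=4, seed=0)
        region = (feats.offsets >= 0) & (feats.offsets <= 150)
        occ = [
            feats.values[np.ix_(assign.labels.to_numpy() == g, region)].mean()
            for g in range(1, 5)
        ]
        assert occ == sorted(occ, reverse=True)


class TestGroupCurves:
    def test_window_size_for_4792_transcripts(self):
        assert subset_window_size(4792, 23) == 209

    def test_single_group_flat_100(self):
        labels = pd.Series(1, index=[f"g{i}" for i in range(100)], name="group")
        assign = ClusterAssignment(labels, 1, 0.0, 0)
        prop = pd.Series(np.arange(100.0), index=labels.index)
        curves = group_frequency_curves(assign, prop, window_genes=10)
        assert (curves["percent"] == 100.0).all()

    def test_monotone_association_recovered(self):
        rng = np.random.default_rng(7)
        n = 600
        labels = pd.Series(
            np.repeat([1, 2], n // 2), index=[f"g{i}" for i in range(n)], name="group"
        )
        prop = pd.Series(labels.to_numpy() + rng.normal(0, 0.5, n), index=labels.index)
        assign = ClusterAssignment(labels, 2, 0.0, 0)
        curves = group_frequency_curves(assign, prop, window_genes=60)
        g2 = curves[curves["group"] == 2]
        rho = stats.spearmanr(g2["mean_property"], g2["percent"]).statistic
        assert rho > 0.9

    def test_fewer_genes_than_window_rejected(self):
        labels = pd.Series([1, 2], index=["a", "b"], name="group")
        assign = ClusterAssignment(labels, 2, 0.0, 0)
        with pytest.raises(ValueError, match="window"):
            group_frequency_curves(assign, pd.Series([1.0, 2.0], index=["a", "b"]), window_genes=5)


class TestDensityTest:
    def _assign(self, labels):
        idx = [f"g{i}" for i in range(len(labels))]
        return ClusterAssignment(pd.Series(labels, index=idx, name="group"), len(set(labels)), 0.0, 0)

    def test_identical_groups(self):
        vals = np.tile(np.arange(20.0), 2)
        assign = self._assign([1] * 20 + [2] * 20)
        rep = group_density_test(assign, pd.Series(vals, index=assign.labels.index))
        assert abs(rep.loc[0, "t"]) < 1e-12 and rep.loc[0, "p"] > 0.99

    def test_five_sigma_shift(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate([rng.normal(0, 1, 200), rng.normal(5, 1, 200)])
        assign = self._assign([1] * 200 + [2] * 200)
        rep = group_density_test(assign, pd.Series(vals, index=assign.labels.index))
        assert rep.loc[0, "p"] < 1e-10

    def test_null_calibration_uniform(self):
        """Permuted labels give uniform p-values (KS at alpha=0.01)."""
        rng = np.random.default_rng(9)
        vals = rng.normal(size=100)
        ps = []
        for _ in range(500):
            labels = rng.permutation([1] * 50 + [2] * 50)
            assign = self._assign(labels)
            rep = group_density_test(assign, pd.Series(vals, index=assign.labels.index))
            ps.append(rep.loc[0, "p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestLRC:
    def test_property_equal_to_window_mean_gives_r_one(self):
        rng = np.random.default_rng(10)
        x = rng.random((50, 400))
        m = GeneMatrix(x, np.arange(-200, 200), [f"g{i}" for i in range(50)], "tss")
        win = x[:, 150:250].mean(axis=1)  # width 100 centred at offset 0
        prop = pd.Series(win, index=m.gene_ids, name="p")
        lrc = lrc_map(m, prop, widths=[100], position_step=1)
        cell = lrc.r[0, np.flatnonzero(lrc.centres == 0)[0]]
        assert cell == pytest.approx(1.0)

    def test_negating_property_negates_map(self):
        rng = np.random.default_rng(11)
        x = rng.random((30, 300))
        m = GeneMatrix(x, np.arange(-150, 150), [f"g{i}" for i in range(30)], "tss")
        prop = pd.Series(rng.normal(size=30), index=m.gene_ids, name="p")
        a = lrc_map(m, prop, widths=[100, 150], position_step=5)
        b = lrc_map(m, -prop, widths=[100, 150], position_step=5)
        np.testing.assert_allclose(a.r, -b.r, equal_nan=True)

    def test_independent_property_mostly_null(self):
        rng = np.random.default_rng(12)
        n = 500
        x = rng.random((n, 400))
        m = GeneMatrix(x, np.arange(-200, 200), [f"g{i}" for i in range(n)], "tss")
        prop = pd.Series(rng.normal(size=n), index=m.gene_ids, name="p")
        lrc = lrc_map(m, prop, widths=range(100, 301, 50), position_step=5)
        frac = np.nanmean(np.abs(lrc.r) > 0.1)
        assert frac <= 0.05

    def test_too_few_genes_rejected(self):
        m = matrix(np.random.default_rng(0).random((2, 100)), flank=50)
        with pytest.raises(ValueError, match="three genes"):
            lrc_map(m, pd.Series([1.0, 2.0], index=m.gene_ids))


def two_gene_annotation():
    genes = pd.DataFrame(
        {
            "gene_id": ["p", "m"],
            "chrom": ["chrI", "chrI"],
            "strand": ["+", "-"],
            "tss": [2000, 6000],
            "tts": [3000, 5000],
            "tata": [True, False],
            "gene_class": ["unknown", "unknown"],
        }
    )
    return GenomeAnnotation(genes, {"chrI": 9000})


class TestPlusOne:
    def _calls(self, dyads):
        return NucleosomeCallSet(
            "s",
            pd.DataFrame(
                {
                    "chrom": "chrI",
                    "start": [d - 73 for d in dyads],
                    "end": [d + 74 for d in dyads],
                    "dyad": dyads,
                }
            ),
        )

    def test_distance_sign_convention(self):
        """A +1 dyad 60 bp downstream of the TSS has TSS - dyad distance -60,
        placing the TSS floor(147/2) - 60 = 13 bp inside the upstream border."""
        ann = two_gene_annotation()
        plus_one = assign_plus_one(self._calls([2060, 5940]), ann)
        assert plus_one.loc["p", "offset"] == 60
        assert plus_one.loc["p", "distance"] == -60
        assert plus_one.loc["m", "offset"] == 60  # minus strand: genomic TSS-60
        border_inset = 147 // 2 - plus_one.loc["p", "offset"]
        assert border_inset == 13

    def test_dyad_at_tss(self):
        plus_one = assign_plus_one(self._calls([2000]), two_gene_annotation())
        assert plus_one.loc["p", "distance"] == 0

    def test_unassigned_counted(self):
        plus_one = assign_plus_one(self._calls([2500]), two_gene_annotation())
        assert len(plus_one) == 0
        assert plus_one.attrs["n_unassigned"] == 2


class TestPlusOneDistanceAnalysis:
    def test_binned_property_means_with_bootstrap(self):
        from nucconsensus.regulation import plus_one_distance_analysis

        rng = np.random.default_rng(20)
        n = 40
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "chrom": "chrI",
                "strand": "+",
                "tss": 2000 + np.arange(n) * 2000,
                "tts": 3000 + np.arange(n) * 2000,
                "tata": False,
                "gene_class": "unknown",
            }
        )
        ann = GenomeAnnotation(genes, {"chrI": int(genes["tss"].max() + 2000)})
        offsets = rng.integers(40, 90, size=n)
        dyads = genes["tss"].to_numpy() + offsets
        calls = NucleosomeCallSet(
            "s",
            pd.DataFrame(
                {"chrom": "chrI", "start": dyads - 73, "end": dyads + 74, "dyad": dyads}
            ),
        )
        props = pd.DataFrame(
            {"activity": offsets.astype(float)}, index=genes["gene_id"]
        )
        per_gene, binned = plus_one_distance_analysis(
            calls, ann, props, bin_width=10, n_boot=100, seed=0
        )
        assert len(per_gene) == n
        np.testing.assert_array_equal(per_gene["offset"].to_numpy(), offsets)
        # property == offset, so binned means must increase with the bin
        b = binned.sort_values("offset_bin")
        assert (np.diff(b["mean"]) > 0).all()
        assert ((b["ci_low"] <= b["mean"]) & (b["mean"] <= b["ci_high"])).all()


class TestTataContrast:
    def _track(self, plus_one_offsets, ann):
        arr = np.zeros(9000, dtype=np.uint8)
        for (gid, off) in plus_one_offsets.items():
            g = ann.genes.set_index("gene_id").loc[gid]
            dyad = g.tss + off if g.strand == "+" else g.tss - off
            arr[dyad - 60 : dyad + 61] = 1
        return BinaryTrack({"chrI": arr})

    def test_planted_offset_difference_recovered(self):
        ann = two_gene_annotation()
        track = self._track({"p": 58, "m": 64}, ann)
        contrast = tata_contrast(ann, track, min_run=80)
        assert contrast.plus_one_offset_tata == pytest.approx(58, abs=1)
        assert contrast.plus_one_offset_tatafree == pytest.approx(64, abs=1)
        assert contrast.offset_difference == pytest.approx(6, abs=2)

    def test_single_class_rejected(self):
        ann = two_gene_annotation()
        genes = ann.genes.copy()
        genes["tata"] = True
        with pytest.raises(ValueError, match="non-empty"):
            tata_contrast(GenomeAnnotation(genes, ann.chrom_sizes), self._track({"p": 58}, ann))
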