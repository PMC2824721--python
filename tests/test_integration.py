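"""Oracle tests for AND / XOR-mean / BDID integration and pair decomposition."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucconsensus.integration import (
    bdid_decompose,
    dataset_correlations,
    decompose_occupancy_pair,
    dyad_density_track,
    logical_and_stack,
    stable_calls_from_track,
    xor_mean_stack,
    xor_pairs,
)
from nucconsensus.tracks_io import BinaryTrack, GenomeAnnotation, NucleosomeCallSet, RealTrack


def tracks_from(rows) -> list[BinaryTrack]:
    return [BinaryTrack({"chrI": np.asarray(r, dtype=np.uint8)}, name=f"t{i}") for i, r in enumerate(rows)]


def all_site_patterns(n: int, length_one: bool = False) -> list[BinaryTrack]:
    """n tracks whose sites jointly enumerate every 0/1 pattern of n datasets."""
    patterns = list(itertools.product([0, 1], repeat=n))
    rows = np.array(patterns).T  # n x 2^n
    return tracks_from(rows)


class TestLogicalAnd:
    def test_idempotent_on_identical_tracks(self):
        row = np.array([0, 1, 1, 0, 1], dtype=np.uint8)
        out = logical_and_stack(tracks_from([row] * 6))
        np.testing.assert_array_equal(out.data["chrI"], row)

    def test_all_zero_absorbs(self):
        rng = np.random.default_rng(0)
        rows = [rng.integers(0, 2, 30) for _ in range(5)] + [np.zeros(30, dtype=int)]
        out = logical_and_stack(tracks_from(rows))
        assert out.data["chrI"].sum() == 0

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6))
    def test_equals_elementwise_minimum(self, seed, n):
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, 2, size=(n, 20))
        out = logical_and_stack(tracks_from(rows)).data["chrI"]
        np.testing.assert_array_equal(out, rows.min(axis=0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            logical_and_stack(tracks_from([[0, 1], [0, 1, 1]]))


class TestXorMean:
    def test_five_datasets_enumerate_ten_pairs(self):
        assert len(xor_pairs(5)) == 10

    def test_matches_explicit_pairwise_oracle_exhaustively(self):
        """On every possible 6-dataset site pattern, the closed form
        k(n-k)/C(n,2) equals the explicit mean over all pairwise XORs."""
        tracks = all_site_patterns(6)
        out = xor_mean_stack(tracks).data["chrI"]
        rows = np.vstack([t.data["chrI"] for t in tracks])
        oracle = np.mean(
            [rows[i] ^ rows[j] for i, j in itertools.combinations(range(6), 2)], axis=0
        )
        np.testing.assert_allclose(out, oracle)

    def test_closed_form_value_k3_of_6(self):
        rows = [[1], [1], [1], [0], [0], [0]]
        out = xor_mean_stack(tracks_from(rows)).data["chrI"]
        assert out[0] == pytest.approx(3 * 3 / 15)  # 0.6

    def test_identical_tracks_vanish(self):
        row = np.array([1, 0, 1, 1])
        out = xor_mean_stack(tracks_from([row] * 5)).data["chrI"]
        assert (out == 0).all()

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 7))
    def test_range_bound_and_unanimity(self, seed, n):
        """xor_mean lies in [0, n/(2(n-1))], with 0 exactly at unanimous sites."""
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, 2, size=(n, 25))
        out = xor_mean_stack(tracks_from(rows)).data["chrI"]
        assert (out >= 0).all() and (out <= n / (2 * (n - 1)) + 1e-12).all()
        unanimous = (rows.sum(axis=0) % n) == 0
        np.testing.assert_array_equal(out == 0, unanimous)


def enumeration_binomial(p: float, n: int, k: int) -> float:
    """Independent oracle: sum over all n-bit outcomes with k ones."""
    total = 0.0
    for bits in itertools.product([0, 1], repeat=n):
        if sum(bits) == k:
            total += math.prod(p if b else 1 - p for b in bits)
    return total


class TestBDID:
    @pytest.fixture
    def random_stack(self):
        rng = np.random.default_rng(42)
        return tracks_from(rng.integers(0, 2, size=(6, 200)))

    def test_probabilities_sum_to_one(self, random_stack):
        bdid = bdid_decompose(random_stack)
        total = sum(bdid.probabilities[k].data["chrI"] for k in range(7))
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_six_choose_two_site(self):
        """A site where 2 of 6 datasets call a nucleosome: the number of
        arrangements is 6-choose-2 = 15, so P{X=2} = 15 p^2 (1-p)^4."""
        rows = [[1], [1], [0], [0], [0], [0]]
        bdid = bdid_decompose(tracks_from(rows))
        p = 2 / 6
        arrangements = sum(
            1 for bits in itertools.product([0, 1], repeat=6) if sum(bits) == 2
        )
        assert arrangements == 15
        assert bdid.probabilities[2].data["chrI"][0] == pytest.approx(
            15 * p**2 * (1 - p) ** 4
        )

    def test_degenerate_p_one(self):
        bdid = bdid_decompose(tracks_from([[1]] * 6))
        assert bdid.probabilities[6].data["chrI"][0] == 1.0
        for k in range(6):
            assert bdid.probabilities[k].data["chrI"][0] == 0.0

    def test_half_p_k3(self):
        rows = [[1], [1], [1], [0], [0], [0]]
        bdid = bdid_decompose(tracks_from(rows))
        assert bdid.probabilities[3].data["chrI"][0] == pytest.approx(20 * 0.5**6)  # 0.3125

    def test_matches_enumeration_oracle(self, random_stack):
        bdid = bdid_decompose(random_stack)
        site = 17
        p = bdid.p.data["chrI"][site]
        for k in range(7):
            assert bdid.probabilities[k].data["chrI"][site] == pytest.approx(
                enumeration_binomial(p, 6, k), abs=1e-12
            )

    def test_linkage_with_and_and_xor(self, random_stack):
        stable = logical_and_stack(random_stack).data["chrI"]
        xor = xor_mean_stack(random_stack).data["chrI"]
        p = bdid_decompose(random_stack).p.data["chrI"]
        np.testing.assert_array_equal(stable == 1, p == 1.0)
        np.testing.assert_array_equal(xor == 0.0, (p == 0.0) | (p == 1.0))

    def test_group_partition(self):
        bdid = bdid_decompose(all_site_patterns(6))
        assert bdid.group(0) == "nfr"
        assert all(bdid.group(k) == "dynamic" for k in range(1, 5))
        assert bdid.group(5) == "stable" and bdid.group(6) == "stable"
        total = (
            bdid.group_track("nfr").data["chrI"]
            + bdid.group_track("dynamic").data["chrI"]
            + bdid.group_track("stable").data["chrI"]
        )
        np.testing.assert_allclose(total, 1.0, atol=1e-12)


class TestDatasetCorrelations:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        row = rng.integers(0, 2, 100)
        (rep,) = dataset_correlations(tracks_from([row, row]), regions=["genome"])
        assert rep.matrix.iloc[0, 1] == pytest.approx(1.0)

    def test_complement_is_minus_one(self):
        rng = np.random.default_rng(2)
        row = rng.integers(0, 2, 100)
        (rep,) = dataset_correlations(tracks_from([row, 1 - row]), regions=["genome"])
        assert rep.matrix.iloc[0, 1] == pytest.approx(-1.0)

    def test_constant_pair_undefined_and_excluded(self):
        rng = np.random.default_rng(3)
        rows = [rng.integers(0, 2, 50), np.zeros(50, dtype=int), rng.integers(0, 2, 50)]
        (rep,) = dataset_correlations(tracks_from(rows), regions=["genome"])
        assert np.isnan(rep.matrix.iloc[0, 1]) and np.isnan(rep.matrix.iloc[1, 1])
        assert rep.n_defined_pairs == 1

    def test_gene_segment_strand_orientation(self):
        """A signal at TSS-100 of a minus-strand gene must land at the same
        promoter position as for its plus-strand twin."""
        genes = pd.DataFrame(
            {
                "gene_id": ["p", "m"],
                "chrom": ["chrI", "chrI"],
                "strand": ["+", "-"],
                "tss": [1000, 3000],
                "tts": [1500, 2500],
                "tata": [False, False],
                "gene_class": ["unknown", "unknown"],
            }
        )
        ann = GenomeAnnotation(genes, {"chrI": 5000})
        a = np.zeros(5000)
        a[900] = 1.0  # plus-strand promoter, offset -100
        a[3100] = 1.0  # minus-strand promoter, offset -100 (genomic +100)
        b = a.copy()
        tr = [RealTrack({"chrI": a}, "a"), RealTrack({"chrI": b}, "b")]
        (rep,) = dataset_correlations(tr, ann, regions=["promoter"])
        assert rep.matrix.iloc[0, 1] == pytest.approx(1.0)

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="unknown region"):
            dataset_correlations(tracks_from([[0, 1], [1, 0]]), regions=["exon"])


def closed_form_axes(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Analytic eigenvectors of a symmetric 2x2 matrix [[a, c], [c, b]]."""
    a, c, b = cov[0, 0], cov[0, 1], cov[1, 1]
    theta = 0.5 * math.atan2(2 * c, a - b)
    v1 = np.array([math.cos(theta), math.sin(theta)])
    v2 = np.array([-math.sin(theta), math.cos(theta)])
    return v1, v2


class TestDecomposePair:
    def test_identical_tracks_have_zero_independent(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=500)
        a = RealTrack({"chrI": x})
        common, indep = decompose_occupancy_pair(a, RealTrack({"chrI": x.copy()}))
        np.testing.assert_allclose(indep.data["chrI"], 0.0, atol=1e-9)
        assert common.data["chrI"].std() > 0

    def test_sign_opposed_tracks_have_zero_common(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=500)
        common, indep = decompose_occupancy_pair(
            RealTrack({"chrI": x}), RealTrack({"chrI": -x})
        )
        np.testing.assert_allclose(common.data["chrI"], 0.0, atol=1e-9)

    def test_matches_closed_form_2x2_eigendecomposition(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=(2, 2000))
        mix = np.array([[1.0, 0.6], [0.2, 1.0]])
        x, y = mix @ z
        a, b = RealTrack({"chrI": x}), RealTrack({"chrI": y})
        common, indep = decompose_occupancy_pair(a, b)
        za = (x - x.mean()) / x.std()
        zb = (y - y.mean()) / y.std()
        v1, v2 = closed_form_axes(np.cov(np.vstack([za, zb])))
        same_sign = v1 if v1[0] * v1[1] >= 0 else v2
        other = v2 if same_sign is v1 else v1
        if same_sign.sum() < 0:
            same_sign = -same_sign
        expected_common = same_sign[0] * za + same_sign[1] * zb
        np.testing.assert_allclose(common.data["chrI"], expected_common, atol=1e-8)
        np.testing.assert_allclose(
            np.abs(indep.data["chrI"]), np.abs(other[0] * za + other[1] * zb), atol=1e-8
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            decompose_occupancy_pair(
                RealTrack({"chrI": np.zeros(10)}), RealTrack({"chrI": np.arange(10.0)})
            )


class TestConsensusCalls:
    def test_runs_become_calls_with_min_run_filter(self):
        arr = np.zeros(1000, dtype=np.uint8)
        arr[100:240] = 1  # one nucleosome-sized run
        arr[500:530] = 1  # too short
        cs = stable_calls_from_track(BinaryTrack({"chrI": arr}), min_run=80)
        assert len(cs) == 1
        assert cs.calls.loc[0, "dyad"] == 170

    def test_long_run_split_at_repeat_length(self):
        arr = np.zeros(1000, dtype=np.uint8)
        arr[100:420] = 1  # 320 bp: two fused nucleosomes
        cs = stable_calls_from_track(BinaryTrack({"chrI": arr}), min_run=80)
        assert len(cs) == 2
        np.testing.assert_array_equal(cs.calls["dyad"], [180, 340])

    def test_dyad_density_counts(self):
        cs = NucleosomeCallSet(
            "t",
            pd.DataFrame({"chrom": ["chrI", "chrI"], "start": [0, 0], "end": [10, 10], "dyad": [5, 5]}),
        )
        tr = dyad_density_track(cs, {"chrI": 20})
        assert tr.data["chrI"][5] == 2 and tr.data["chrI"].sum() == 2
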