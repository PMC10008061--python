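import numpy as np
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from fingerrsa.rdm import RDM
from fingerrsa.repstats import (
    activation_volume,
    block_summaries,
    classical_mds,
    distance_correct,
    euclidean_distance_matrix,
    fisher_z,
    functional_connectivity,
    normalize_structural,
)


class TestEuclideanDistances:
    def test_closed_form_345(self):
        d = euclidean_distance_matrix(np.array([[0.0, 0, 0], [1.0, 2, 2]]))
        assert d.values[0, 1] == pytest.approx(3.0)

    def test_collinear_unit_spacing(self):
        coords = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        d = euclidean_distance_matrix(coords)
        for k in range(5):
            assert d.values[0, k] == pytest.approx(k)

    def test_missing_roi_masked(self):
        coords = np.array([[0.0, 0, 0], [np.nan, 0, 0], [1.0, 0, 0]])
        d = euclidean_distance_matrix(coords)
        assert np.isnan(d.values[1, 0]) and np.isnan(d.values[1, 1])
        assert d.values[0, 2] == pytest.approx(1.0)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance_matrix(np.full((3, 3), np.nan))


class TestActivationVolume:
    @pytest.mark.parametrize(
        "stats,expected",
        [(np.full(10, 5.0), 1.0), (np.zeros(10), 0.0)],
    )
    def test_extremes(self, stats, expected):
        assert activation_volume(stats, np.ones(10, bool), 3.0) == expected

    def test_counting_case(self):
        stats = np.array([0.0, 1, 2, 3, 4, 5, 0, 0, 0, 0])
        assert activation_volume(stats, np.ones(10, bool), 2.5) == pytest.approx(0.3)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            activation_volume(np.ones(5), np.zeros(5, bool), 0.0)


class TestBlockSummaries:
    def test_identity_patterned_cross_block(self):
        m = np.ones((10, 10))
        m[np.arange(5), np.arange(5) + 5] = 0.0
        m[np.arange(5) + 5, np.arange(5)] = 0.0
        np.fill_diagonal(m, 0.0)
        s = block_summaries(m)
        assert s["inter_modality_same"] == 0.0
        assert s["inter_modality_adjacent"] == 1.0

    def test_constant_matrix(self):
        m = np.full((8, 8), 3.5)
        np.fill_diagonal(m, 0.0)
        s = block_summaries(m)
        for key in ("intra_modality_1", "intra_modality_2",
                    "inter_modality_same", "inter_modality_adjacent"):
            assert s[key] == 3.5

    def test_brute_force_oracle_on_random_matrix(self):
        rng = np.random.default_rng(0)
        m = rng.standard_normal((10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        s = block_summaries(m)
        n = 5
        intra1 = np.mean([m[i, i + 1] for i in range(n - 1)])
        intra2 = np.mean([m[n + i, n + i + 1] for i in range(n - 1)])
        same = np.mean([m[i, n + i] for i in range(n)])
        adj = np.mean(
            [m[i, n + i + 1] for i in range(n - 1)] + [m[i + 1, n + i] for i in range(n - 1)]
        )
        assert s["intra_modality_1"] == pytest.approx(intra1, abs=1e-12)
        assert s["intra_modality_2"] == pytest.approx(intra2, abs=1e-12)
        assert s["inter_modality_same"] == pytest.approx(same, abs=1e-12)
        assert s["inter_modality_adjacent"] == pytest.approx(adj, abs=1e-12)

    def test_masked_entries_excluded_with_counts(self):
        m = np.full((6, 6), 2.0)
        np.fill_diagonal(m, 0.0)
        m[0, 3] = m[3, 0] = np.nan  # same-finger cell D1
        s = block_summaries(m)
        assert s["inter_modality_same"] == 2.0
        assert s["inter_modality_same_n"] == 2  # of 3 fingers


class TestFisher:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(0.5493061443340549, abs=1e-12)

    def test_odd_symmetry(self):
        for r in (0.1, 0.3, 0.9):
            assert fisher_z(-r) == pytest.approx(-fisher_z(r))

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)

    def test_functional_connectivity_recovers_latent_correlation(self):
        rng = np.random.default_rng(1)
        latent = rng.standard_normal(4000)
        ts = np.stack([latent + 0.5 * rng.standard_normal(4000) for _ in range(3)])
        fz = functional_connectivity(ts)
        # true pairwise correlation = 1/(1+0.25) = 0.8 -> z = atanh(0.8)
        assert fz.values[0, 1] == pytest.approx(np.arctanh(0.8), abs=0.08)


class TestStructural:
    def test_max_maps_to_one(self):
        counts = np.array([[0.0, 4.0], [4.0, 0.0]])
        assert normalize_structural(counts).values.max() == 1.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 100, (4, 4)).astype(float)
        counts = (counts + counts.T) / 2
        np.fill_diagonal(counts, 0.0)
        a = normalize_structural(counts).values
        b = normalize_structural(7.0 * counts).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_elementwise_division_oracle(self):
        counts = np.array(
            [[0.0, 10, 20, 5], [10, 0, 40, 8], [20, 40, 0, 2], [5, 8, 2, 0]], dtype=float
        )
        np.testing.assert_allclose(normalize_structural(counts).values, counts / 40.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_structural(np.zeros((3, 3)))


class TestDistanceCorrect:
    def test_unit_distances_identity(self):
        conn = RDM(squareform([0.5, 0.2, 0.8]))
        dist = RDM(squareform([1.0, 1.0, 1.0]))
        np.testing.assert_allclose(distance_correct(conn, dist).values, conn.values)

    def test_doubling_distances_halves_values(self):
        conn = RDM(squareform([0.5, 0.2, 0.8]))
        d1 = RDM(squareform([1.0, 2.0, 4.0]))
        d2 = RDM(squareform([2.0, 4.0, 8.0]))
        np.testing.assert_allclose(
            distance_correct(conn, d1).values, 2.0 * distance_correct(conn, d2).values
        )

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        c = squareform(rng.random(6))
        d = squareform(1.0 + rng.random(6))
        out = distance_correct(RDM(c), RDM(d)).values
        off = ~np.eye(4, dtype=bool)
        with np.errstate(invalid="ignore"):
            expected = (c / d)[off]
        np.testing.assert_allclose(out[off], expected, atol=1e-12)

    def test_zero_distance_masked(self):
        conn = RDM(squareform([0.5, 0.2, 0.8]))
        dist = RDM(squareform([0.0, 1.0, 1.0]))
        out = distance_correct(conn, dist)
        assert np.isnan(out.values[0, 1])


class TestClassicalMds:
    def test_collinear_points_recovered_in_1d(self):
        coords = np.array([[0.0], [1.0], [3.0]])
        d = squareform(pdist(coords))
        emb = classical_mds(RDM(d), dims=1)
        np.testing.assert_allclose(squareform(pdist(emb)), d, atol=1e-10)

    def test_planar_hand_configuration_roundtrip(self):
        # five fingertip-like points in a plane: embedding must match
        # the generating configuration up to rotation/reflection
        pts = np.array(
            [[0.0, 0.0], [4.5, 9.0], [6.5, 10.0], [8.5, 9.0], [10.3, 7.0]]
        )
        d = squareform(pdist(pts))
        emb = classical_mds(RDM(d), dims=2)
        _, _, disparity = procrustes(pts, emb)
        assert disparity < 1e-8

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((6, 2))
        d = squareform(pdist(pts))
        perm = rng.permutation(6)
        a = classical_mds(RDM(d), dims=2)
        b = classical_mds(RDM(d[np.ix_(perm, perm)]), dims=2)
        np.testing.assert_allclose(squareform(pdist(b)), squareform(pdist(a[perm])), atol=1e-8)

    def test_excess_dims_padded_with_zeros(self):
        coords = np.array([[0.0], [1.0], [2.0]])
        emb = classical_mds(RDM(squareform(pdist(coords))), dims=3)
        np.testing.assert_allclose(emb[:, 1:], 0.0, atol=1e-10)

    def test_negative_entries_clipped(self, caplog):
        d = squareform([-0.1, 1.0, 1.0])
        with caplog.at_level("WARNING"):
            emb = classical_mds(RDM(d), dims=2)
        assert "clipped" in caplog.text
        assert np.isfinite(emb).all()
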