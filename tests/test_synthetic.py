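import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

import fingerrsa as fr
from fingerrsa.rdm import RDM
from fingerrsa.synthetic import (
    BehavioralSimConfig,
    SimulationConfig,
    build_true_second_moment,
    load_patterns,
    perceived_positions,
    save_patterns,
    simulate_behavior,
    simulate_patterns,
    simulate_rois_and_connectivity,
)


class TestSecondMoment:
    def test_hand_computed_double_centering(self):
        # 3 collinear fingers, d(1,2)=d(2,3)=1, d(1,3)=2: the centered
        # Gram matrix is [[1,0,-1],[0,0,0],[-1,0,1]] (computed by hand),
        # which after unit-diagonal scaling (trace/n = 2/3) and signal
        # variance s becomes s * 3/2 * that matrix.
        model = RDM(np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]]))
        g = build_true_second_moment(model, rho=0.0, signal_variances=(2.0, 2.0))
        expected_block = 2.0 * 1.5 * np.array(
            [[1.0, 0.0, -1.0], [0.0, 0.0, 0.0], [-1.0, 0.0, 1.0]]
        )
        np.testing.assert_allclose(g[:3, :3], expected_block, atol=1e-12)
        np.testing.assert_allclose(g[3:, 3:], expected_block, atol=1e-12)

    def test_rho_one_equal_variances_rank_deficient(self):
        model = RDM(squareform(pdist(np.arange(4, dtype=float)[:, None])))
        g = build_true_second_moment(model, rho=1.0, signal_variances=(1.0, 1.0))
        np.testing.assert_allclose(g[:4, :4], g[4:, 4:], atol=1e-12)
        np.testing.assert_allclose(g[:4, 4:], g[:4, :4], atol=1e-12)
        assert np.linalg.matrix_rank(g, tol=1e-8) <= 4

    def test_rho_zero_cross_block_zero(self):
        model = RDM(squareform(pdist(np.arange(3, dtype=float)[:, None])))
        g = build_true_second_moment(model, rho=0.0, signal_variances=(1.0, 0.5))
        np.testing.assert_allclose(g[:3, 3:], 0.0, atol=1e-12)

    def test_result_is_psd(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((5, 3))
        model = RDM(squareform(pdist(pts)))
        g = build_true_second_moment(model, rho=0.7, signal_variances=(1.0, 2.0))
        assert np.linalg.eigvalsh(g).min() >= -1e-10

    def test_invalid_rho_rejected(self):
        model = RDM(squareform(pdist(np.arange(3, dtype=float)[:, None])))
        with pytest.raises(ValueError):
            build_true_second_moment(model, rho=1.5, signal_variances=(1.0, 1.0))


class TestSimulatePatterns:
    def test_seed_determinism(self):
        config = SimulationConfig(n_subjects=2, n_voxels=30, seed=11)
        a = simulate_patterns(config)
        b = simulate_patterns(config)
        for key in a:
            np.testing.assert_array_equal(a[key].betas, b[key].betas)
            np.testing.assert_array_equal(a[key].residuals, b[key].residuals)

    def test_second_moment_convergence_at_low_noise(self):
        # with many voxels the empirical condition second moment
        # converges to the configured truth (relative Frobenius < 5%)
        config = SimulationConfig(
            n_subjects=1,
            n_voxels=10_000,
            noise_variance=1e-12,
            modality_mean_offset=(0.0, 0.0),
            seed=3,
            regions=("precentral",),
        )
        ds = simulate_patterns(config)[("sub01", "precentral")]
        g_true = build_true_second_moment(
            config.true_model, config.cross_modal_correlation, config.signal_variance
        )
        u = ds.betas[0]
        g_emp = u @ u.T / config.n_voxels
        rel = np.linalg.norm(g_emp - g_true) / np.linalg.norm(g_true)
        assert rel < 0.05

    def test_noise_free_crossnobis_recovers_model_geometry(self):
        # crossnobis on near-noiseless patterns reproduces the
        # generating squared distances up to positive scale (r > 0.99)
        config = SimulationConfig(
            n_subjects=1, n_voxels=4000, noise_variance=1e-10, seed=9,
            regions=("precentral",),
        )
        ds = simulate_patterns(config)[("sub01", "precentral")]
        joint = fr.crossnobis_rdm(ds, noise=None)
        motor = fr.split_modalities(joint)["motor"]
        model_sq = config.true_model.vector() ** 2
        r, _ = pearsonr(motor.vector(), model_sq)
        assert r > 0.99

    def test_odd_repetitions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_repetitions=5)

    def test_hdf5_roundtrip(self, tmp_path):
        config = SimulationConfig(n_subjects=1, n_voxels=20, seed=2)
        datasets = simulate_patterns(config)
        path = tmp_path / "patterns.h5"
        save_patterns(path, datasets, seed=2)
        back = load_patterns(path)
        for key in datasets:
            np.testing.assert_array_equal(back[key].betas, datasets[key].betas)
            assert back[key].conditions == datasets[key].conditions


class TestSimulateBehavior:
    def test_identity_distortion_no_noise_matches_rest(self):
        config = BehavioralSimConfig(
            width_scale=1.0, length_scale=1.0, judgment_noise_sd=0.0,
            n_objects=1, n_kin_trials_per_object=1, n_emg_trials=1,
            emg_duration_s=0.1, kin_duration_s=0.5, seed=0,
        )
        np.testing.assert_allclose(perceived_positions(config), config.rest_positions)

    def test_affine_distortion_closed_form(self):
        config = BehavioralSimConfig(width_scale=1.2, length_scale=0.8)
        target = perceived_positions(config)
        center = config.rest_positions.mean(axis=0)
        manual = center + (config.rest_positions - center) * np.array([1.2, 0.8, 1.0])
        np.testing.assert_allclose(target, manual, atol=1e-12)

    def test_identical_synergy_rows_give_zero_distance(self):
        syn = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.2, 0.6], [0.1, 0.7]])
        config = BehavioralSimConfig(
            synergy_matrix=syn, kin_noise_sd=0.0,
            n_objects=2, n_kin_trials_per_object=2, kin_duration_s=1.0,
            n_emg_trials=1, emg_duration_s=0.1, seed=4,
        )
        beh = simulate_behavior(config)
        rdm = fr.manipulation_model(beh.kinematics)
        assert rdm.values[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_mixing_rejected(self):
        with pytest.raises(ValueError):
            BehavioralSimConfig(synergy_matrix=np.zeros((5, 3)))

    def test_seeded_determinism(self):
        config = BehavioralSimConfig(
            n_objects=1, n_kin_trials_per_object=1, n_emg_trials=1,
            emg_duration_s=0.1, kin_duration_s=0.5, seed=8,
        )
        a = simulate_behavior(config)
        b = simulate_behavior(config)
        np.testing.assert_array_equal(
            a.landmarks[["x", "y", "z"]], b.landmarks[["x", "y", "z"]]
        )
        np.testing.assert_array_equal(a.kinematics["speed"], b.kinematics["speed"])


class TestSimulateRois:
    def test_zero_jitter_unit_spacing_distances(self):
        sim = simulate_rois_and_connectivity(jitter_sd=0.0, spacing=1.0, seed=0)
        grp = sim.roi_centers.query("modality == 'motor' and region == 'precentral'")
        coords = grp.sort_values("finger")[["x", "y", "z"]].to_numpy()
        for k in range(5):
            assert np.linalg.norm(coords[k] - coords[0]) == pytest.approx(k)

    def test_seed_determinism(self):
        a = simulate_rois_and_connectivity(seed=5)
        b = simulate_rois_and_connectivity(seed=5)
        np.testing.assert_array_equal(a.structural_counts, b.structural_counts)
        np.testing.assert_array_equal(a.timeseries, b.timeseries)

    def test_negative_jitter_rejected(self):
        with pytest.raises(ValueError):
            simulate_rois_and_connectivity(jitter_sd=-1.0)

    def test_same_finger_coupling_dominates_downstream(self):
        # direction check: strong same-finger coupling produces higher
        # same-finger than adjacent-finger cross-modal connectivity
        hits = 0
        for seed in range(10):
            sim = simulate_rois_and_connectivity(
                coupling_same=0.7, coupling_adjacent=0.15, n_timepoints=300, seed=seed
            )
            fz = fr.functional_connectivity(sim.timeseries, sim.labels)
            s = fr.block_summaries(fz)
            hits += s["inter_modality_same"] > s["inter_modality_adjacent"]
        assert hits >= 9
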