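import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from fingerrsa.hand_models import (
    manipulation_model,
    model_correlations,
    muscle_model,
    perceived_hand_model,
    real_hand_model,
)
from fingerrsa.rdm import RDM
from fingerrsa.synthetic import perceived_positions


class TestRealHand:
    def test_coincident_fingertips_zero_rdm(self):
        rdm = real_hand_model(np.zeros((4, 3)))
        np.testing.assert_array_equal(rdm.values, 0.0)

    def test_3_4_5_distance(self):
        rdm = real_hand_model(np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 2.0]]), ["D1", "D2"])
        assert rdm.values[0, 1] == pytest.approx(3.0)

    def test_collinear_unit_spacing_closed_form(self):
        coords = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        rdm = real_hand_model(coords)
        i, j = np.indices((5, 5))
        np.testing.assert_allclose(rdm.values, np.abs(i - j))

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            real_hand_model(np.zeros((2, 3)), ["D1", "D1"])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        coords = rng.standard_normal((5, 3))
        perm = [2, 0, 4, 1, 3]
        a = real_hand_model(coords).values
        b = real_hand_model(coords[perm]).values
        np.testing.assert_allclose(b, a[np.ix_(perm, perm)], atol=1e-12)


class TestPerceivedHand:
    def test_exact_judgments_equal_real_model(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [3.0, 4, 0]])
        judgments = pd.DataFrame(
            {"finger": ["D1", "D2", "D3"], "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2]}
        )
        np.testing.assert_array_equal(
            perceived_hand_model(judgments).values, real_hand_model(coords).values
        )

    def test_symmetric_noise_cancels_in_mean(self):
        centers = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        rows = []
        for f, c in zip(["D1", "D2"], centers):
            for delta in ([1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]):
                rows.append((f, *(c + np.array(delta))))
        judgments = pd.DataFrame(rows, columns=["finger", "x", "y", "z"])
        assert perceived_hand_model(judgments).values[0, 1] == pytest.approx(5.0)

    def test_recovers_distorted_geometry_from_noisy_judgments(self):
        from fingerrsa.synthetic import BehavioralSimConfig, simulate_behavior

        config = BehavioralSimConfig(
            judgment_noise_sd=5.0, n_landmark_trials=200,
            n_objects=1, n_kin_trials_per_object=1, n_emg_trials=1,
            emg_duration_s=0.1, kin_duration_s=0.5, seed=21,
        )
        beh = simulate_behavior(config)
        target_rdm = squareform(pdist(perceived_positions(config)))
        recovered = perceived_hand_model(beh.landmarks).values
        # 200 trials at SD 5 mm: mean SE ~0.35 mm per coordinate
        np.testing.assert_allclose(recovered, target_rdm, atol=2.5)


class TestManipulation:
    @staticmethod
    def _frame(traces: np.ndarray, fs: float = 100.0) -> pd.DataFrame:
        n_f, n_t = traces.shape
        rows = []
        for f in range(n_f):
            rows.append(
                pd.DataFrame(
                    {
                        "participant": "P1",
                        "object": 0,
                        "trial": 0,
                        "time": np.arange(n_t) / fs,
                        "finger": f"D{f + 1}",
                        "speed": traces[f],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def test_identical_traces_zero_distance(self):
        trace = 50.0 * np.exp(-0.5 * ((np.arange(200) - 100) / 30.0) ** 2)
        rdm = manipulation_model(self._frame(np.stack([trace, trace, 0.5 * trace])))
        assert rdm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_distance_oracle(self):
        # distances must equal a direct pairwise loop over the
        # conditioned traces; bypass filtering/windowing effects by
        # computing the oracle with the same conditioning steps off
        rng = np.random.default_rng(3)
        traces = 30.0 + 20.0 * rng.random((4, 150))
        rdm = manipulation_model(
            self._frame(traces), cutoff_hz=49.9, speed_threshold=0.0,
            resample_length=150, normalization="none",
        ).values
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, 49.9, fs=100.0, output="sos")
        conditioned = sosfiltfilt(sos, traces, axis=1)
        expected = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                expected[i, j] = np.sqrt(np.sum((conditioned[i] - conditioned[j]) ** 2))
        np.testing.assert_allclose(rdm, expected, atol=1e-10)

    def test_threshold_windowing_removes_padding(self):
        # identical movement, but one trial padded with sub-threshold
        # tails: the windowed distances must agree
        burst = 80.0 * np.exp(-0.5 * ((np.arange(100) - 50) / 12.0) ** 2)
        quiet = np.zeros(40)
        base = np.stack([burst, 0.5 * burst])
        padded = np.stack(
            [np.concatenate([quiet, burst, quiet]), np.concatenate([quiet, 0.5 * burst, quiet])]
        )
        r1 = manipulation_model(self._frame(base)).values[0, 1]
        r2 = manipulation_model(self._frame(padded)).values[0, 1]
        assert r1 == pytest.approx(r2, rel=1e-6)

    def test_trial_without_crossing_excluded(self, caplog):
        ok = 80.0 * np.exp(-0.5 * ((np.arange(100) - 50) / 12.0) ** 2)
        frames = [self._frame(np.stack([ok, 0.3 * ok]))]
        silent = self._frame(np.stack([np.ones(100), np.ones(100)]))
        silent["trial"] = 1
        df = pd.concat(frames + [silent], ignore_index=True)
        with caplog.at_level("WARNING"):
            rdm = manipulation_model(df)
        assert "never crosses" in caplog.text
        assert np.isfinite(rdm.values).all()


class TestMuscle:
    @staticmethod
    def _frame(vectors: np.ndarray, fs: float = 2000.0, n_t: int = 200) -> pd.DataFrame:
        """Constant-amplitude channel profiles per finger."""
        rows = []
        for f in range(vectors.shape[1]):
            for ch in range(vectors.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "participant": "P1",
                            "finger": f"D{f + 1}",
                            "trial": 0,
                            "time": np.arange(n_t) / fs,
                            "channel": ch,
                            "value": np.full(n_t, vectors[ch, f]),
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def test_identical_profiles_zero_distance(self):
        vec = np.array([[1.0, 1.0], [0.5, 0.5], [0.0, 0.0]])
        assert muscle_model(self._frame(vec)).values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_channels_closed_form(self):
        # finger A drives channel 1 at level a, finger B channel 2 at b
        a, b = 2.0, 3.0
        vec = np.array([[a, 0.0], [0.0, b], [0.0, 0.0]])
        assert muscle_model(self._frame(vec)).values[0, 1] == pytest.approx(
            np.hypot(a, b), rel=1e-6
        )

    def test_matrix_column_oracle(self):
        rng = np.random.default_rng(9)
        coact = rng.random((6, 4))
        rdm = muscle_model(self._frame(coact)).values
        expected = squareform(pdist(coact.T))
        np.testing.assert_allclose(rdm, expected, rtol=1e-6)


class TestModelCorrelations:
    def test_self_correlation_and_formula_oracle(self):
        rng = np.random.default_rng(2)
        mats = [RDM(squareform(rng.random(10))) for _ in range(3)]
        table = model_correlations(mats)
        np.testing.assert_allclose(np.diag(table.to_numpy()), 1.0, atol=1e-12)
        v0, v1 = mats[0].vector(), mats[1].vector()
        manual = np.sum((v0 - v0.mean()) * (v1 - v1.mean())) / np.sqrt(
            np.sum((v0 - v0.mean()) ** 2) * np.sum((v1 - v1.mean()) ** 2)
        )
        assert table.iloc[0, 1] == pytest.approx(manual, abs=1e-12)

    def test_negated_model_gives_minus_one(self):
        base = squareform(np.array([1.0, 2.0, 3.0]))
        flipped = squareform(2.0 * np.mean([1.0, 2.0, 3.0]) - np.array([1.0, 2.0, 3.0]))
        table = model_correlations([RDM(base), RDM(flipped)])
        assert table.iloc[0, 1] == pytest.approx(-1.0)

    def test_constant_model_rejected(self):
        with pytest.raises(ValueError):
            model_correlations([RDM(np.zeros((3, 3))), RDM(squareform([1.0, 2.0, 3.0]))])
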