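"""Property-based evaluations of the full analysis stack.

Because the original subject-level recordings are not publicly
released, the package validates itself against ground-truth-known
synthetic studies: estimator unbiasedness and closed-form limits for
the crossnobis distances, recovery of the generating cross-modal
correlation by PCM, recovery of generating mixture weights by the
non-negative RSA regression, noise-ceiling dominance, limiting values
of the order-constrained Bayes factors, and the qualitative
end-to-end direction effects (same-finger cross-modal organization).
These functions are used both by the test suite and by the
reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from . import hand_models, pcm, repstats, rsa
from .crossnobis import (
    crossnobis_rdm,
    naive_mahalanobis_rdm,
    partition_even_odd,
    remove_condition_mean,
)
from .order_bayes import HypothesisSpec, bayes_factor, estimate_group_posterior
from .pipeline import PipelineConfig, build_behavioral_models
from .rdm import RDM
from .synthetic import (
    SimulationConfig,
    simulate_patterns,
    simulate_rois_and_connectivity,
)


def crossnobis_unbiasedness(
    n_sims: int = 1000, n_voxels: int = 20, seed: int = 0
) -> dict[str, float]:
    """Zero-signal simulations: crossnobis mean ~ 0, naive estimator
    positively biased."""
    cross_means, naive_means = [], []
    for i in range(n_sims):
        config = SimulationConfig(
            n_subjects=1, n_voxels=n_voxels, signal_variance=(0.0, 0.0),
            seed=seed + i, regions=("precentral",),
        )
        ds = simulate_patterns(config)[("sub01", "precentral")]
        cross_means.append(np.nanmean(crossnobis_rdm(ds, noise=None).vector()))
        naive_means.append(np.nanmean(naive_mahalanobis_rdm(ds).vector()))
    cross_means = np.asarray(cross_means)
    return {
        "mean_distance": float(cross_means.mean()),
        "se": float(cross_means.std(ddof=1) / np.sqrt(n_sims)),
        "naive_mean_distance": float(np.mean(naive_means)),
        "n": n_sims,
    }


def crossnobis_euclidean_limit(n_instances: int = 20, seed: int = 0) -> dict[str, float]:
    """Noise-free, identity-whitening limit: crossnobis equals squared
    Euclidean distance of partition means / P (brute-force loop)."""
    from .crossnobis import ActivityDataset

    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_instances):
        p = int(rng.integers(5, 30))
        patterns = rng.standard_normal((5, p))
        betas = np.tile(patterns, (4, 1, 1))  # noise -> 0: identical repetitions
        ds = ActivityDataset(
            "s", "r", betas, rng.standard_normal((10, p)),
            [(f"D{i+1}", "motor") for i in range(5)],
        )
        est = crossnobis_rdm(ds, noise=None).values
        centered = remove_condition_mean(patterns)
        for i in range(5):
            for j in range(5):
                expected = np.sum((centered[i] - centered[j]) ** 2) / p
                max_err = max(max_err, abs(est[i, j] - expected))
    return {"max_abs_error": float(max_err), "n": n_instances}


def pcm_dense_oracle(seed: int = 0) -> dict[str, float]:
    """Eigendecomposition log-likelihood vs dense MVN density."""
    from scipy.stats import multivariate_normal

    from .pcm import _observations

    config = SimulationConfig(
        n_subjects=1, n_fingers=2, n_voxels=10, seed=seed, regions=("precentral",)
    )
    ds = simulate_patterns(config)[("sub01", "precentral")]
    gh = pcm.estimate_unit_geometry(ds)
    model = pcm.build_model_grid(gh)[9]
    s1, s2, sn = 0.9, 1.4, 0.8
    ll = pcm.pcm_loglik(model, ds, np.log([s1, s2, sn]))
    y, z, p = _observations(ds)
    v = z @ model.joint_g(s1, s2) @ z.T + sn * np.eye(z.shape[0])
    dense = sum(
        multivariate_normal.logpdf(y[:, i], mean=np.zeros(y.shape[0]), cov=v)
        for i in range(p)
    )
    return {"abs_error": float(abs(ll - dense)), "n": p}


def pcm_recovery(
    n_replicates: int = 50,
    n_subjects: int = 20,
    n_voxels: int = 200,
    true_rs: tuple[float, ...] = (0.2, 0.5, 0.8),
    seed: int = 0,
) -> dict[str, float]:
    """Recovery of the generating cross-modal correlation.

    Per replicate: modal best-model r across subjects; success = modal
    r within one grid step (0.05) of the truth.
    """
    rates = {}
    all_modal, all_truth = [], []
    for r_idx, true_r in enumerate(true_rs):
        hits = 0
        for rep in range(n_replicates):
            config = SimulationConfig(
                n_subjects=n_subjects, n_voxels=n_voxels,
                cross_modal_correlation=true_r,
                seed=seed + 100_000 * r_idx + rep, regions=("precentral",),
            )
            datasets = simulate_patterns(config)
            best = np.array([pcm.fit_pcm_grid(ds).best_r for ds in datasets.values()])
            vals, counts = np.unique(np.round(best, 3), return_counts=True)
            modal = float(vals[np.argmax(counts)])
            hits += abs(modal - true_r) <= 0.0501
            all_modal.append(modal)
            all_truth.append(true_r)
        rates[f"rate_r{true_r:g}"] = hits / n_replicates
    rank_corr, _ = spearmanr(all_truth, all_modal)
    return {**rates, "rank_correlation": float(rank_corr), "n": n_replicates}


def nnls_recovery(
    n_replicates: int = 100, n_subjects: int = 50, noise_sd: float = 0.5, seed: int = 0
) -> dict[str, float]:
    """Recovery of the generating (0.7, 0.3) mixture by NNLS."""
    rng = np.random.default_rng(seed)
    n_pairs = 10  # 5-finger upper triangle

    def orthonormal_models():
        a = rng.standard_normal(n_pairs)
        b = rng.standard_normal(n_pairs)
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= (b @ a) / (a @ a) * a
        b = b / b.std()
        return a, b

    m1, m2 = orthonormal_models()
    d = 0.7 * m1 + 0.3 * m2
    res = rsa.nnls_multiple_regression(d, [m1, m2])
    exact_err = float(np.max(np.abs(res.betas - [0.7, 0.3])))

    hits = 0
    for _ in range(n_replicates):
        m1, m2 = orthonormal_models()
        betas = np.array(
            [
                rsa.nnls_multiple_regression(
                    0.7 * m1 + 0.3 * m2 + noise_sd * rng.standard_normal(n_pairs),
                    [m1, m2],
                ).betas
                for _ in range(n_subjects)
            ]
        )
        mean_beta = betas.mean(axis=0)
        hits += mean_beta[0] > mean_beta[1]
    return {
        "noise_free_max_error": exact_err,
        "ordering_rate": hits / n_replicates,
        "n": n_replicates,
    }


def noise_ceiling_dominance(
    n_replicates: int = 100,
    n_subjects: int = 20,
    shared_sd: float = 0.3,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> dict[str, float]:
    """Leave-one-out ceiling vs the generating model's mean fit.

    Subject RDM vectors share the model structure plus a common
    non-model deviation (idiosyncratic to the replicate group) plus
    subject noise; the ceiling must capture the shared deviation that
    the model misses.
    """
    rng = np.random.default_rng(seed)
    n_pairs = 10
    dominated = 0
    differences = []
    for _ in range(n_replicates):
        model = rng.standard_normal(n_pairs)
        model = (model - model.mean()) / model.std()
        shared = shared_sd * rng.standard_normal(n_pairs)
        subjects = [
            model + shared + noise_sd * rng.standard_normal(n_pairs)
            for _ in range(n_subjects)
        ]
        nc = rsa.noise_ceiling(subjects)
        fits = [
            rsa.simple_regressions(
                rsa.vectorize_and_zscore(s), [model]
            ).betas[0]
            for s in subjects
        ]
        differences.append(nc.ceiling - np.mean(fits))
        dominated += differences[-1] >= 0
    differences = np.asarray(differences)
    identical = rsa.noise_ceiling([squareform(pdist(np.arange(5.0)[:, None]))] * 4).ceiling
    return {
        "dominance_rate": dominated / n_replicates,
        "mean_ceiling_minus_model_fit": float(differences.mean()),
        "mean_difference_se": float(differences.std(ddof=1) / np.sqrt(n_replicates)),
        "identical_subject_ceiling": float(identical),
        "n": n_replicates,
    }


def order_bayes_limits(
    n_mc: int = 1_000_000, n_replicates: int = 200, seed: int = 0
) -> dict[str, float]:
    """Limiting values of the informative-hypothesis Bayes factors."""
    rng = np.random.default_rng(seed)
    table = np.array([10.0, 20.0, 30.0, 40.0]) + 0.01 * rng.standard_normal((20, 4))
    est = estimate_group_posterior(table)
    strong = bayes_factor(est, HypothesisSpec("ordering"), n_mc=n_mc, seed=seed)
    unconstrained = bayes_factor(est, HypothesisSpec("unconstrained"))

    bfs = []
    for rep in range(n_replicates):
        t = 2.0 + 0.5 * rng.standard_normal((20, 4))
        e = estimate_group_posterior(t)
        bfs.append(
            bayes_factor(e, HypothesisSpec("ordering"), n_mc=100_000, seed=seed + rep).bf
        )
    bfs = np.asarray(bfs)
    return {
        "bf_ordering_strong": strong.bf,
        "bf_ordering_strong_mc_error": strong.mc_error,
        "bf_unconstrained": unconstrained.bf,
        "exchangeable_mean_bf": float(bfs.mean()),
        "exchangeable_mean_bf_se": float(bfs.std(ddof=1) / np.sqrt(n_replicates)),
        "exchangeable_median_bf": float(np.median(bfs)),
        "n": n_replicates,
    }


def hand_model_closed_forms(seed: int = 0) -> dict[str, float]:
    """Closed-form checks of the behavioral model builders."""
    import pandas as pd

    coords = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    linear = hand_models.real_hand_model(coords)
    i, j = np.indices((5, 5))
    linear_err = float(np.max(np.abs(linear.values - np.abs(i - j))))

    judgments = pd.DataFrame(
        {"finger": [f"D{k+1}" for k in range(5)],
         "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2]}
    )
    perceived = hand_models.perceived_hand_model(judgments)
    identity_exact = bool(np.array_equal(perceived.values, linear.values))

    # manipulation: brute-force pairwise loop on the conditioned traces
    rng = np.random.default_rng(seed)
    traces = 30.0 + 20.0 * rng.random((4, 150))
    frame = pd.concat(
        [
            pd.DataFrame(
                {"participant": "P1", "object": 0, "trial": 0,
                 "time": np.arange(150) / 100.0, "finger": f"D{f+1}",
                 "speed": traces[f]}
            )
            for f in range(4)
        ],
        ignore_index=True,
    )
    from scipy.signal import butter, sosfiltfilt

    got = hand_models.manipulation_model(
        frame, cutoff_hz=49.9, speed_threshold=0.0,
        resample_length=150, normalization="none",
    ).values
    cond = sosfiltfilt(butter(4, 49.9, fs=100.0, output="sos"), traces, axis=1)
    manip_err = 0.0
    for a in range(4):
        for b in range(4):
            manip_err = max(
                manip_err, abs(got[a, b] - np.sqrt(np.sum((cond[a] - cond[b]) ** 2)))
            )

    # muscle: constant channel profiles, matrix-column oracle
    coact = rng.random((6, 4))
    rows = []
    for f in range(4):
        for ch in range(6):
            rows.append(
                pd.DataFrame(
                    {"participant": "P1", "finger": f"D{f+1}", "trial": 0,
                     "time": np.arange(200) / 2000.0, "channel": ch,
                     "value": np.full(200, coact[ch, f])}
                )
            )
    emg_got = hand_models.muscle_model(pd.concat(rows, ignore_index=True)).values
    muscle_err = float(np.max(np.abs(emg_got - squareform(pdist(coact.T)))))

    return {
        "collinear_max_error": linear_err,
        "identity_perception_exact": float(identity_exact),
        "manipulation_oracle_error": float(manip_err),
        "muscle_oracle_error": muscle_err,
        "n": 5,
    }


def end_to_end_direction(
    n_replicates: int = 50,
    n_subjects: int = 6,
    n_voxels: int = 120,
    seed: int = 0,
) -> dict[str, float]:
    """Full-pipeline direction checks on same-finger-coupled data.

    (a) same-finger cross-modal dissimilarity below adjacent-finger;
    (b) same-finger cross-modal connectivity above adjacent-finger;
    (c) highest mean NNLS weight on the generating perceived-hand model.
    """
    config = PipelineConfig(seed=seed, n_subjects=n_subjects, n_voxels=n_voxels)
    models = build_behavioral_models(config)
    generating = models["perceived_hand"]
    model_list = list(models.values())

    a_hits = b_hits = c_hits = 0
    for rep in range(n_replicates):
        sim = SimulationConfig(
            n_subjects=n_subjects, n_voxels=n_voxels, true_model=generating,
            cross_modal_correlation=config.cross_modal_correlation,
            seed=seed + 1000 + rep,
        )
        datasets = simulate_patterns(sim)
        same, adjacent = [], []
        betas: dict[str, list[float]] = {name: [] for name in models}
        for ds in datasets.values():
            from .crossnobis import estimate_noise, split_modalities

            joint = crossnobis_rdm(ds, noise=estimate_noise(ds.residuals))
            s = repstats.block_summaries(joint)
            same.append(s["inter_modality_same"])
            adjacent.append(s["inter_modality_adjacent"])
            for modality, sub in split_modalities(joint).items():
                res = rsa.fit_rdm_models(sub, model_list, mode="nnls")
                for name, b in res.to_dict().items():
                    betas[name].append(b)
        a_hits += np.mean(same) < np.mean(adjacent)
        mean_betas = {name: np.mean(v) for name, v in betas.items()}
        c_hits += max(mean_betas, key=mean_betas.get) == "perceived_hand"

        conn = simulate_rois_and_connectivity(
            coupling_same=config.coupling_same,
            coupling_adjacent=config.coupling_adjacent,
            seed=seed + 5000 + rep,
        )
        fz = repstats.functional_connectivity(conn.timeseries, conn.labels)
        s = repstats.block_summaries(fz)
        b_hits += s["inter_modality_same"] > s["inter_modality_adjacent"]

    return {
        "dissimilarity_rate": a_hits / n_replicates,
        "connectivity_rate": b_hits / n_replicates,
        "generating_model_rate": c_hits / n_replicates,
        "n": n_replicates,
    }


def mds_roundtrip() -> dict[str, float]:
    """Planar five-point hand configuration recovered by classical MDS."""
    pts = np.array([[0.0, 0.0], [4.5, 9.0], [6.5, 10.0], [8.5, 9.0], [10.3, 7.0]])
    d = squareform(pdist(pts))
    emb = repstats.classical_mds(RDM(d), dims=2)
    _, _, disparity = procrustes(pts, emb)
    return {"procrustes_disparity": float(disparity), "n": 5}
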