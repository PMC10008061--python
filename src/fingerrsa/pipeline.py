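"""End-to-end orchestration: simulate -> models -> RDMs -> PCM -> RSA
-> somatotopy -> connectivity -> report.

Each stage derives its own sub-seed from the master seed through
`numpy.random.SeedSequence` spawn keys, so a stage's randomness does
not depend on whether earlier stages ran. Outputs carry the config
hash and seed for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hand_models, order_bayes, pcm, repstats, rsa, synthetic
from .crossnobis import crossnobis_rdm, estimate_noise, split_modalities
from .rdm import RDM, average_rdms

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "models", "rdm", "pcm", "rsa", "somatotopy", "connectivity")


@dataclass
class PipelineConfig:
    """Single configuration for a full synthetic-data analysis run."""

    seed: int = 0
    n_subjects: int = 6
    n_fingers: int = 5
    n_voxels: int = 120
    n_repetitions: int = 6
    cross_modal_correlation: float = 0.8
    signal_variance: tuple[float, float] = (1.0, 1.0)
    noise_variance: float = 1.0
    generating_model: str = "perceived_hand"
    model_subset: tuple[str, ...] | None = None
    n_behavioral_participants: int = 6
    whitening: str = "analytic"  # or "identity"
    mean_removal: str = "voxel"
    pcm_grid: tuple[float, float, int] = (0.05, 1.0, 20)
    run_pcm: bool = True
    bayes_margin: float = 0.25
    n_mc: int = 200_000
    fdr_alpha: float = 0.05
    coupling_same: float = 0.6
    coupling_adjacent: float = 0.2
    roi_jitter_sd: float = 0.5
    roi_spacing: float = 2.0

    def __post_init__(self) -> None:
        if self.model_subset is None:
            # the 6-finger variant drops the muscle model
            self.model_subset = (
                ("real_hand", "perceived_hand", "manipulation")
                if self.n_fingers == 6
                else ("real_hand", "perceived_hand", "manipulation", "muscle")
            )
        if not self.model_subset:
            raise ValueError("model subset must be non-empty")

    def stage_seed(self, stage: str) -> int:
        idx = _STAGES.index(stage)
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % (2**31))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        kwargs = {}
        for f_ in dataclasses.fields(cls):
            if f_.name in raw:
                val = raw[f_.name]
                kwargs[f_.name] = tuple(val) if isinstance(val, list) else val
        return cls(**kwargs)


def build_behavioral_models(config: PipelineConfig) -> dict[str, RDM]:
    """Construct the behavioral model RDMs from simulated recordings.

    Real and perceived hand come from the rest geometry and the
    landmark judgments pooled over participants; manipulation and
    muscle average single-participant RDMs, as in the group models.
    """
    seed0 = config.stage_seed("models")
    fingers = synthetic.finger_labels(config.n_fingers)
    sims = [
        synthetic.simulate_behavior(
            synthetic.BehavioralSimConfig(n_fingers=config.n_fingers, seed=seed0 + i),
            participant=f"B{i + 1:02d}",
        )
        for i in range(config.n_behavioral_participants)
    ]
    models: dict[str, RDM] = {}
    models["real_hand"] = hand_models.real_hand_model(sims[0].rest_positions)
    perceived = [hand_models.perceived_hand_model(s.landmarks) for s in sims]
    models["perceived_hand"] = average_rdms(perceived, provenance="perceived_hand")
    if "manipulation" in config.model_subset:
        kin = pd.concat([s.kinematics for s in sims], ignore_index=True)
        models["manipulation"] = hand_models.manipulation_model(kin)
    if "muscle" in config.model_subset:
        emg = pd.concat([s.emg for s in sims], ignore_index=True)
        models["muscle"] = hand_models.muscle_model(emg)
    for m in models.values():
        assert m.labels == fingers
    return {k: models[k] for k in config.model_subset}


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute all stages and return the report bundle.

    With `outdir` set, RDMs, coefficient tables and the JSON report are
    also written to disk.
    """
    bundle: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    # --- models ---------------------------------------------------
    models = build_behavioral_models(config)
    bundle["models"] = models
    bundle["model_correlations"] = hand_models.model_correlations(list(models.values()))
    generating = models[config.generating_model]

    # --- simulate patterns ---------------------------------------
    sim_config = synthetic.SimulationConfig(
        n_subjects=config.n_subjects,
        n_fingers=config.n_fingers,
        n_voxels=config.n_voxels,
        n_repetitions=config.n_repetitions,
        true_model=generating,
        cross_modal_correlation=config.cross_modal_correlation,
        signal_variance=config.signal_variance,
        noise_variance=config.noise_variance,
        seed=config.stage_seed("simulate"),
    )
    datasets = synthetic.simulate_patterns(sim_config)

    # --- crossnobis RDMs ------------------------------------------
    joint_rdms: dict[tuple[str, str], RDM] = {}
    modality_rdms: dict[tuple[str, str, str], RDM] = {}
    for key, ds in datasets.items():
        noise = None if config.whitening == "identity" else estimate_noise(
            ds.residuals, shrinkage=config.whitening
        )
        joint = crossnobis_rdm(ds, noise=noise, mean_removal=config.mean_removal)
        joint_rdms[key] = joint
        for modality, sub in split_modalities(joint).items():
            modality_rdms[key + (modality,)] = sub
    bundle["joint_rdms"] = joint_rdms
    bundle["modality_rdms"] = modality_rdms

    # --- block summaries (dissimilarity) --------------------------
    summaries = []
    for (subject, region), joint in joint_rdms.items():
        row = repstats.block_summaries(joint, n_fingers=config.n_fingers)
        summaries.append({"subject": subject, "region": region, **row})
    bundle["dissimilarity_summaries"] = pd.DataFrame(summaries)

    # --- PCM ------------------------------------------------------
    if config.run_pcm:
        r_min, r_max, n_models = config.pcm_grid
        fits = {
            key: pcm.fit_pcm_grid(ds, r_min=r_min, r_max=r_max, n_models=int(n_models))
            for key, ds in datasets.items()
        }
        bundle["pcm_fits"] = fits
        by_region: dict[str, list] = {}
        for (subject, region), fit in fits.items():
            by_region.setdefault(region, []).append(fit)
        bundle["pcm_comparison"] = {
            region: pcm.compare_best_vs_rest(region_fits)
            for region, region_fits in by_region.items()
            if len(region_fits) >= 2
        }

    # --- RSA ------------------------------------------------------
    model_list = list(models.values())
    rows = []
    for (subject, region, modality), neural in modality_rdms.items():
        for mode in ("nnls", "simple"):
            res = rsa.fit_rdm_models(neural, model_list, mode=mode)
            for name, beta in res.to_dict().items():
                rows.append(
                    {
                        "subject": subject,
                        "region": region,
                        "task": modality,
                        "model": name,
                        "beta": beta,
                        "fit_type": mode,
                    }
                )
    coef = pd.DataFrame(rows)
    bundle["rsa_coefficients"] = coef

    ceilings = []
    for (region, modality), cell in coef.groupby(["region", "task"]):
        cell_rdms = [
            modality_rdms[(s, region, modality)]
            for s in sorted({k[0] for k in modality_rdms if k[1] == region and k[2] == modality})
        ]
        nc = rsa.noise_ceiling(cell_rdms)
        ceilings.append(
            {"region": region, "task": modality, "ceiling": nc.ceiling, "n": nc.n_subjects}
        )
    bundle["noise_ceilings"] = pd.DataFrame(ceilings)

    nnls_rows = coef[coef.fit_type == "nnls"]
    bundle["rsa_contrasts"] = rsa.group_contrasts(
        nnls_rows.groupby(["subject", "model"], as_index=False)["beta"].mean(),
        value="beta", within="model", unit="subject", alpha=config.fdr_alpha,
    )

    # --- somatotopy + connectivity --------------------------------
    soma_seed = config.stage_seed("somatotopy")
    conn_seed = config.stage_seed("connectivity")
    distance_rows = {}
    conn_summaries = []
    bf_reports = {}
    n = config.n_fingers
    for s in range(config.n_subjects):
        sim = synthetic.simulate_rois_and_connectivity(
            somatotopic=True,
            n_fingers=n,
            jitter_sd=config.roi_jitter_sd,
            spacing=config.roi_spacing,
            coupling_same=config.coupling_same,
            coupling_adjacent=config.coupling_adjacent,
            seed=conn_seed + s,
        )
        centers = sim.roi_centers
        for (modality, region), grp in centers.groupby(["modality", "region"]):
            coords = grp.sort_values("finger")[["x", "y", "z"]].to_numpy()
            dmat = repstats.euclidean_distance_matrix(coords, synthetic.finger_labels(n))
            if n >= 5:
                distance_rows.setdefault((modality, region), []).append(dmat.values[0, 1:5])

        func = repstats.functional_connectivity(sim.timeseries, sim.labels)
        struct = repstats.normalize_structural(sim.structural_counts, sim.labels)
        joint_coords = np.vstack(
            [
                centers[(centers.modality == m) & (centers.region == "precentral")]
                .sort_values("finger")[["x", "y", "z"]]
                .to_numpy()
                + (0.0 if m == "motor" else 1.0)  # modalities occupy offset sheets
                for m in synthetic.MODALITIES
            ]
        )
        roi_dist = repstats.euclidean_distance_matrix(joint_coords, sim.labels)
        for kind, mat in (("functional", func), ("structural", struct)):
            corrected = repstats.distance_correct(mat, roi_dist)
            row = repstats.block_summaries(corrected, n_fingers=n)
            conn_summaries.append({"subject": f"sub{s + 1:02d}", "kind": kind, **row})
    bundle["connectivity_summaries"] = pd.DataFrame(conn_summaries)

    if n >= 5:
        for (modality, region), rows_ in distance_rows.items():
            table = np.stack(rows_)
            if np.isfinite(table).all(axis=1).sum() < 2:
                logger.warning(
                    "somatotopy cell %s/%s skipped: fewer than 2 complete hands",
                    region, modality,
                )
                continue
            bf_reports[f"{region}_{modality}"] = order_bayes.somatotopy_analysis(
                table, margin=config.bayes_margin, n_mc=config.n_mc, seed=soma_seed
            )
        bundle["somatotopy"] = bf_reports

    # --- MDS projections ------------------------------------------
    bundle["mds"] = {
        key: repstats.classical_mds(joint, dims=2) for key, joint in joint_rdms.items()
    }

    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    rdm_dir = outdir / "rdms"
    rdm_dir.mkdir(exist_ok=True)
    for (subject, region), joint in bundle["joint_rdms"].items():
        joint.to_csv(rdm_dir / f"{subject}_{region}_joint.csv")
    model_dir = outdir / "models"
    model_dir.mkdir(exist_ok=True)
    for name, model in bundle["models"].items():
        model.to_csv(model_dir / f"{name}.csv")
    bundle["rsa_coefficients"].to_csv(outdir / "rsa_coefficients.tsv", sep="\t", index=False)
    bundle["noise_ceilings"].to_csv(outdir / "noise_ceilings.tsv", sep="\t", index=False)
    bundle["dissimilarity_summaries"].to_csv(
        outdir / "dissimilarity_summaries.tsv", sep="\t", index=False
    )
    bundle["connectivity_summaries"].to_csv(
        outdir / "connectivity_summaries.tsv", sep="\t", index=False
    )
    report = {
        "config_hash": bundle["config_hash"],
        "seed": bundle["seed"],
        "noise_ceilings": bundle["noise_ceilings"].to_dict(orient="records"),
    }
    if "somatotopy" in bundle:
        report["somatotopy"] = {
            cell: {
                "bayes_factors": {k: v.bf for k, v in res["bayes_factors"].items()},
                "posterior_probabilities": res["posterior_probabilities"],
            }
            for cell, res in bundle["somatotopy"].items()
        }
    if "pcm_fits" in bundle:
        report["pcm_best_r"] = {
            f"{subject}_{region}": fit.best_r
            for (subject, region), fit in bundle["pcm_fits"].items()
        }
    with open(outdir / "report.json", "w") as f:
        json.dump(report, f, indent=2, default=_jsonable)
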