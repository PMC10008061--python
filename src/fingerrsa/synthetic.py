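"""Synthetic multivoxel, behavioral and connectivity data.

Every downstream stage of the package (crossnobis RDMs, PCM correlation
models, RSA regressions, connectivity summaries) can be exercised on
data generated here with known ground truth:

* multivoxel beta patterns for two modalities (motor, tactile) in two
  regions (precentral, postcentral), with a controllable true
  second-moment geometry, cross-modal correlation, modality-specific
  mean activation offsets, and i.i.d. measurement noise;
* behavioral recordings — fingertip rest geometry, landmark-pointing
  judgments with an affine width/length distortion, fingertip-speed
  traces mixed through a synergy matrix, and multi-channel EMG traces
  following a coactivation matrix;
* finger ROI centers arranged somatotopically (D1..Dn along a line with
  jitter) plus structural fiber-count and resting time-series data with
  configurable same-finger vs adjacent-finger coupling.

Condition profiles are drawn once per subject and shared across
repetitions; repetition-to-repetition variability enters only through
the additive noise, which keeps crossnobis expectations analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .crossnobis import ActivityDataset
from .rdm import RDM

MODALITIES = ("motor", "tactile")
REGIONS = ("precentral", "postcentral")

#: Plausible fingertip rest coordinates (mm), hand flat on a table,
#: x lateral (thumb -> little finger), y distal, z vertical.
DEFAULT_REST_POSITIONS = np.array(
    [
        [0.0, 0.0, 0.0],  # D1
        [45.0, 90.0, 0.0],  # D2
        [65.0, 100.0, 0.0],  # D3
        [85.0, 90.0, 0.0],  # D4
        [103.0, 70.0, 0.0],  # D5
        [120.0, 45.0, 0.0],  # D6 (supernumerary variant)
    ]
)


def finger_labels(n_fingers: int) -> list[str]:
    return [f"D{i + 1}" for i in range(n_fingers)]


def _double_center(squared_d: np.ndarray) -> np.ndarray:
    n = squared_d.shape[0]
    h = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * h @ squared_d @ h


def _psd_clip(g: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    g = (g + g.T) / 2.0
    w, v = np.linalg.eigh(g)
    w = np.where(w < tol, np.maximum(w, 0.0), w)
    return v @ np.diag(w) @ v.T


@dataclass
class SimulationConfig:
    """Design of the simulated multivoxel experiment.

    Defaults mirror the mapping design: 5 fingers, 6 repetitions per
    finger, motor and tactile modalities in precentral and postcentral
    regions, and modality-specific mean-activation offsets.
    """

    n_subjects: int = 6
    n_fingers: int = 5
    n_voxels: int = 200
    n_repetitions: int = 6
    modalities: tuple[str, str] = MODALITIES
    regions: tuple[str, ...] = REGIONS
    true_model: RDM | None = None
    cross_modal_correlation: float = 0.8
    signal_variance: tuple[float, float] = (1.0, 1.0)
    noise_variance: float = 1.0
    modality_mean_offset: tuple[float, float] = (1.0, 0.4)
    missing_roi_rate: float = 0.0
    n_residual_samples: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repetitions % 2 != 0:
            raise ValueError("n_repetitions must be even for balanced even/odd partitions")
        if not 0.0 <= self.cross_modal_correlation <= 1.0:
            raise ValueError("cross_modal_correlation must be in [0, 1]")
        if any(not np.isfinite(s) or s < 0 for s in self.signal_variance):
            raise ValueError("signal variances must be finite and non-negative")
        if not (np.isfinite(self.noise_variance) and self.noise_variance > 0):
            raise ValueError("noise variance must be finite and positive")
        if not 0.0 <= self.missing_roi_rate < 1.0:
            raise ValueError("missing_roi_rate must be in [0, 1)")
        if self.true_model is None:
            pos = DEFAULT_REST_POSITIONS[: self.n_fingers]
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
            if d.max() > 0:
                d = d / d.max()
            self.true_model = RDM(d, finger_labels(self.n_fingers))
        if self.true_model.n != self.n_fingers:
            raise ValueError("true_model size does not match n_fingers")


def build_true_second_moment(
    model: RDM, rho: float, signal_variances: tuple[float, float]
) -> np.ndarray:
    """Joint 2n x 2n second-moment matrix implied by a model RDM.

    The within-modality block is the double-centered transform of the
    squared model distances, normalized to unit mean diagonal and
    scaled by the modality's signal variance; the cross-modal block is
    the same unit geometry scaled by rho * sqrt(s1 * s2). At rho = 1
    with equal variances the two modality patterns are scaled copies of
    each other. The result is projected to the PSD cone (eigenvalues
    clipped at 0, tolerance 1e-10).
    """
    d = np.asarray(model.values, dtype=float)
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("model RDM must be symmetric")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    g = _double_center(d**2)
    scale = np.trace(g) / g.shape[0]
    g_unit = g / scale if scale > 0 else g
    s1, s2 = signal_variances
    joint = np.block(
        [
            [s1 * g_unit, rho * np.sqrt(s1 * s2) * g_unit],
            [rho * np.sqrt(s1 * s2) * g_unit, s2 * g_unit],
        ]
    )
    return _psd_clip(joint)


def simulate_patterns(config: SimulationConfig) -> dict[tuple[str, str], ActivityDataset]:
    """Simulate beta patterns for every subject x region.

    Each subject draws condition profiles U (2n x V) once, with voxel
    columns i.i.d. N(0, G) under the configured joint second moment;
    each repetition observes U plus its modality's mean offset plus
    i.i.d. Gaussian noise. Residual draws with the same noise variance
    are attached for noise-covariance estimation.
    """
    rng = np.random.default_rng(config.seed)
    n, v = config.n_fingers, config.n_voxels
    if v < 2 * n:
        import warnings

        warnings.warn("n_voxels < number of conditions: covariance estimates rank-deficient")
    g = build_true_second_moment(
        config.true_model, config.cross_modal_correlation, config.signal_variance
    )
    w, vec = np.linalg.eigh(g)
    sqrt_g = vec @ np.diag(np.sqrt(np.maximum(w, 0.0))) @ vec.T
    fingers = finger_labels(n)
    conditions = [(f, m) for m in config.modalities for f in fingers]
    offsets = np.repeat(config.modality_mean_offset, n)[:, None]
    noise_sd = np.sqrt(config.noise_variance)

    out: dict[tuple[str, str], ActivityDataset] = {}
    for s in range(config.n_subjects):
        subject = f"sub{s + 1:02d}"
        for region in config.regions:
            u = sqrt_g @ rng.standard_normal((2 * n, v))
            betas = (
                u[None]
                + offsets[None]
                + noise_sd * rng.standard_normal((config.n_repetitions, 2 * n, v))
            )
            residuals = noise_sd * rng.standard_normal((config.n_residual_samples, v))
            out[(subject, region)] = ActivityDataset(
                subject=subject,
                region=region,
                betas=betas,
                residuals=residuals,
                conditions=conditions,
            )
    return out


@dataclass
class BehavioralSimConfig:
    """Design of the simulated behavioral recordings.

    Defaults follow the behavioral protocols: 12 manipulated objects
    with 10 trials each, fingertip speed sampled at 100 Hz, 13 EMG
    channels sampled at 2 kHz with 6 trials per moved finger. The
    perceived-hand distortion defaults to the classic overestimated
    width (x1.2) and underestimated length (x0.8).
    """

    n_fingers: int = 5
    rest_positions: np.ndarray | None = None
    width_scale: float = 1.2
    length_scale: float = 0.8
    judgment_noise_sd: float = 5.0
    n_landmark_trials: int = 10
    synergy_matrix: np.ndarray | None = None
    n_objects: int = 12
    n_kin_trials_per_object: int = 10
    kin_sampling_hz: float = 100.0
    kin_duration_s: float = 2.5
    kin_noise_sd: float = 2.0
    coactivation_matrix: np.ndarray | None = None
    n_emg_channels: int = 13
    n_emg_trials: int = 6
    emg_sampling_hz: float = 2000.0
    emg_duration_s: float = 1.0
    emg_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_objects < 1:
            raise ValueError("n_objects must be >= 1")
        if min(self.judgment_noise_sd, self.kin_noise_sd, self.emg_noise_sd) < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.rest_positions is None:
            self.rest_positions = DEFAULT_REST_POSITIONS[: self.n_fingers].copy()
        self.rest_positions = np.asarray(self.rest_positions, dtype=float)
        if self.rest_positions.shape != (self.n_fingers, 3):
            raise ValueError("rest_positions must be n_fingers x 3")
        if self.synergy_matrix is None:
            self.synergy_matrix = _default_synergies(self.n_fingers)
        self.synergy_matrix = np.asarray(self.synergy_matrix, dtype=float)
        if not np.isfinite(self.synergy_matrix).all():
            raise ValueError("synergy weights must be finite")
        if np.all(self.synergy_matrix == 0):
            raise ValueError("synergy matrix is degenerate (all zero)")
        if self.coactivation_matrix is None:
            self.coactivation_matrix = _default_coactivation(self.n_emg_channels, self.n_fingers)
        self.coactivation_matrix = np.asarray(self.coactivation_matrix, dtype=float)
        if not np.isfinite(self.coactivation_matrix).all():
            raise ValueError("coactivation weights must be finite")
        if np.all(self.coactivation_matrix == 0):
            raise ValueError("coactivation matrix is degenerate (all zero)")


def _default_synergies(n_fingers: int, n_synergies: int = 3) -> np.ndarray:
    """Neighbor-correlated synergy loadings: thumb largely independent,
    D2-D5 loaded on overlapping grasp/roll synergies (enslaving)."""
    centers = np.linspace(0, n_fingers - 1, n_synergies)
    idx = np.arange(n_fingers)[:, None]
    w = np.exp(-0.5 * ((idx - centers[None, :]) / 1.2) ** 2)
    return w / w.sum(axis=1, keepdims=True)


def _default_coactivation(n_channels: int, n_fingers: int) -> np.ndarray:
    """Each finger drives a preferred channel plus spillover to the
    channels of adjacent fingers; remaining (wrist) channels get a
    small common activation."""
    w = np.zeros((n_channels, n_fingers))
    for f in range(n_fingers):
        ch = f % n_channels
        w[ch, f] = 1.0
        if f > 0:
            w[(f - 1) % n_channels, f] += 0.35
        if f < n_fingers - 1:
            w[(f + 1) % n_channels, f] += 0.35
    w[min(n_fingers, n_channels) :, :] += 0.1
    return w


@dataclass
class BehavioralData:
    """Container for the four behavioral tables."""

    rest_positions: pd.DataFrame  # finger, x, y, z
    landmarks: pd.DataFrame  # finger, trial, x, y, z
    kinematics: pd.DataFrame  # participant, object, trial, time, finger, speed
    emg: pd.DataFrame  # participant, finger, trial, time, channel, value
    true_perceived_positions: np.ndarray = field(repr=False, default=None)


def perceived_positions(config: BehavioralSimConfig) -> np.ndarray:
    """Noise-free distorted fingertip positions (affine width/length map,
    applied about the fingertip centroid)."""
    pos = config.rest_positions
    center = pos.mean(axis=0)
    scale = np.array([config.width_scale, config.length_scale, 1.0])
    return center + (pos - center) * scale


def simulate_behavior(config: BehavioralSimConfig, participant: str = "P01") -> BehavioralData:
    """Generate geometry, landmark, kinematic and EMG tables for one
    participant."""
    rng = np.random.default_rng(config.seed)
    fingers = finger_labels(config.n_fingers)

    rest = pd.DataFrame(config.rest_positions, columns=["x", "y", "z"])
    rest.insert(0, "finger", fingers)

    target = perceived_positions(config)
    rows = []
    for t in range(config.n_landmark_trials):
        pts = target + config.judgment_noise_sd * rng.standard_normal(target.shape)
        for f, lbl in enumerate(fingers):
            rows.append((lbl, t, *pts[f]))
    landmarks = pd.DataFrame(rows, columns=["finger", "trial", "x", "y", "z"])

    # Kinematics: latent synergy activations are smooth positive bumps;
    # finger speed = synergy mixture + rectified noise. The movement is
    # embedded in low-speed padding so the 10 mm/s threshold windowing
    # has something to cut.
    n_t = int(round(config.kin_duration_s * config.kin_sampling_hz))
    time = np.arange(n_t) / config.kin_sampling_hz
    kin_rows = []
    n_syn = config.synergy_matrix.shape[1]
    for obj in range(config.n_objects):
        obj_phase = rng.uniform(0.3, 0.7, size=n_syn)
        obj_amp = 60.0 + 40.0 * rng.random(n_syn)
        for trial in range(config.n_kin_trials_per_object):
            phase = obj_phase + 0.05 * rng.standard_normal(n_syn)
            amp = obj_amp * (1 + 0.1 * rng.standard_normal(n_syn))
            act = np.stack(
                [
                    a * np.exp(-0.5 * ((time / time[-1] - p) / 0.12) ** 2)
                    for a, p in zip(amp, phase)
                ]
            )
            speed = config.synergy_matrix @ act
            speed += config.kin_noise_sd * np.abs(rng.standard_normal(speed.shape))
            for f, lbl in enumerate(fingers):
                kin_rows.append(
                    pd.DataFrame(
                        {
                            "participant": participant,
                            "object": obj,
                            "trial": trial,
                            "time": time,
                            "finger": lbl,
                            "speed": speed[f],
                        }
                    )
                )
    kinematics = pd.concat(kin_rows, ignore_index=True)

    # EMG: per moved finger, channels follow the coactivation column
    # modulated by a 1 Hz tapping envelope, plus noise (to be rectified
    # and filtered downstream).
    n_e = int(round(config.emg_duration_s * config.emg_sampling_hz))
    etime = np.arange(n_e) / config.emg_sampling_hz
    envelope = 0.6 + 0.4 * np.sin(2 * np.pi * 1.0 * etime) ** 2
    emg_rows = []
    channels = np.arange(config.coactivation_matrix.shape[0])
    for f, lbl in enumerate(fingers):
        col = config.coactivation_matrix[:, f]
        for trial in range(config.n_emg_trials):
            sig = col[:, None] * envelope[None, :]
            sig = sig * np.sign(rng.standard_normal(sig.shape))  # raw EMG is zero-mean
            sig += config.emg_noise_sd * rng.standard_normal(sig.shape)
            for ch in channels:
                emg_rows.append(
                    pd.DataFrame(
                        {
                            "participant": participant,
                            "finger": lbl,
                            "trial": trial,
                            "time": etime,
                            "channel": ch,
                            "value": sig[ch],
                        }
                    )
                )
    emg = pd.concat(emg_rows, ignore_index=True)

    return BehavioralData(rest, landmarks, kinematics, emg, true_perceived_positions=target)


@dataclass
class ConnectivitySim:
    """ROI centers plus structural/functional connectivity inputs."""

    roi_centers: pd.DataFrame  # finger, modality, region, x, y, z, available
    structural_counts: np.ndarray  # 2n x 2n symmetric fiber counts
    timeseries: np.ndarray  # 2n x n_timepoints resting signals
    labels: list[str]
    design_correlation: np.ndarray


def simulate_rois_and_connectivity(
    somatotopic: bool = True,
    n_fingers: int = 5,
    jitter_sd: float = 0.0,
    spacing: float = 1.0,
    coupling_same: float = 0.6,
    coupling_adjacent: float = 0.2,
    n_timepoints: int = 150,
    base_count: float = 50.0,
    count_gain: float = 400.0,
    missing_roi_rate: float = 0.035,
    seed: int = 0,
    regions: tuple[str, ...] = REGIONS,
) -> ConnectivitySim:
    """Simulate finger ROI geometry and connectivity inputs.

    Somatotopic centers lie on a lateromedial line D1..Dn with Gaussian
    jitter; non-somatotopic centers are shuffled. Missing finger ROIs
    (default rate 3.5%, the observed proportion of unrecoverable
    finger peaks) carry NaN coordinates and available=False. Resting time series
    come from a Gaussian latent-factor model whose expected pairwise
    correlation matches the same-finger / adjacent-finger coupling
    design; structural counts are Poisson around the same design.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    if coupling_same < 0 or coupling_adjacent < 0:
        raise ValueError("coupling strengths must be non-negative")
    rng = np.random.default_rng(seed)
    fingers = finger_labels(n_fingers)

    rows = []
    for modality in MODALITIES:
        for region in regions:
            order = np.arange(n_fingers)
            if not somatotopic:
                order = rng.permutation(n_fingers)
            base = np.zeros((n_fingers, 3))
            base[:, 0] = order * spacing
            base += jitter_sd * rng.standard_normal(base.shape)
            for f, lbl in enumerate(fingers):
                available = rng.random() >= missing_roi_rate
                coords = base[f] if available else np.full(3, np.nan)
                rows.append((lbl, modality, region, *coords, available))
    roi_centers = pd.DataFrame(
        rows, columns=["finger", "modality", "region", "x", "y", "z", "available"]
    )

    labels = [f"{f}_{m}" for m in MODALITIES for f in fingers]
    k = 2 * n_fingers
    design = np.eye(k)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            fi, fj = i % n_fingers, j % n_fingers
            same_modality = (i < n_fingers) == (j < n_fingers)
            if fi == fj and not same_modality:
                design[i, j] = coupling_same
            elif abs(fi - fj) == 1:
                design[i, j] = coupling_adjacent
    design_psd = _psd_clip(design, tol=1e-8)
    w, vec = np.linalg.eigh(design_psd)
    sqrt_c = vec @ np.diag(np.sqrt(np.maximum(w, 0))) @ vec.T
    timeseries = sqrt_c @ rng.standard_normal((k, n_timepoints))

    lam = base_count + count_gain * (design - np.eye(k))
    lam = np.maximum(lam, 0.0)
    counts = rng.poisson(np.triu(lam, k=1))
    counts = counts + counts.T
    np.fill_diagonal(counts, 0)

    return ConnectivitySim(roi_centers, counts.astype(float), timeseries, labels, design)


def save_patterns(path, datasets: dict[tuple[str, str], ActivityDataset], seed: int | None = None):
    """Write pattern datasets to an HDF5 container
    (/subject/region/{betas,residuals})."""
    with h5py.File(path, "w") as f:
        if seed is not None:
            f.attrs["seed"] = seed
        for (subject, region), ds in datasets.items():
            grp = f.require_group(f"{subject}/{region}")
            grp.create_dataset("betas", data=ds.betas)
            grp.create_dataset("residuals", data=ds.residuals)
            grp.attrs["conditions"] = [f"{a}|{b}" for a, b in ds.conditions]
            grp.attrs["condition_mask"] = ds.condition_mask


def load_patterns(path) -> dict[tuple[str, str], ActivityDataset]:
    out: dict[tuple[str, str], ActivityDataset] = {}
    with h5py.File(path, "r") as f:
        for subject in f:
            for region in f[subject]:
                grp = f[subject][region]
                conditions = [tuple(c.split("|")) for c in grp.attrs["conditions"]]
                out[(subject, region)] = ActivityDataset(
                    subject=subject,
                    region=region,
                    betas=grp["betas"][()],
                    residuals=grp["residuals"][()],
                    conditions=conditions,
                    condition_mask=np.asarray(grp.attrs["condition_mask"], dtype=bool),
                )
    return out
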