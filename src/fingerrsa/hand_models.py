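"""Behavioral models of finger representations.

Four explanatory RDMs, each a pairwise inter-finger dissimilarity:

* real hand — 3D Euclidean distances between fingertip rest positions;
* perceived hand — distances between subjectively localized fingertip
  positions (mean of repeated landmark-pointing judgments);
* manipulation — distances between fingertip-speed profiles during
  object manipulation (10 Hz low-pass, 10 mm/s movement window,
  [0, 1] normalization, averaged over trials, objects, participants);
* muscle — distances between trial-averaged multi-channel EMG activity
  during single-finger movements (1 kHz downsample, rectification,
  4th-order 40 Hz low-pass).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal
from scipy.spatial.distance import pdist, squareform

from .rdm import RDM, average_rdms

logger = logging.getLogger(__name__)


def _pairwise_rdm(vectors: np.ndarray, labels: list[str], provenance: str) -> RDM:
    return RDM(squareform(pdist(vectors)), labels, provenance=provenance)


def real_hand_model(positions: pd.DataFrame | np.ndarray, labels=None) -> RDM:
    """Physical fingertip distances at rest.

    `positions` is either an (n, 3) array with `labels`, or a DataFrame
    with columns finger, x, y, z.
    """
    if isinstance(positions, pd.DataFrame):
        labels = positions["finger"].tolist()
        coords = positions[["x", "y", "z"]].to_numpy(dtype=float)
    else:
        coords = np.asarray(positions, dtype=float)
        labels = list(labels) if labels is not None else [f"D{i+1}" for i in range(len(coords))]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate finger labels")
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    return _pairwise_rdm(coords, labels, "real_hand")


def perceived_hand_model(judgments: pd.DataFrame) -> RDM:
    """Distances between perceived fingertip positions.

    The perceived position of each fingertip is the mean of its
    repeated pointing judgments (columns finger, x, y, z; a trial
    column is ignored if present).
    """
    required = {"finger", "x", "y", "z"}
    if not required.issubset(judgments.columns):
        raise ValueError(f"judgments need columns {sorted(required)}")
    means = judgments.groupby("finger", sort=False)[["x", "y", "z"]].mean()
    if (judgments.groupby("finger").size() < 1).any():
        raise ValueError("every fingertip needs at least one judgment")
    return _pairwise_rdm(means.to_numpy(), means.index.tolist(), "perceived_hand")


def _movement_window(speed: np.ndarray, threshold: float) -> tuple[int, int] | None:
    """First-to-last crossing of the threshold by the fastest finger.

    `speed` is (n_fingers, n_samples); the window is defined on the
    per-sample maximum across fingers and applied to all fingers.
    """
    envelope = speed.max(axis=0)
    above = np.nonzero(envelope >= threshold)[0]
    if above.size == 0:
        return None
    return int(above[0]), int(above[-1]) + 1


def manipulation_model(
    kinematics: pd.DataFrame,
    sampling_hz: float = 100.0,
    cutoff_hz: float = 10.0,
    speed_threshold: float = 10.0,
    filter_order: int = 4,
    resample_length: int = 101,
    normalization: str = "trial",
) -> RDM:
    """Inter-finger dissimilarity of fingertip-speed profiles.

    Per trial: zero-phase Butterworth low-pass (``cutoff_hz``) on each
    finger's speed trace; movement window from the first to the last
    crossing of ``speed_threshold`` (mm/s) by the fastest finger;
    min-max normalization to [0, 1] (jointly across fingers within the
    trial by default); traces resampled to a common length; RDM entry =
    Euclidean distance between finger speed vectors. Trial RDMs are
    averaged over trials and objects within a participant, then over
    participants.

    normalization : {"trial", "finger", "none"}
        Scope of the min-max normalization.
    """
    required = {"participant", "object", "trial", "time", "finger", "speed"}
    if not required.issubset(kinematics.columns):
        raise ValueError(f"kinematics need columns {sorted(required)}")
    sos = signal.butter(filter_order, cutoff_hz, fs=sampling_hz, output="sos")
    fingers = list(dict.fromkeys(kinematics["finger"]))
    participant_rdms = []
    for participant, pdata in kinematics.groupby("participant", sort=False):
        object_rdms = []
        for obj, odata in pdata.groupby("object", sort=False):
            trial_rdms = []
            for trial, tdata in odata.groupby("trial", sort=False):
                wide = tdata.pivot_table(
                    index="finger", columns="time", values="speed", sort=False
                ).reindex(fingers)
                if wide.isna().any().any():
                    raise ValueError(
                        f"unequal trace lengths in participant {participant} trial {trial}"
                    )
                speed = signal.sosfiltfilt(sos, wide.to_numpy(dtype=float), axis=1)
                win = _movement_window(speed, speed_threshold)
                if win is None:
                    logger.warning(
                        "trial %s/%s/%s never crosses %.0f mm/s; excluded",
                        participant, obj, trial, speed_threshold,
                    )
                    continue
                speed = speed[:, win[0] : win[1]]
                if normalization == "trial":
                    lo, hi = speed.min(), speed.max()
                    speed = (speed - lo) / (hi - lo) if hi > lo else np.zeros_like(speed)
                elif normalization == "finger":
                    lo = speed.min(axis=1, keepdims=True)
                    hi = speed.max(axis=1, keepdims=True)
                    rng_ = np.where(hi > lo, hi - lo, 1.0)
                    speed = (speed - lo) / rng_
                elif normalization != "none":
                    raise ValueError(f"unknown normalization {normalization!r}")
                if speed.shape[1] != resample_length:
                    old = np.linspace(0.0, 1.0, speed.shape[1])
                    new = np.linspace(0.0, 1.0, resample_length)
                    speed = np.stack([np.interp(new, old, row) for row in speed])
                trial_rdms.append(squareform(pdist(speed)))
            if not trial_rdms:
                raise ValueError(f"object {obj} of participant {participant} has no valid trial")
            object_rdms.append(np.mean(trial_rdms, axis=0))
        participant_rdms.append(RDM(np.mean(object_rdms, axis=0), fingers, provenance="manipulation"))
    return average_rdms(participant_rdms, provenance="manipulation")


def muscle_model(
    emg: pd.DataFrame,
    sampling_hz: float = 2000.0,
    downsample_hz: float = 1000.0,
    cutoff_hz: float = 40.0,
    filter_order: int = 4,
) -> RDM:
    """Inter-finger dissimilarity of trial-averaged EMG activity.

    Per trial: downsample to ``downsample_hz``, full-wave rectify, and
    zero-phase low-pass (4th-order Butterworth, ``cutoff_hz``); average
    each channel over time, then over trials per moved finger, giving a
    channel-space vector per finger; RDM entry = Euclidean distance
    between finger vectors, averaged over participants.
    """
    required = {"participant", "finger", "trial", "time", "channel", "value"}
    if not required.issubset(emg.columns):
        raise ValueError(f"EMG needs columns {sorted(required)}")
    decim = sampling_hz / downsample_hz
    if abs(decim - round(decim)) > 1e-9 or decim < 1:
        raise ValueError("sampling rate must be an integer multiple of the downsample rate")
    decim = int(round(decim))
    sos = signal.butter(filter_order, cutoff_hz, fs=downsample_hz, output="sos")

    fingers = list(dict.fromkeys(emg["finger"]))
    channels = sorted(emg["channel"].unique())
    participant_rdms = []
    for participant, pdata in emg.groupby("participant", sort=False):
        finger_vectors = {}
        for finger, fdata in pdata.groupby("finger", sort=False):
            trial_means = []
            for _, tdata in fdata.groupby("trial", sort=False):
                wide = tdata.pivot_table(
                    index="channel", columns="time", values="value"
                ).reindex(channels)
                if wide.isna().any().any():
                    raise ValueError(f"channel mismatch for participant {participant}")
                x = wide.to_numpy(dtype=float)[:, ::decim]
                x = np.abs(x)
                x = signal.sosfiltfilt(sos, x, axis=1)
                trial_means.append(x.mean(axis=1))
            if not trial_means:
                raise ValueError(f"finger {finger} has no trials")
            finger_vectors[finger] = np.mean(trial_means, axis=0)
        vecs = np.stack([finger_vectors[f] for f in fingers])
        participant_rdms.append(RDM(squareform(pdist(vecs)), fingers, provenance="muscle"))
    return average_rdms(participant_rdms, provenance="muscle")


def model_correlations(models: list[RDM]) -> pd.DataFrame:
    """Pairwise Pearson correlations of the vectorized upper triangles."""
    if len({m.n for m in models}) != 1:
        raise ValueError("all models must have the same size")
    names = [m.provenance or f"model{i}" for i, m in enumerate(models)]
    vectors = np.stack([m.vector() for m in models])
    if np.any(vectors.std(axis=1) == 0):
        raise ValueError("constant (zero-variance) model vector")
    return pd.DataFrame(np.corrcoef(vectors), index=names, columns=names)
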