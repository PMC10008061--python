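"""Cross-validated Mahalanobis (crossnobis) dissimilarities.

Activity patterns are beta estimates per repetition x condition x voxel.
The six repetitions per finger are split into odd and even repetitions to
form two independent partitions; the dissimilarity between conditions i
and j is the inner product of their (whitened) pattern differences across
the two partitions, divided by the voxel count. Because the two factors
of the product carry independent noise, the estimator is unbiased: a zero
true distance yields estimates scattered around zero, and negative values
are meaningful rather than errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .rdm import RDM

logger = logging.getLogger(__name__)


@dataclass
class ActivityDataset:
    """Per-subject, per-region multivoxel beta patterns.

    Parameters
    ----------
    betas : (n_repetitions, n_conditions, n_voxels) ndarray
        One pattern per repetition and condition.
    residuals : (n_samples, n_voxels) ndarray
        GLM residual draws used to estimate the voxel noise covariance.
    conditions : list of (finger, modality) tuples
        Condition labels; fingers "D1".."Dn", modalities e.g. "motor".
    condition_mask : bool ndarray, optional
        False marks conditions unavailable for this subject/region.
    """

    subject: str
    region: str
    betas: np.ndarray
    residuals: np.ndarray
    conditions: list[tuple[str, str]]
    condition_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.betas.ndim != 3:
            raise ValueError("betas must be (repetitions, conditions, voxels)")
        if self.betas.shape[1] != len(self.conditions):
            raise ValueError("condition labels do not match betas")
        if self.residuals.shape[1] != self.betas.shape[2]:
            raise ValueError("residual voxel count does not match betas")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if self.condition_mask is None:
            self.condition_mask = np.ones(len(self.conditions), dtype=bool)
        else:
            self.condition_mask = np.asarray(self.condition_mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[2]

    @property
    def condition_labels(self) -> list[str]:
        return [f"{f}_{m}" for f, m in self.conditions]

    @property
    def modalities(self) -> list[str]:
        seen: list[str] = []
        for _, m in self.conditions:
            if m not in seen:
                seen.append(m)
        return seen


@dataclass
class NoiseModel:
    """Voxel-space whitening derived from residual covariance.

    ``whitening`` is the inverse transpose Cholesky factor L^-T of the
    (shrunk) covariance: right-multiplying patterns by it makes the
    residual covariance identity.
    """

    whitening: np.ndarray
    shrinkage: float
    n_samples: int

    def whiten(self, patterns: np.ndarray) -> np.ndarray:
        return patterns @ self.whitening


def partition_even_odd(betas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split repetitions into odd (1st, 3rd, ...) and even partitions.

    Returns the per-condition mean pattern of each partition,
    shape (n_conditions, n_voxels) each.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.shape[0] < 2:
        raise ValueError("need at least 2 repetitions to form partitions")
    odd = betas[0::2].mean(axis=0)
    even = betas[1::2].mean(axis=0)
    return odd, even


def remove_condition_mean(patterns: np.ndarray) -> np.ndarray:
    """Subtract each condition's across-voxel mean activity.

    Removes the average-activation difference between modalities that
    would otherwise bias between-modality dissimilarities. Every
    returned row sums to zero across voxels.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.shape[-1] < 1:
        raise ValueError("need at least one voxel")
    return patterns - patterns.mean(axis=-1, keepdims=True)


def _analytic_shrinkage(residuals: np.ndarray) -> tuple[np.ndarray, float]:
    """Diagonal-target analytic shrinkage of the sample covariance.

    Off-diagonal entries are shrunk toward zero with the analytic
    intensity lambda* = sum Var(s_ij) / sum s_ij^2 (off-diagonal sums),
    clipped to [0, 1].
    """
    x = residuals - residuals.mean(axis=0, keepdims=True)
    t, p = x.shape
    s = x.T @ x / (t - 1)
    # Var of each covariance entry, estimated from the per-sample products
    w = np.einsum("ti,tj->ij", x**2, x**2) / (t - 1) - s**2 * (t - 1) / t
    var_s = w * t / ((t - 1) ** 2)
    off = ~np.eye(p, dtype=bool)
    denom = np.sum(s[off] ** 2)
    lam = 1.0 if denom <= 0 else float(np.clip(np.sum(var_s[off]) / denom, 0.0, 1.0))
    sigma = lam * np.diag(np.diag(s)) + (1.0 - lam) * s
    return sigma, lam


def estimate_noise(residuals: np.ndarray, shrinkage: str | float = "analytic") -> NoiseModel:
    """Estimate a voxel noise model from GLM residuals.

    Parameters
    ----------
    residuals : (n_samples, n_voxels) ndarray
    shrinkage : {"analytic", "identity"} or float in [0, 1]
        "analytic" uses the diagonal-target analytic intensity;
        "identity" skips whitening entirely (plain cross-validated
        Euclidean distances); a float forces that intensity.
    """
    residuals = np.asarray(residuals, dtype=float)
    t, p = residuals.shape
    if t < 2:
        raise ValueError("need at least 2 residual samples")
    if shrinkage == "identity":
        return NoiseModel(np.eye(p), 1.0, t)

    x = residuals - residuals.mean(axis=0, keepdims=True)
    s = x.T @ x / (t - 1)
    var_floor = 1e-12
    d = np.diag(s).copy()
    if np.any(d < var_floor):
        logger.warning("zero-variance voxels regularized with floor %g", var_floor)
        d = np.maximum(d, var_floor)
        s[np.diag_indices(p)] = d

    if shrinkage == "analytic":
        sigma, lam = _analytic_shrinkage(residuals)
        sigma[np.diag_indices(p)] = np.maximum(np.diag(sigma), var_floor)
    else:
        lam = float(np.clip(shrinkage, 0.0, 1.0))
        sigma = lam * np.diag(d) + (1.0 - lam) * s

    chol_l = cholesky(sigma, lower=True)
    whitening = solve_triangular(chol_l, np.eye(p), lower=True).T  # L^-T
    return NoiseModel(whitening, lam, t)


def crossnobis_rdm(
    dataset: ActivityDataset,
    noise: NoiseModel | None = None,
    conditions: list[tuple[str, str]] | None = None,
    mean_removal: str = "voxel",
) -> RDM:
    """Cross-validated Mahalanobis RDM over the selected conditions.

    For each condition pair, d(i,j) = <bA_i - bA_j, bB_i - bB_j> / P
    where A/B are the odd/even partition means after whitening and
    condition-mean removal, and P is the voxel count. Masked conditions
    produce NaN rows/columns.

    mean_removal : {"voxel", "condition_set", "none"}
        "voxel" subtracts each condition's across-voxel mean (default);
        "condition_set" subtracts each modality's mean pattern across
        its conditions; "none" skips removal.
    """
    if conditions is None:
        conditions = dataset.conditions
    idx = [dataset.conditions.index(c) for c in conditions]
    mask = dataset.condition_mask[idx]
    for c, ok in zip(conditions, mask):
        if not ok:
            logger.warning("condition %s masked for subject %s", c, dataset.subject)

    part_a, part_b = partition_even_odd(dataset.betas)
    part_a, part_b = part_a[idx], part_b[idx]

    if mean_removal == "voxel":
        part_a = remove_condition_mean(part_a)
        part_b = remove_condition_mean(part_b)
    elif mean_removal == "condition_set":
        modalities = [m for _, m in conditions]
        for m in dict.fromkeys(modalities):
            rows = [i for i, mm in enumerate(modalities) if mm == m]
            part_a[rows] -= part_a[rows].mean(axis=0, keepdims=True)
            part_b[rows] -= part_b[rows].mean(axis=0, keepdims=True)
    elif mean_removal != "none":
        raise ValueError(f"unknown mean_removal mode {mean_removal!r}")

    if noise is not None:
        part_a = noise.whiten(part_a)
        part_b = noise.whiten(part_b)

    p = dataset.n_voxels
    k = len(conditions)
    d = np.zeros((k, k))
    for i in range(k):
        da = part_a[i] - part_a
        db = part_b[i] - part_b
        d[i] = np.einsum("cv,cv->c", da, db) / p
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d[~mask, :] = np.nan
    d[:, ~mask] = np.nan
    np.fill_diagonal(d, np.where(mask, 0.0, np.nan))

    labels = [f"{f}_{m}" for f, m in conditions]
    return RDM(d, labels)


def naive_mahalanobis_rdm(dataset: ActivityDataset, noise: NoiseModel | None = None) -> RDM:
    """Non-cross-validated squared Mahalanobis distances (biased oracle).

    Uses the grand mean over all repetitions in both factors; serves as
    the positively biased comparator for the unbiasedness checks.
    """
    mean = remove_condition_mean(dataset.betas.mean(axis=0))
    if noise is not None:
        mean = noise.whiten(mean)
    p = dataset.n_voxels
    diff = mean[:, None, :] - mean[None, :, :]
    d = np.einsum("ijv,ijv->ij", diff, diff) / p
    np.fill_diagonal(d, 0.0)
    return RDM(d, dataset.condition_labels)


def split_modalities(joint: RDM) -> dict[str, RDM]:
    """Extract per-modality n x n RDMs from a joint 2n x 2n RDM.

    Labels must follow the "finger_modality" convention used by
    `crossnobis_rdm`.
    """
    parsed = [tuple(lbl.rsplit("_", 1)) for lbl in joint.labels]
    out: dict[str, RDM] = {}
    for modality in dict.fromkeys(m for _, m in parsed):
        rows = [i for i, (_, m) in enumerate(parsed) if m == modality]
        sub = joint.values[np.ix_(rows, rows)]
        out[modality] = RDM(sub, [parsed[i][0] for i in rows])
    return out
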