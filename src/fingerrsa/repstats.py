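"""Geometry and connectivity summaries on joint finger matrices.

Joint 2n x 2n matrices carry (finger, modality) labels with the motor
block first. The block summaries extract the quantities compared at
the group level: mean dissimilarity between adjacent fingers within
each modality, mean dissimilarity between the same finger across
modalities (cross-block diagonal), and between adjacent fingers across
modalities. The same machinery serves structural and functional
connectivity matrices after their own normalization (max fiber count
for structural; Fisher z of pairwise correlations for functional),
optionally divided by the inter-ROI Euclidean distances to remove the
distance bias.
"""

from __future__ import annotations

import logging

import numpy as np

from .rdm import RDM

logger = logging.getLogger(__name__)


def euclidean_distance_matrix(coords: np.ndarray, labels=None) -> RDM:
    """Pairwise 3D Euclidean distances between ROI centers.

    Rows with any NaN coordinate count as missing and produce masked
    (NaN) rows/columns.
    """
    coords = np.asarray(coords, dtype=float)
    available = np.isfinite(coords).all(axis=1)
    if available.sum() < 2:
        raise ValueError("need at least 2 available ROIs")
    filled = np.where(available[:, None], coords, 0.0)
    diff = filled[:, None, :] - filled[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    d[~available, :] = np.nan
    d[:, ~available] = np.nan
    np.fill_diagonal(d, np.where(available, 0.0, np.nan))
    return RDM(d, labels or [])


def activation_volume(stat_map: np.ndarray, roi_mask: np.ndarray, threshold: float) -> float:
    """Fraction of ROI voxels whose statistic exceeds the threshold."""
    stat_map = np.asarray(stat_map, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    n = int(roi_mask.sum())
    if n == 0:
        raise ValueError("empty ROI mask")
    return float(np.sum(stat_map[roi_mask] > threshold) / n)


def block_summaries(matrix: np.ndarray | RDM, n_fingers: int | None = None) -> dict[str, float]:
    """Within- and cross-modality summaries of a joint 2n x 2n matrix.

    Returns means over: adjacent-finger pairs within modality 1
    (``intra_modality_1``) and modality 2 (``intra_modality_2``); the
    cross-block diagonal, i.e. the same finger across modalities
    (``inter_modality_same``); and adjacent-finger entries of the
    cross block (``inter_modality_adjacent``). Masked (NaN) entries are
    excluded; ``*_n`` fields report the effective counts.
    """
    values = matrix.values if isinstance(matrix, RDM) else np.asarray(matrix, dtype=float)
    k = values.shape[0]
    if n_fingers is None:
        if k % 2:
            raise ValueError("joint matrix must have an even size")
        n_fingers = k // 2
    n = n_fingers

    def masked_mean(entries: np.ndarray) -> tuple[float, int]:
        entries = entries[np.isfinite(entries)]
        if entries.size == 0:
            raise ValueError("fully masked block")
        return float(entries.mean()), int(entries.size)

    adj = np.array([values[i, i + 1] for i in range(n - 1)])
    intra1, n1 = masked_mean(adj)
    adj2 = np.array([values[n + i, n + i + 1] for i in range(n - 1)])
    intra2, n2 = masked_mean(adj2)
    cross = values[:n, n:]
    same, ns = masked_mean(np.diag(cross))
    cross_adj = np.concatenate(
        [np.array([cross[i, i + 1] for i in range(n - 1)]),
         np.array([cross[i + 1, i] for i in range(n - 1)])]
    )
    inter_adj, na = masked_mean(cross_adj)
    return {
        "intra_modality_1": intra1,
        "intra_modality_2": intra2,
        "inter_modality_same": same,
        "inter_modality_adjacent": inter_adj,
        "intra_modality_1_n": n1,
        "intra_modality_2_n": n2,
        "inter_modality_same_n": ns,
        "inter_modality_adjacent_n": na,
    }


def fisher_z(r) -> np.ndarray | float:
    """Fisher transform atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r[np.isfinite(r)]) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def functional_connectivity(timeseries: np.ndarray, labels=None) -> RDM:
    """Fisher-z connectivity matrix from ROI time series (rows = ROIs)."""
    ts = np.asarray(timeseries, dtype=float)
    corr = np.corrcoef(ts)
    z = np.arctanh(np.clip(corr, -1 + 1e-12, 1 - 1e-12))
    np.fill_diagonal(z, 0.0)
    return RDM(z, labels or [])


def normalize_structural(counts: np.ndarray, labels=None) -> RDM:
    """Divide fiber counts by the matrix maximum (scale-invariant)."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("fiber counts must be non-negative")
    mx = np.nanmax(counts)
    if not mx > 0:
        raise ValueError("all-zero count matrix")
    out = counts / mx
    np.fill_diagonal(out, 0.0)
    return RDM(out, labels or [])


def distance_correct(connectivity: RDM, distances: RDM) -> RDM:
    """Divide connectivity by inter-ROI Euclidean distance, entrywise.

    Removes the distance bias shared by structural and functional
    connectivity. The diagonal is left at zero; zero or masked
    distances propagate as masked entries.
    """
    if connectivity.labels != distances.labels:
        raise ValueError("label mismatch between connectivity and distances")
    c = connectivity.values.copy()
    d = distances.values
    off = ~np.eye(c.shape[0], dtype=bool)
    bad = off & (~np.isfinite(d) | (d <= 0))
    if bad.any():
        logger.warning("%d entries masked (zero or missing distance)", int(bad.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(off, c / d, 0.0)
    out[bad] = np.nan
    return RDM(out, connectivity.labels)


def classical_mds(rdm: RDM | np.ndarray, dims: int = 2) -> np.ndarray:
    """Torgerson classical multidimensional scaling.

    Negative dissimilarities (possible for crossnobis estimates) are
    clipped to 0 before double centering. Coordinates are the top-d
    eigenvectors scaled by sqrt(eigenvalue); axes whose eigenvalue is
    not positive are padded with zeros. Sign convention: the first
    nonzero coordinate of each axis is positive.
    """
    d = rdm.values if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    if np.any(d < 0):
        logger.warning("negative dissimilarities clipped to 0 for MDS")
        d = np.clip(d, 0.0, None)
    n = d.shape[0]
    h = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * h @ (d**2) @ h
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    n_pos = int(np.sum(w > 1e-12))
    if dims > n_pos:
        logger.warning("only %d positive eigenvalues for %d requested dims", n_pos, dims)
    coords = np.zeros((n, dims))
    use = min(dims, n_pos)
    coords[:, :use] = v[:, :use] * np.sqrt(w[:use])
    for a in range(use):
        col = coords[:, a]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, a] = -col
    return coords
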