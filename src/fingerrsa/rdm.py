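"""Labeled dissimilarity matrices.

The central container of the package is a small labeled square matrix:
pairwise dissimilarities between finger conditions, either behavioral
(model RDMs built from hand geometry, kinematics or EMG) or neural
(cross-validated Mahalanobis distances between multivoxel patterns).
Cross-validated entries may legitimately be negative; masked (missing)
entries are stored as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: provenance tags for behavioral model RDMs
MODEL_PROVENANCES = ("real_hand", "perceived_hand", "manipulation", "muscle", "group_mean")


@dataclass
class RDM:
    """Symmetric dissimilarity matrix with condition labels.

    Parameters
    ----------
    values : (n, n) ndarray
        Symmetric, zero diagonal. NaN marks masked entries. Negative
        off-diagonal values are allowed (cross-validated distance
        estimates are unbiased, hence can undershoot zero).
    labels : sequence of str
        Condition labels, e.g. ``["D1", ..., "D5"]`` or
        ``["D1_motor", ..., "D5_tactile"]``.
    provenance : str, optional
        For behavioral model RDMs, one of `MODEL_PROVENANCES`.
    """

    values: np.ndarray
    labels: list[str] = field(default_factory=list)
    provenance: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("RDM values must be a square matrix")
        n = self.values.shape[0]
        if not self.labels:
            self.labels = [f"D{i + 1}" for i in range(n)]
        self.labels = list(self.labels)
        if len(self.labels) != n:
            raise ValueError("label count does not match matrix size")
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        finite = np.isfinite(self.values)
        sym_ok = np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite.T, self.values.T, 0.0),
            atol=1e-10,
        ) and np.array_equal(finite, finite.T)
        if not sym_ok:
            raise ValueError("RDM must be symmetric (NaN mask included)")
        if not np.allclose(np.diag(self.values)[np.isfinite(np.diag(self.values))], 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        if self.provenance is not None and self.provenance not in MODEL_PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def vector(self) -> np.ndarray:
        """Strict upper triangle, row-major (length n(n-1)/2)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def mask(self) -> np.ndarray:
        """Boolean matrix, True where the entry is available."""
        return np.isfinite(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, provenance: str | None = None) -> "RDM":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.columns), provenance=provenance)

    @classmethod
    def from_condensed(cls, condensed: np.ndarray, labels=None, provenance=None) -> "RDM":
        """Build from a condensed (upper-triangle) distance vector."""
        from scipy.spatial.distance import squareform

        return cls(squareform(np.asarray(condensed, dtype=float)), labels or [], provenance=provenance)


def average_rdms(rdms: list[RDM], provenance: str | None = None) -> RDM:
    """Unweighted mean of same-shape RDMs, ignoring masked cells."""
    if not rdms:
        raise ValueError("need at least one RDM")
    n = rdms[0].n
    labels = rdms[0].labels
    for r in rdms:
        if r.n != n or r.labels != labels:
            raise ValueError("RDMs must share shape and labels")
    stack = np.stack([r.values for r in rdms])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return RDM(mean, labels, provenance=provenance)
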