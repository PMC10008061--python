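"""RSA model regressions on dissimilarity matrices.

The neural RDM of each subject/hemisphere/region/task is compared with
the behavioral models through

* a non-negative multiple regression
  D ~ real hand + perceived hand + manipulation + muscle
  on z-scored upper-triangle vectors (negative weights are not
  meaningful for dissimilarity models);
* per-model simple regressions (OLS slope of z-scored vectors, i.e.
  the Pearson correlation), as a collinearity control;
* a leave-one-out noise ceiling: each subject's RDM regressed on the
  group-mean RDM with that subject removed, averaged per task/region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

from .rdm import RDM

logger = logging.getLogger(__name__)


def vectorize_and_zscore(rdm: RDM | np.ndarray) -> np.ndarray:
    """Strict upper triangle, z-scored with the population SD.

    Raises on constant vectors (zero variance), which carry no
    geometry to regress on.
    """
    if isinstance(rdm, RDM):
        vec = rdm.vector()
    else:
        arr = np.asarray(rdm, dtype=float)
        vec = arr[np.triu_indices(arr.shape[0], k=1)] if arr.ndim == 2 else arr
    if vec.size < 3:
        raise ValueError("need an RDM of at least 3 conditions")
    sd = vec.std()  # population SD
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("constant (zero-variance) RDM vector")
    return (vec - vec.mean()) / sd


@dataclass
class RegressionResult:
    model_names: list[str]
    betas: np.ndarray
    residual_norm: float
    condition_number: float
    fit_type: str

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.model_names, self.betas.tolist()))


def nnls_multiple_regression(
    d: np.ndarray, models: list[np.ndarray], model_names: list[str] | None = None
) -> RegressionResult:
    """Non-negative least squares fit of D on the model vectors.

    All vectors must be z-scored, so no intercept is fitted. Solved by
    the active-set method (deterministic).
    """
    d = np.asarray(d, dtype=float)
    design = np.column_stack([np.asarray(m, dtype=float) for m in models])
    if design.shape[0] != d.shape[0]:
        raise ValueError("model vectors and data vector must share length")
    betas, rnorm = nnls(design, d)
    cond = float(np.linalg.cond(design))
    if cond > 1e8:
        logger.warning("near rank-deficient design (cond=%.2g)", cond)
    names = model_names or [f"model{i}" for i in range(design.shape[1])]
    return RegressionResult(names, betas, float(rnorm), cond, "nnls")


def simple_regressions(
    d: np.ndarray, models: list[np.ndarray], model_names: list[str] | None = None,
    non_negative: bool = False,
) -> RegressionResult:
    """Per-model OLS slope of z-scored D on each z-scored model.

    For z-scored vectors (population SD) the slope equals the Pearson
    correlation. With `non_negative=True`, negative slopes are clamped
    to zero.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    betas = []
    for m in models:
        m = np.asarray(m, dtype=float)
        denom = float(m @ m)
        if denom == 0:
            raise ValueError("constant model vector")
        b = float(m @ d) / denom
        betas.append(max(b, 0.0) if non_negative else b)
    names = model_names or [f"model{i}" for i in range(len(models))]
    # fits are per-model, so no single joint residual applies
    return RegressionResult(names, np.array(betas), float("nan"), float(n), "simple")


@dataclass
class NoiseCeiling:
    per_subject: np.ndarray
    ceiling: float
    n_subjects: int


def noise_ceiling(subject_rdms: list[RDM | np.ndarray]) -> NoiseCeiling:
    """Leave-one-out noise ceiling for one task/region cell.

    For each subject, the simple-regression coefficient of the
    subject's z-scored RDM vector on the z-scored mean RDM vector of
    the remaining subjects; the ceiling is the mean coefficient.
    """
    if len(subject_rdms) < 2:
        raise ValueError("noise ceiling needs at least 2 subjects")
    vectors = np.stack(
        [r.vector() if isinstance(r, RDM) else np.asarray(r, dtype=float) for r in subject_rdms]
    )
    n = vectors.shape[0]
    coefs = np.empty(n)
    for i in range(n):
        loo_mean = np.delete(vectors, i, axis=0).mean(axis=0)
        zi = vectorize_and_zscore(vectors[i])
        zm = vectorize_and_zscore(loo_mean)
        coefs[i] = simple_regressions(zi, [zm]).betas[0]
    return NoiseCeiling(coefs, float(coefs.mean()), n)


def fit_rdm_models(
    neural: RDM, models: list[RDM], mode: str = "nnls"
) -> RegressionResult:
    """Z-score and regress a neural RDM on behavioral model RDMs."""
    d = vectorize_and_zscore(neural)
    mats = [vectorize_and_zscore(m) for m in models]
    names = [m.provenance or f"model{i}" for i, m in enumerate(models)]
    if mode == "nnls":
        return nnls_multiple_regression(d, mats, names)
    if mode == "simple":
        return simple_regressions(d, mats, names)
    raise ValueError(f"unknown mode {mode!r}")


def group_contrasts(
    table: pd.DataFrame, value: str = "beta", within: str = "model",
    unit: str = "subject", alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Cell means plus paired comparisons with Benjamini-Hochberg FDR.

    `table` is tidy with one row per unit x level of `within`; the
    design must be balanced (every unit observed at every level).
    """
    from scipy import stats

    wide = table.pivot_table(index=unit, columns=within, values=value)
    if wide.isna().any().any():
        raise ValueError("unbalanced table: every unit needs every level")
    levels = list(wide.columns)
    summary = pd.DataFrame(
        {"mean": wide.mean(axis=0), "sd": wide.std(axis=0, ddof=1), "n": wide.shape[0]}
    )
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            diff = wide[levels[i]] - wide[levels[j]]
            if np.isclose(diff.std(ddof=1), 0.0):
                t_val, p_val = (0.0, 1.0) if np.allclose(diff, 0) else (np.nan, np.nan)
            else:
                t_val, p_val = stats.ttest_rel(wide[levels[i]], wide[levels[j]])
            rows.append(
                {
                    "level_a": levels[i],
                    "level_b": levels[j],
                    "mean_diff": float(diff.mean()),
                    "t": float(t_val),
                    "p": float(p_val),
                }
            )
    pairs = pd.DataFrame(rows)
    if len(pairs):
        valid = pairs["p"].notna()
        adj = np.full(len(pairs), np.nan)
        if valid.any():
            adj[valid.to_numpy()] = multipletests(
                pairs.loc[valid, "p"].to_numpy(), alpha=alpha, method="fdr_bh"
            )[1]
        pairs["p_fdr"] = adj
        pairs["significant"] = pairs["p_fdr"] < alpha
    return {"summary": summary, "pairwise": pairs}
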