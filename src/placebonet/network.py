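"""Covariate residualization and group-wise binarized covariance networks.

Regional CT is first adjusted by per-region OLS for total brain volume, age,
sex and age x sex (all participants), plus disease duration, site and lesion
load for the MS sample (configurable: without lesion load, or with baseline
EDSS substituted). The residuals replace the raw thickness values. Within
each group a regions x regions Pearson correlation matrix is computed across
subjects and binarized by keeping the top fraction ``s`` ("sparsity") of
region pairs ranked by signed correlation, so every group graph has the same
number of edges m = round(s * n(n-1)/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parcellation import N_REGIONS

logger = logging.getLogger(__name__)

__all__ = [
    "residualize",
    "correlation_matrix",
    "sparsity_grid",
    "threshold_graph",
    "GroupCorrelation",
    "BinaryGraph",
]

MS_GROUPS = ("nonresponder", "responder")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns that are linear combinations of the columns before them."""
    bad, rank = [], 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, : j + 1])
        if r == rank:
            bad.append(names[j])
        rank = r
    return bad


def _design(meta: pd.DataFrame, columns: list[str]) -> tuple[np.ndarray, list[str]]:
    """Build a design matrix with intercept; site expands to indicators."""
    cols: list[np.ndarray] = [np.ones(len(meta))]
    names = ["intercept"]
    age_c = meta["age"].to_numpy(float) - meta["age"].to_numpy(float).mean()
    for c in columns:
        if c == "site":
            dummies = pd.get_dummies(meta["site"], prefix="site", drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(float))
                names.append(dc)
        elif c == "age_x_sex":
            cols.append(age_c * meta["sex"].to_numpy(float))
            names.append("age_x_sex")
        else:
            cols.append(meta[c].to_numpy(float))
            names.append(c)
    return np.column_stack(cols), names


def _fit_residuals(Y: np.ndarray, X: np.ndarray, names: list[str]) -> np.ndarray:
    keep, dropped = [], []
    for j in range(X.shape[1]):
        if j > 0 and np.ptp(X[:, j]) == 0:
            dropped.append(names[j])
        else:
            keep.append(j)
    if dropped:
        logger.warning("dropping constant covariate columns: %s", dropped)
        X = X[:, keep]
        names = [names[j] for j in keep]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def residualize(
    ct: pd.DataFrame,
    metadata: pd.DataFrame,
    covariate_model: str = "with-ll",
    model_scope: str = "pooled",
) -> pd.DataFrame:
    """Per-region OLS residuals of CT on the covariate set.

    MS subjects (both placebo groups) are fitted in one model — pooled by
    default, so group differences in covariance are not absorbed — with
    covariates total brain volume, age, sex, age x sex, disease duration,
    site, and a disease-burden term chosen by ``covariate_model``:
    ``"with-ll"`` (lesion load, default), ``"without-ll"`` (none) or
    ``"edss"`` (baseline EDSS). Controls are fitted separately with the
    demographic covariates only. ``model_scope="per-group"`` fits each MS
    group in its own model instead.
    """
    if covariate_model not in ("with-ll", "without-ll", "edss"):
        raise ValueError(f"unknown covariate_model {covariate_model!r}")
    meta = metadata.set_index("subject_id").loc[ct.index]
    burden = {"with-ll": ["lesion_load"], "without-ll": [], "edss": ["baseline_edss"]}
    ms_cols = (
        ["total_brain_volume", "age", "sex", "age_x_sex", "disease_duration", "site"]
        + burden[covariate_model]
    )
    hc_cols = ["total_brain_volume", "age", "sex", "age_x_sex"]

    out = ct.copy()
    is_ms = meta["group"].isin(MS_GROUPS)
    fit_sets: list[pd.Index] = []
    if model_scope == "pooled":
        fit_sets.append(ct.index[is_ms.to_numpy()])
    elif model_scope == "per-group":
        for g in MS_GROUPS:
            fit_sets.append(ct.index[(meta["group"] == g).to_numpy()])
    else:
        raise ValueError(f"unknown model_scope {model_scope!r}")
    for idx in fit_sets:
        if len(idx) == 0:
            continue
        X, names = _design(meta.loc[idx], ms_cols)
        out.loc[idx] = _fit_residuals(ct.loc[idx].to_numpy(float), X, names)
    hc_idx = ct.index[(meta["group"] == "control").to_numpy()]
    if len(hc_idx):
        X, names = _design(meta.loc[hc_idx], hc_cols)
        out.loc[hc_idx] = _fit_residuals(ct.loc[hc_idx].to_numpy(float), X, names)
    return out


@dataclass
class GroupCorrelation:
    """Inter-regional Pearson correlation matrix for one group."""

    group: str
    matrix: pd.DataFrame  # regions x regions
    n_subjects: int

    @property
    def median_r(self) -> float:
        return float(np.nanmedian(self._offdiag()))

    @property
    def r_range(self) -> tuple[float, float]:
        off = self._offdiag()
        return float(np.nanmin(off)), float(np.nanmax(off))

    def _offdiag(self) -> np.ndarray:
        v = self.matrix.to_numpy()
        return v[np.triu_indices(v.shape[0], 1)]


def correlation_matrix(
    residuals: pd.DataFrame, labels: pd.Series
) -> dict[str, GroupCorrelation]:
    """Within-group inter-regional correlation matrices.

    A region with zero variance inside a group has its correlations set to
    NaN (excluded from thresholding) with a logged warning. Requires >= 3
    subjects per group.
    """
    labels = labels.loc[residuals.index]
    out = {}
    for g in pd.unique(labels):
        sub = residuals.loc[labels == g]
        if len(sub) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 subjects")
        vals = sub.to_numpy(float)
        sd = vals.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.corrcoef(vals.T)
        if (sd == 0).any():
            dead = list(np.asarray(residuals.columns)[sd == 0])
            logger.warning("zero-variance regions in group %r: %s", g, dead)
            R[sd == 0, :] = np.nan
            R[:, sd == 0] = np.nan
        np.fill_diagonal(R, 1.0)
        out[g] = GroupCorrelation(
            group=str(g),
            matrix=pd.DataFrame(R, index=residuals.columns, columns=residuals.columns),
            n_subjects=len(sub),
        )
    return out


def sparsity_grid(lo: float = 0.1, hi: float = 0.5, k: int = 30) -> np.ndarray:
    """k linearly spaced sparsity thresholds, inclusive of both endpoints."""
    if not (0 < lo < hi <= 1):
        raise ValueError("require 0 < lo < hi <= 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    return np.linspace(lo, hi, k)


@dataclass
class BinaryGraph:
    """Undirected binarized covariance graph at one sparsity level."""

    adjacency: np.ndarray  # boolean, symmetric, zero diagonal
    sparsity: float
    r_cutoff: float  # smallest correlation admitted as an edge

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


def threshold_graph(R, s: float, absolute: bool = False) -> BinaryGraph:
    """Binarize a correlation matrix at sparsity ``s``.

    Keeps the m = round(s * n(n-1)/2) strongest region pairs by signed
    correlation (or |r| with ``absolute=True``; signed ranking is the
    structural-covariance convention, so negative correlations can only enter
    at high sparsity). Ties are broken by (i, j) lexicographic order, making
    edge sets nested across increasing sparsity. NaN pairs are never selected.
    """
    if not 0 < s <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    mat = R.to_numpy(float) if isinstance(R, pd.DataFrame) else np.asarray(R, float)
    n = mat.shape[0]
    if mat.shape != (n, n):
        raise ValueError("correlation matrix must be square")
    ii, jj = np.triu_indices(n, 1)
    r = mat[ii, jj]
    m = _round_half_away(s * n * (n - 1) / 2)
    key = np.abs(r) if absolute else r.copy()
    valid = np.isfinite(key)
    if valid.sum() < m:
        raise ValueError(
            f"only {int(valid.sum())} valid pairs but {m} edges requested"
        )
    key[~valid] = -np.inf
    order = np.lexsort((jj, ii, -key))[:m]
    adj = np.zeros((n, n), dtype=bool)
    adj[ii[order], jj[order]] = True
    adj |= adj.T
    cutoff = float(r[order[-1]]) if m > 0 else float("nan")
    return BinaryGraph(adjacency=adj, sparsity=float(s), r_cutoff=cutoff)
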