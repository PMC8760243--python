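"""Region-level general linear models of cortical thickness.

Region-level stand-in for vertex-wise CT inference: each of the 78 regional
mean thickness values is modelled by OLS with the study covariates, and the
coefficient of interest is tested across regions with Benjamini-Hochberg FDR
control (q = 0.05). This is a declared substitute for surface-based
random-field-theory correction — outputs are region tables, not corrected
vertex maps.

Model variants (terms mirror the study's printed equations):

``group``        covariates + LL + Group          (responder vs non-responder)
``dimensional``  covariates + LL + Baseline + Response   (continuous response)
``interaction``  covariates + LL + Group + Responder x LL (the main effects
                 are required for the product term to measure a *difference*
                 of slopes; ``include_main_effects=False`` gives the bare
                 product-only parameterisation, which cannot express a
                 lesion-load slope confined to the reference group)
``ll``           covariates + LL, within a single group

where "covariates" is intercept, total brain volume, age, sex, age x sex
(on centered age), disease duration and site indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import _collinear_columns

logger = logging.getLogger(__name__)

__all__ = [
    "fit_regional_model",
    "per_group_ll_slopes",
    "RegionalThicknessGLM",
    "RegionalGLMResults",
]

MS_GROUPS = ("nonresponder", "responder")


def _base_design(meta: pd.DataFrame) -> tuple[list[np.ndarray], list[str]]:
    age = meta["age"].to_numpy(float)
    sex = meta["sex"].to_numpy(float)
    age_c = age - age.mean()
    cols = [
        np.ones(len(meta)),
        meta["total_brain_volume"].to_numpy(float),
        age,
        sex,
        age_c * sex,
        meta["disease_duration"].to_numpy(float),
    ]
    names = ["intercept", "volume", "age", "sex", "age_x_sex", "disease_duration"]
    dummies = pd.get_dummies(meta["site"], prefix="site", drop_first=True)
    for dc in dummies.columns:
        cols.append(dummies[dc].to_numpy(float))
        names.append(dc)
    return cols, names


def _model_design(
    meta: pd.DataFrame, model: str, include_main_effects: bool
) -> tuple[np.ndarray, list[str], str]:
    cols, names = _base_design(meta)
    ll = meta["lesion_load"].to_numpy(float)
    if model == "group":
        grp = (meta["group"] == "responder").to_numpy(float)
        cols += [ll, grp]
        names += ["lesion_load", "group"]
        interest = "group"
    elif model == "dimensional":
        cols += [ll, meta["baseline_qol"].to_numpy(float),
                 meta["response"].to_numpy(float)]
        names += ["lesion_load", "baseline", "response"]
        interest = "response"
    elif model == "interaction":
        grp = (meta["group"] == "responder").to_numpy(float)
        if include_main_effects:
            cols += [ll, grp]
            names += ["lesion_load", "group"]
        cols += [grp * ll]
        names += ["responder_x_ll"]
        interest = "responder_x_ll"
    elif model == "ll":
        cols += [ll]
        names += ["lesion_load"]
        interest = "lesion_load"
    else:
        raise ValueError(f"unknown model {model!r}")
    return np.column_stack(cols), names, interest


def _drop_constant(X: np.ndarray, names: list[str], protect: str):
    keep, dropped = [0], []
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            if names[j] == protect:
                raise ValueError(
                    f"term of interest {protect!r} has zero variance"
                )
            dropped.append(names[j])
        else:
            keep.append(j)
    if dropped:
        logger.warning("dropping constant design columns: %s", dropped)
    return X[:, keep], [names[j] for j in keep]


def _batch_ols(X: np.ndarray, Y: np.ndarray, names: list[str]):
    """OLS of every column of Y on X: beta, SE, t, p, dof, degenerate flag."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        bad = _collinear_columns(X, names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    if n <= p:
        raise ValueError(f"{n} observations cannot identify {p} parameters")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    degenerate = sigma2 <= np.finfo(float).eps * np.abs(Y).max() ** 2 * n
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), dof)
    return beta, se, t, pvals, dof, degenerate


@dataclass
class RegionalGLMResults:
    """Per-region estimates for the coefficient of interest, FDR-corrected."""

    model: str
    term: str
    table: pd.DataFrame  # region, estimate, se, t, p, q, significant, degenerate
    n_subjects: int
    dof: int
    q_threshold: float = 0.05

    @property
    def significant_regions(self) -> list[str]:
        return self.table.loc[self.table["significant"], "region"].tolist()

    @property
    def any_significant(self) -> bool:
        return bool(self.table["significant"].any())

    def summary(self) -> str:
        t = self.table
        sig = t[t["significant"]]
        lines = [
            f"Regional CT model {self.model!r} — term {self.term!r}",
            "=" * 64,
            f"n={self.n_subjects}  dof={self.dof}  regions={len(t)}  "
            f"BH-FDR q<{self.q_threshold}: {len(sig)} significant",
        ]
        for _, row in sig.iterrows():
            lines.append(
                f"  {row['region']:<24s} b={row['estimate']:+.3e}  "
                f"t={row['t']:+.2f}  p={row['p']:.2e}  q={row['q']:.3f}"
            )
        return "\n".join(lines)


def fit_regional_model(
    ct: pd.DataFrame,
    metadata: pd.DataFrame,
    model: str = "group",
    include_main_effects: bool = True,
    q_threshold: float = 0.05,
) -> RegionalGLMResults:
    """Fit the chosen per-region OLS model over the MS sample.

    ``metadata`` must carry the covariates; the ``dimensional`` model
    additionally needs ``baseline_qol`` and ``response`` columns. The
    coefficient of interest is extracted per region and BH-FDR corrected
    across the 78 regions. Regions with zero residual variance are flagged
    degenerate (p = NaN, never significant).
    """
    meta = metadata.set_index("subject_id")
    meta = meta[meta["group"].isin(MS_GROUPS)]
    idx = ct.index.intersection(meta.index)
    meta = meta.loc[idx]
    Y = ct.loc[idx].to_numpy(float)
    X, names, interest = _model_design(meta, model, include_main_effects)
    X, names = _drop_constant(X, names, interest)
    beta, se, t, p, dof, degen = _batch_ols(X, Y, names)
    j = names.index(interest)
    pj = p[j].copy()
    pj[degen] = np.nan
    finite = np.isfinite(pj)
    q = np.full_like(pj, np.nan)
    sig = np.zeros(len(pj), dtype=bool)
    if finite.any():
        rej, qv, *_ = multipletests(pj[finite], alpha=q_threshold, method="fdr_bh")
        q[finite] = qv
        sig[finite] = rej
    if degen.any():
        logger.warning("%d regions with zero residual variance (degenerate)",
                       int(degen.sum()))
    table = pd.DataFrame(
        {
            "region": ct.columns,
            "estimate": beta[j],
            "se": se[j],
            "t": t[j],
            "p": pj,
            "q": q,
            "significant": sig,
            "degenerate": degen,
        }
    )
    return RegionalGLMResults(
        model=model, term=interest, table=table,
        n_subjects=len(idx), dof=dof, q_threshold=q_threshold,
    )


def per_group_ll_slopes(
    ct: pd.DataFrame,
    metadata: pd.DataFrame,
    group: str,
    interaction: RegionalGLMResults | None = None,
    force: bool = False,
    q_threshold: float = 0.05,
) -> RegionalGLMResults:
    """Per-region lesion-load slope within one group (follow-up model).

    The follow-up is gated on the interaction stage: pass its results (from
    ``fit_regional_model(..., model="interaction")``) or set ``force=True``
    (logged) to run it stand-alone.
    """
    if interaction is None and not force:
        raise ValueError(
            "run the interaction model first and pass its results, or set "
            "force=True to override the gate"
        )
    if interaction is None:
        logger.warning("per-group LL follow-up run without the interaction gate")
    elif interaction.model != "interaction":
        raise ValueError("gate results must come from the interaction model")
    meta = metadata[metadata["group"] == group]
    if meta.empty:
        raise ValueError(f"no subjects in group {group!r}")
    sub = ct.loc[ct.index.intersection(meta.set_index("subject_id").index)]
    res = fit_regional_model(sub, meta, model="ll", q_threshold=q_threshold)
    res.model = f"ll[{group}]"
    return res


class RegionalThicknessGLM:
    """Statsmodels-style wrapper bundling the regional CT model variants.

    Construct once from the CT table and subject metadata, then call
    :meth:`fit` for any variant. The interaction -> per-group follow-up gate
    is tracked on the instance.
    """

    def __init__(self, ct: pd.DataFrame, metadata: pd.DataFrame):
        self.ct = ct
        self.metadata = metadata
        self._interaction: RegionalGLMResults | None = None

    @classmethod
    def from_dataframe(cls, ct, metadata) -> "RegionalThicknessGLM":
        return cls(ct, metadata)

    def fit(self, model: str = "group", **kw) -> RegionalGLMResults:
        res = fit_regional_model(self.ct, self.metadata, model=model, **kw)
        if model == "interaction":
            self._interaction = res
        return res

    def fit_ll_slopes(self, group: str, force: bool = False, **kw) -> RegionalGLMResults:
        return per_group_ll_slopes(
            self.ct, self.metadata, group,
            interaction=self._interaction, force=force, **kw,
        )
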