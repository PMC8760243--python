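"""Placebo-response scoring from longitudinal quality-of-life trajectories.

The response measure is the area under each subject's MSQOL-54 Physical
Health trajectory (trapezoidal rule over the visit schedule), adjusted for
the baseline score by ordinary least squares — higher baselines leave less
room for improvement — and standardized. Subjects with positive standardized
residuals are classified as placebo responders; residuals <= 0 (including
exactly 0) as non-responders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "compute_auc",
    "adjust_for_baseline",
    "classify_responders",
    "PlaceboResponseModel",
    "PlaceboResponseResults",
]


def compute_auc(weeks, scores) -> float:
    """Trapezoidal area under one (weeks, scores) trajectory, in points*weeks.

    Missing scores are dropped pairwise and the trapezoid taken over the
    remaining nodes. Fewer than two non-missing visits returns NaN with a
    logged warning (the subject is scored missing).
    """
    weeks = np.asarray(weeks, float)
    scores = np.asarray(scores, float)
    if weeks.shape != scores.shape:
        raise ValueError("weeks and scores must have equal length")
    if np.any(np.diff(weeks) <= 0):
        raise ValueError("weeks must be strictly increasing")
    ok = np.isfinite(scores) & np.isfinite(weeks)
    if ok.sum() < 2:
        logger.warning("fewer than 2 non-missing visits; AUC scored missing")
        return float("nan")
    return float(np.trapezoid(scores[ok], weeks[ok]))


@dataclass
class BaselineAdjustment:
    """OLS metadata for the AUC-on-baseline adjustment regression."""

    slope: float
    slope_se: float
    slope_t: float
    slope_p: float
    conf_int: tuple[float, float]
    intercept: float
    n: int
    degenerate: bool = False  # zero baseline variance fallback

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_se": self.slope_se,
            "slope_t": self.slope_t,
            "slope_p": self.slope_p,
            "conf_int_95": list(self.conf_int),
            "intercept": self.intercept,
            "n": self.n,
            "degenerate": self.degenerate,
        }


def adjust_for_baseline(aucs, baselines) -> tuple[np.ndarray, BaselineAdjustment]:
    """Regress AUC on baseline score and return standardized residuals.

    Residuals are standardized by their unbiased (n-1) sample SD, giving mean
    0 and SD 1 over the cohort. Zero variance in the baselines triggers a
    degenerate fallback (centered, standardized AUCs) with a logged warning;
    zero residual variance (AUC an exact linear function of baseline) is an
    error, since standardization is then undefined.
    """
    aucs = np.asarray(aucs, float)
    baselines = np.asarray(baselines, float)
    if aucs.shape != baselines.shape:
        raise ValueError("aucs and baselines must have equal length")
    ok = np.isfinite(aucs) & np.isfinite(baselines)
    if ok.sum() < 3:
        raise ValueError("need >= 3 subjects with both AUC and baseline")
    a, b = aucs[ok], baselines[ok]
    if np.ptp(b) == 0:
        logger.warning(
            "baseline scores have zero variance; residuals are centered "
            "standardized AUCs"
        )
        resid = a - a.mean()
        meta = BaselineAdjustment(
            slope=0.0, slope_se=float("nan"), slope_t=float("nan"),
            slope_p=float("nan"), conf_int=(float("nan"), float("nan")),
            intercept=float(a.mean()), n=int(ok.sum()), degenerate=True,
        )
    else:
        fit = sm.OLS(a, sm.add_constant(b)).fit()
        resid = np.asarray(fit.resid)
        ci = fit.conf_int()
        meta = BaselineAdjustment(
            slope=float(fit.params[1]),
            slope_se=float(fit.bse[1]),
            slope_t=float(fit.tvalues[1]),
            slope_p=float(fit.pvalues[1]),
            conf_int=(float(ci[1][0]), float(ci[1][1])),
            intercept=float(fit.params[0]),
            n=int(ok.sum()),
        )
    sd = resid.std(ddof=1)
    if sd <= 1e-10 * max(1.0, float(np.abs(a).max())):
        raise ValueError(
            "residuals have zero variance (AUC is an exact linear function "
            "of baseline); standardized residuals are undefined"
        )
    out = np.full(aucs.shape, np.nan)
    out[ok] = resid / sd
    return out, meta


def classify_responders(residuals) -> np.ndarray:
    """Dichotomize standardized residuals: strictly > 0 -> responder."""
    residuals = np.asarray(residuals, float)
    return residuals > 0


@dataclass
class PlaceboResponseResults:
    """Per-subject response scores plus adjustment-regression metadata."""

    table: pd.DataFrame  # subject_id, auc, baseline, residual, responder
    adjustment: BaselineAdjustment
    excluded: list = field(default_factory=list)

    @property
    def n_responders(self) -> int:
        return int(self.table["responder"].sum())

    @property
    def n_nonresponders(self) -> int:
        return int((~self.table["responder"] & self.table["residual"].notna()).sum())

    def group_stats(self) -> pd.DataFrame:
        """Mean and SD of the standardized residuals within each class."""
        t = self.table.dropna(subset=["residual"])
        lab = np.where(t["responder"], "responder", "nonresponder")
        return (
            t.assign(group=lab)
            .groupby("group")["residual"]
            .agg(["mean", "std", "count"])
        )

    def summary(self) -> str:
        g = self.group_stats()
        a = self.adjustment
        lines = [
            "Placebo response scoring (AUC of MSQOL-54 PH, baseline-adjusted)",
            "=" * 64,
            f"subjects scored: {self.table['residual'].notna().sum()}"
            f"   excluded (<2 visits): {len(self.excluded)}",
            f"baseline adjustment: slope={a.slope:.4g} (SE {a.slope_se:.3g}, "
            f"t={a.slope_t:.3g}, p={a.slope_p:.3g}, "
            f"95% CI [{a.conf_int[0]:.4g}, {a.conf_int[1]:.4g}])",
        ]
        for name, row in g.iterrows():
            lines.append(
                f"{name:>13s}: n={int(row['count'])}  residual mean="
                f"{row['mean']:+.2f}  SD={row['std']:.2f}"
            )
        return "\n".join(lines)


class PlaceboResponseModel:
    """Placebo-response classifier fitted to a long-format QoL table.

    Parameters
    ----------
    qol : DataFrame
        Columns ``subject_id``, ``week``, ``score``; one row per subject per
        assessment.
    change_scores : bool
        If True, compute the AUC of change-from-baseline instead of raw
        scores (sensitivity-analysis mode); the baseline adjustment is then
        applied to the change-score AUC.
    """

    def __init__(self, qol: pd.DataFrame, change_scores: bool = False):
        required = {"subject_id", "week", "score"}
        if not required.issubset(qol.columns):
            raise ValueError(f"QoL table must have columns {sorted(required)}")
        self.qol = qol
        self.change_scores = change_scores

    @classmethod
    def from_dataframe(cls, qol: pd.DataFrame, **kw) -> "PlaceboResponseModel":
        return cls(qol, **kw)

    def fit(self) -> PlaceboResponseResults:
        rows = []
        excluded = []
        for sid, traj in self.qol.groupby("subject_id", sort=True):
            traj = traj.sort_values("week")
            if traj["week"].duplicated().any():
                raise ValueError(f"duplicate weeks for subject {sid!r}")
            weeks = traj["week"].to_numpy(float)
            scores = traj["score"].to_numpy(float)
            baseline = scores[0] if np.isfinite(scores[0]) else np.nan
            if self.change_scores:
                scores = scores - baseline
            auc = compute_auc(weeks, scores)
            if not np.isfinite(auc) or not np.isfinite(baseline):
                excluded.append(sid)
                auc = np.nan
            rows.append((sid, auc, baseline))
        tab = pd.DataFrame(rows, columns=["subject_id", "auc", "baseline"])
        residual, meta = adjust_for_baseline(tab["auc"], tab["baseline"])
        tab["residual"] = residual
        tab["responder"] = classify_responders(residual) & np.isfinite(residual)
        return PlaceboResponseResults(table=tab, adjustment=meta, excluded=excluded)
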