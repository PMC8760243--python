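"""Synthetic trial cohorts with the covariance structure the analysis assumes.

Generates three study groups — placebo non-responders, placebo responders and
healthy controls — with demographic margins anchored to the trial's reported
characteristics, regional cortical thickness (CT) drawn from a group-specific
latent-factor model, and longitudinal MSQOL-54 Physical Health trajectories
with a transient improvement in responders only.

The CT generator is a linear factor model

    CT[s, r] = mu_r + sum_k Lambda[g, k, r] f[s, k] + covariate effects
               + slope[g, r] * (log LL_s - mean log LL) + eps[s, r]

with ``f ~ N(0, 1)`` i.i.d. latent factors and ``eps ~ N(0, sigma^2)``
region noise. Three factor structures are available:

``single``
    One common factor with uniform loading; the implied inter-regional
    correlation is the same for every pair, ``lambda^2/(lambda^2+sigma^2)``.
``banded`` (default)
    One global factor with a mild linear loading profile across regions plus
    one wrap-around window factor per region (half-width 16), producing a
    banded correlation matrix whose thresholded graph is lattice-like — the
    "regular network" regime reported for non-responders — with strength
    increasing in the overall loading scale.
``blocks``
    k non-overlapping block factors over contiguous region blocks.

For each group the whole loading matrix is multiplied by one scale solved
numerically so that the implied median off-diagonal correlation equals a
target (defaults 0.66 / 0.49 / 0.41 for non-responders / responders /
controls), which is how "more regionally homogeneous CT" is operationalised.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._seeding import rng_for
from .parcellation import N_REGIONS, region_names

logger = logging.getLogger(__name__)

GROUPS = ("nonresponder", "responder", "control")
MS_GROUPS = ("nonresponder", "responder")

#: Regions carrying the lesion-load -> cortical-thinning coupling in
#: non-responders: right-lateralised sensorimotor, association, precuneus and
#: insula territory.
DEFAULT_LL_REGIONS = (
    "Precentral_R",
    "Postcentral_R",
    "Paracentral_Lobule_R",
    "Parietal_Sup_R",
    "Precuneus_R",
    "Insula_R",
    "SupraMarginal_R",
    "Occipital_Sup_R",
    "Temporal_Mid_R",
    "Temporal_Inf_R",
    "Precentral_L",
    "Occipital_Sup_L",
)


def _as_group_map(value, groups: Sequence[str]) -> dict:
    if isinstance(value, Mapping):
        return {g: value[g] for g in groups}
    return {g: value for g in groups}


@dataclass
class CohortSpec:
    """Group sizes and demographic margins of the simulated trial cohort.

    Defaults reproduce the reported sample: 45 non-responders, 43 responders,
    43 healthy controls, with the published age / sex / disease-duration /
    baseline-QoL margins. Lesion load (mm^3) is log-normal.
    """

    n_nonresponder: int = 45
    n_responder: int = 43
    n_control: int = 43
    age_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "nonresponder": (55.0, 7.4),
            "responder": (53.0, 8.5),
            "control": (52.98, 8.93),
        }
    )
    female_fraction: Mapping[str, float] = field(
        default_factory=lambda: {
            "nonresponder": 27 / 45,
            "responder": 30 / 43,
            "control": 30 / 43,
        }
    )
    disease_duration_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "nonresponder": (18.8, 9.6),
            "responder": (16.7, 8.1),
        }
    )
    n_sites: int = 4
    lesion_load_lognormal_params: tuple[float, float] = (8.5, 1.0)
    baseline_qol_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "nonresponder": (55.54, 21.57),
            "responder": (56.96, 18.79),
        }
    )
    total_brain_volume_mean_sd: tuple[float, float] = (1.45e6, 1.2e5)
    baseline_edss_mean_sd: tuple[float, float] = (4.0, 1.5)
    seed: int = 0

    def counts(self) -> dict[str, int]:
        return {
            "nonresponder": self.n_nonresponder,
            "responder": self.n_responder,
            "control": self.n_control,
        }

    def validate(self) -> None:
        for g, n in self.counts().items():
            if n < 0:
                raise ValueError(f"negative group size for {g!r}: {n}")
        for g, (_, sd) in self.age_mean_sd.items():
            if sd < 0:
                raise ValueError(f"negative age SD for {g!r}")
        for g, frac in self.female_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"female_fraction for {g!r} not in [0, 1]")
        for g, (_, sd) in self.disease_duration_mean_sd.items():
            if sd < 0:
                raise ValueError(f"negative disease-duration SD for {g!r}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.lesion_load_lognormal_params[1] < 0:
            raise ValueError("negative lesion-load log-SD")
        for g, (_, sd) in self.baseline_qol_mean_sd.items():
            if sd < 0:
                raise ValueError(f"negative baseline QoL SD for {g!r}")


@dataclass
class CovarianceStructureSpec:
    """Latent-factor structure of regional cortical thickness per group."""

    n_regions: int = N_REGIONS
    structure: str = "banded"  # "single" | "banded" | "blocks"
    #: per-group overall loading scale; None -> solved from target_median_r
    shared_factor_loading: Mapping[str, float] | None = None
    target_median_r: Mapping[str, float] = field(
        default_factory=lambda: {
            "nonresponder": 0.66,
            "responder": 0.49,
            "control": 0.41,
        }
    )
    global_profile: tuple[float, float] = (1.1, 1.7)
    band_halfwidth: int = 16
    band_amplitude: float = 1.1
    n_blocks: int = 4
    region_noise_sd: float = 0.12  # mm
    regional_mean_ct: np.ndarray | None = None  # mm; default linspace(2.2, 3.0)
    ll_ct_slope: Mapping[str, float] = field(
        default_factory=lambda: {"nonresponder": -0.06, "responder": 0.0}
    )  # mm per log-mm^3
    ll_affected_regions: tuple[str, ...] = DEFAULT_LL_REGIONS
    covariate_effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: {"age": -0.005, "sex": 0.02, "volume": 5e-8}
    )  # mm per year / per female / per mm^3

    def validate(self) -> None:
        if self.region_noise_sd < 0:
            raise ValueError("region_noise_sd must be >= 0")
        if self.shared_factor_loading is not None:
            for g, lam in self.shared_factor_loading.items():
                if lam < 0:
                    raise ValueError(f"negative loading scale for {g!r}")
        if self.structure not in ("single", "banded", "blocks"):
            raise ValueError(f"unknown structure {self.structure!r}")

    def mean_ct(self) -> np.ndarray:
        if self.regional_mean_ct is not None:
            mu = np.asarray(self.regional_mean_ct, float)
            if mu.shape != (self.n_regions,):
                raise ValueError("regional_mean_ct length mismatch")
            return mu
        return np.linspace(2.2, 3.0, self.n_regions)


@dataclass
class QoLEffectSpec:
    """Shape of the longitudinal MSQOL-54 PH trajectories.

    Baseline plus six follow-up visits over 48 weeks. Responders receive a
    transient rise-then-decay gain (peak ``responder_peak_gain`` points,
    returning to baseline by the final visit); non-responders drift linearly
    (default: flat).
    """

    assessment_weeks: tuple[float, ...] = (0, 8, 16, 24, 32, 40, 48)
    responder_peak_gain: float = 10.0
    responder_gain_shape: tuple[float, ...] = (0.0, 0.5, 1.0, 0.75, 0.5, 0.25, 0.0)
    nonresponder_drift: float = 0.0  # points per week
    measurement_noise_sd: float = 5.0

    def validate(self) -> None:
        w = np.asarray(self.assessment_weeks, float)
        if len(w) != len(set(w.tolist())):
            raise ValueError("duplicate assessment weeks")
        if not np.all(np.diff(w) > 0):
            raise ValueError("assessment weeks must be strictly increasing")
        if w[0] != 0:
            raise ValueError("first assessment week must be 0 (baseline)")
        if len(self.responder_gain_shape) != len(w):
            raise ValueError("gain shape length must match the visit schedule")
        if self.measurement_noise_sd < 0:
            raise ValueError("measurement_noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort: one row per subject with covariates and group label.

    Controls carry no disease duration, lesion load, EDSS or QoL baseline
    (NaN). MS subjects are assigned to sites round-robin; controls to a
    single control site. Deterministic in ``spec.seed``.
    """
    spec.validate()
    frames = []
    prefixes = {"nonresponder": "NR", "responder": "R", "control": "HC"}
    for group in GROUPS:
        n = spec.counts()[group]
        if n == 0:
            continue
        rng = rng_for(spec.seed, "cohort", group)
        mean_age, sd_age = spec.age_mean_sd[group]
        age = rng.normal(mean_age, sd_age, n)
        n_female = int(round(spec.female_fraction[group] * n))
        sex = np.zeros(n, int)
        sex[:n_female] = 1
        rng.shuffle(sex)
        row = {
            "subject_id": [f"{prefixes[group]}{i + 1:03d}" for i in range(n)],
            "group": group,
            "age": age,
            "sex": sex,
        }
        if group in MS_GROUPS:
            mean_d, sd_d = spec.disease_duration_mean_sd[group]
            mu_ll, sd_ll = spec.lesion_load_lognormal_params
            mean_q, sd_q = spec.baseline_qol_mean_sd[group]
            row["site"] = [f"site{(i % spec.n_sites) + 1}" for i in range(n)]
            row["disease_duration"] = np.clip(rng.normal(mean_d, sd_d, n), 0.5, None)
            row["lesion_load"] = rng.lognormal(mu_ll, sd_ll, n)
            edss = rng.normal(*spec.baseline_edss_mean_sd, n)
            row["baseline_edss"] = np.clip(np.round(edss * 2) / 2, 0.0, 6.5)
            row["baseline_qol"] = rng.normal(mean_q, sd_q, n)
        else:
            row["site"] = "hc"
            row["disease_duration"] = np.nan
            row["lesion_load"] = np.nan
            row["baseline_edss"] = np.nan
            row["baseline_qol"] = np.nan
        row["total_brain_volume"] = rng.normal(*spec.total_brain_volume_mean_sd, n)
        frames.append(pd.DataFrame(row))
    columns = [
        "subject_id", "group", "age", "sex", "site", "disease_duration",
        "lesion_load", "baseline_edss", "baseline_qol", "total_brain_volume",
    ]
    if not frames:
        return pd.DataFrame(columns=columns)
    return pd.concat(frames, ignore_index=True)[columns]


# ---------------------------------------------------------------------------
# factor-model machinery


def base_loading_matrix(spec: CovarianceStructureSpec) -> np.ndarray:
    """Unscaled (n_factors, n_regions) loading matrix for the chosen structure."""
    n = spec.n_regions
    if spec.structure == "single":
        return np.ones((1, n))
    if spec.structure == "blocks":
        L = np.zeros((spec.n_blocks, n))
        bounds = np.linspace(0, n, spec.n_blocks + 1).astype(int)
        for b in range(spec.n_blocks):
            L[b, bounds[b]:bounds[b + 1]] = 1.0
        return L
    # banded: global factor + one wrap-around window factor per region
    w = spec.band_halfwidth
    amp = spec.band_amplitude / math.sqrt(2 * w + 1)
    rows = [np.linspace(spec.global_profile[0], spec.global_profile[1], n)]
    for c in range(n):
        win = np.zeros(n)
        win[np.arange(c - w, c + w + 1) % n] = amp
        rows.append(win)
    return np.vstack(rows)


def implied_correlation(loadings: np.ndarray, noise_sd: float) -> np.ndarray:
    """Population inter-regional correlation of the factor model."""
    cov = loadings.T @ loadings + np.eye(loadings.shape[1]) * noise_sd**2
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def implied_median_r(loadings: np.ndarray, noise_sd: float) -> float:
    """Median off-diagonal implied correlation."""
    r = implied_correlation(loadings, noise_sd)
    iu = np.triu_indices(r.shape[0], 1)
    return float(np.median(r[iu]))


def loading_scale_for_median_r(
    target: float, loadings: np.ndarray, noise_sd: float
) -> float:
    """Solve for the scalar c with implied median r of ``c * loadings`` = target.

    The implied correlation is strictly increasing in the overall scale, so
    bisection on [0, 60] suffices; an unreachable target (e.g. a block
    structure whose cross-block correlations are zero) raises ValueError.
    """
    if target == 0:
        return 0.0
    hi = 60.0
    if implied_median_r(hi * loadings, noise_sd) < target:
        raise ValueError(
            f"target median r={target} unreachable for this factor structure"
        )
    return brentq(
        lambda c: implied_median_r(c * loadings, noise_sd) - target, 0.0, hi
    )


def group_loadings(spec: CovarianceStructureSpec) -> dict[str, np.ndarray]:
    """Scaled loading matrix per group."""
    spec.validate()
    base = base_loading_matrix(spec)
    out = {}
    for g in GROUPS:
        if spec.shared_factor_loading is not None:
            c = spec.shared_factor_loading.get(g, 0.0)
        else:
            c = loading_scale_for_median_r(
                spec.target_median_r[g], base, spec.region_noise_sd
            )
        out[g] = c * base
    return out


# ---------------------------------------------------------------------------
# regional CT


def simulate_regional_ct(
    cohort: pd.DataFrame, cov_spec: CovarianceStructureSpec, seed: int
) -> pd.DataFrame:
    """Simulate the subjects x regions cortical-thickness table (mm).

    Group-specific factor structure, covariate effects (age, sex, total brain
    volume), and — in groups with a nonzero ``ll_ct_slope`` — thinning
    proportional to (centered) log lesion load in the configured region
    subset. Values are floored at 0.5 mm (with a logged warning).
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    cohort = cohort.reset_index(drop=True)
    cov_spec.validate()
    if cov_spec.n_regions != N_REGIONS:
        raise ValueError(
            f"region count {cov_spec.n_regions} does not match the packaged "
            f"parcellation ({N_REGIONS})"
        )
    regions = region_names()
    name_to_idx = {nm: i for i, nm in enumerate(regions)}
    try:
        ll_idx = np.array([name_to_idx[nm] for nm in cov_spec.ll_affected_regions], int)
    except KeyError as exc:
        raise ValueError(f"unknown region in ll_affected_regions: {exc}") from exc

    loadings = group_loadings(cov_spec)
    mu = cov_spec.mean_ct()
    eff = cov_spec.covariate_effect_sizes

    ms = cohort["group"].isin(MS_GROUPS)
    log_ll_center = (
        float(np.log(cohort.loc[ms, "lesion_load"]).mean()) if ms.any() else 0.0
    )

    ct = np.empty((len(cohort), cov_spec.n_regions))
    for group, sub in cohort.groupby("group", sort=False):
        rng = rng_for(seed, "regional_ct", group)
        n = len(sub)
        L = loadings[group]
        f = rng.standard_normal((n, L.shape[0]))
        eps = rng.standard_normal((n, cov_spec.n_regions)) * cov_spec.region_noise_sd
        block = mu[None, :] + f @ L + eps
        covar = (
            eff.get("age", 0.0) * (sub["age"].to_numpy() - 52.0)
            + eff.get("sex", 0.0) * sub["sex"].to_numpy()
            + eff.get("volume", 0.0)
            * (sub["total_brain_volume"].to_numpy() - 1.45e6)
        )
        block += covar[:, None]
        slope = cov_spec.ll_ct_slope.get(group, 0.0)
        if slope != 0.0 and group in MS_GROUPS:
            zll = np.log(sub["lesion_load"].to_numpy()) - log_ll_center
            block[:, ll_idx] += slope * zll[:, None]
        ct[sub.index.to_numpy(), :] = block

    n_clip = int((ct < 0.5).sum())
    if n_clip:
        logger.warning("clipped %d CT values at the 0.5 mm floor", n_clip)
        ct = np.maximum(ct, 0.5)
    return pd.DataFrame(ct, index=pd.Index(cohort["subject_id"], name="subject_id"),
                        columns=regions)


# ---------------------------------------------------------------------------
# QoL trajectories


def simulate_qol(
    cohort: pd.DataFrame, qol_spec: QoLEffectSpec, seed: int
) -> pd.DataFrame:
    """Simulate long-format MSQOL-54 PH trajectories for the MS subjects.

    Responder trajectories follow baseline + peak_gain * shape(t); with zero
    noise the maximum excess over baseline is exactly ``responder_peak_gain``.
    Non-responders follow baseline + drift * week. Scores are not clipped to
    the 0-100 instrument range, so additive effects remain exact.
    """
    qol_spec.validate()
    ms = cohort[cohort["group"].isin(MS_GROUPS)]
    if ms.empty:
        raise ValueError("cohort contains no MS subjects")
    weeks = np.asarray(qol_spec.assessment_weeks, float)
    shape = np.asarray(qol_spec.responder_gain_shape, float)
    rows = []
    for group, sub in ms.groupby("group", sort=False):
        rng = rng_for(seed, "qol", group)
        base = sub["baseline_qol"].to_numpy()
        if group == "responder":
            signal = base[:, None] + qol_spec.responder_peak_gain * shape[None, :]
        else:
            signal = base[:, None] + qol_spec.nonresponder_drift * weeks[None, :]
        noise = rng.standard_normal(signal.shape) * qol_spec.measurement_noise_sd
        scores = signal + noise
        for i, sid in enumerate(sub["subject_id"]):
            for j, w in enumerate(weeks):
                rows.append((sid, w, scores[i, j]))
    return pd.DataFrame(rows, columns=["subject_id", "week", "score"])


def simulate_study(
    cohort_spec: CohortSpec | None = None,
    cov_spec: CovarianceStructureSpec | None = None,
    qol_spec: QoLEffectSpec | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a full study: (metadata, regional CT, long QoL) tables."""
    cohort_spec = cohort_spec or CohortSpec()
    cov_spec = cov_spec or CovarianceStructureSpec()
    qol_spec = qol_spec or QoLEffectSpec()
    if seed is not None:
        cohort_spec.seed = seed
    cohort = generate_cohort(cohort_spec)
    ct = simulate_regional_ct(cohort, cov_spec, seed=cohort_spec.seed)
    qol = simulate_qol(cohort, qol_spec, seed=cohort_spec.seed)
    return cohort, ct, qol
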