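"""Generator contracts: counts, determinism, factor-model calibration."""

import numpy as np
import pandas as pd
import pytest

from placebonet import (
    CohortSpec,
    CovarianceStructureSpec,
    QoLEffectSpec,
    generate_cohort,
    simulate_qol,
    simulate_regional_ct,
)
from placebonet.synthetic import (
    base_loading_matrix,
    group_loadings,
    implied_median_r,
    loading_scale_for_median_r,
)


def offdiag_median(ct_values: np.ndarray) -> float:
    r = np.corrcoef(ct_values.T)
    return float(np.median(r[np.triu_indices(r.shape[0], 1)]))


class TestGenerateCohort:
    def test_default_group_sizes_match_trial(self):
        cohort = generate_cohort(CohortSpec(seed=0))
        counts = cohort["group"].value_counts()
        assert counts["nonresponder"] == 45
        assert counts["responder"] == 43
        assert counts["control"] == 43

    def test_empty_spec_gives_empty_cohort(self):
        cohort = generate_cohort(
            CohortSpec(n_nonresponder=0, n_responder=0, n_control=0)
        )
        assert cohort.empty

    def test_controls_carry_no_disease_fields(self):
        cohort = generate_cohort(CohortSpec(seed=0))
        hc = cohort[cohort["group"] == "control"]
        assert hc[["disease_duration", "lesion_load", "baseline_qol"]].isna().all().all()
        ms = cohort[cohort["group"] != "control"]
        assert ms[["disease_duration", "lesion_load", "baseline_qol"]].notna().all().all()

    def test_sites_round_robin(self):
        cohort = generate_cohort(CohortSpec(seed=0))
        ms = cohort[cohort["group"] == "nonresponder"]
        assert set(ms["site"]) == {"site1", "site2", "site3", "site4"}

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_responder": -1},
            {"age_mean_sd": {"nonresponder": (55, -1), "responder": (53, 8.5),
                             "control": (53, 9)}},
            {"female_fraction": {"nonresponder": 1.5, "responder": 0.7,
                                 "control": 0.7}},
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_cohort(CohortSpec(**bad))

    def test_identical_seed_identical_tables(self):
        spec = CohortSpec(seed=1)
        a = generate_cohort(spec)
        b = generate_cohort(CohortSpec(seed=1))
        assert a.to_csv() == b.to_csv()
        ct_a = simulate_regional_ct(a, CovarianceStructureSpec(), seed=1)
        ct_b = simulate_regional_ct(b, CovarianceStructureSpec(), seed=1)
        assert ct_a.to_csv() == ct_b.to_csv()
        q_a = simulate_qol(a, QoLEffectSpec(), seed=1)
        q_b = simulate_qol(b, QoLEffectSpec(), seed=1)
        assert q_a.to_csv() == q_b.to_csv()


class TestFactorModel:
    def test_zero_loading_independence_limit(self):
        spec = CohortSpec(n_nonresponder=2000, n_responder=0, n_control=0, seed=5)
        cov = CovarianceStructureSpec(
            shared_factor_loading={"nonresponder": 0.0, "responder": 0.0,
                                   "control": 0.0},
            ll_ct_slope={}, covariate_effect_sizes={},
        )
        ct = simulate_regional_ct(generate_cohort(spec), cov, seed=5)
        assert abs(offdiag_median(ct.to_numpy())) < 0.05

    def test_single_factor_closed_form_median(self):
        # lambda with lambda^2/(lambda^2+sigma^2) = 0.66
        sigma = 0.12
        lam = sigma * np.sqrt(0.66 / 0.34)
        spec = CohortSpec(n_nonresponder=2000, n_responder=0, n_control=0, seed=6)
        cov = CovarianceStructureSpec(
            structure="single",
            shared_factor_loading={"nonresponder": lam},
            region_noise_sd=sigma, ll_ct_slope={}, covariate_effect_sizes={},
        )
        ct = simulate_regional_ct(generate_cohort(spec), cov, seed=6)
        assert offdiag_median(ct.to_numpy()) == pytest.approx(0.66, abs=0.05)

    def test_default_targets_hit_empirically(self, big_factor_sample):
        _, ct = big_factor_sample
        assert offdiag_median(ct.to_numpy()) == pytest.approx(0.66, abs=0.05)

    def test_median_r_monotone_in_loading(self):
        spec = CohortSpec(n_nonresponder=2000, n_responder=0, n_control=0, seed=8)
        cohort = generate_cohort(spec)
        medians = []
        for scale in (0.05, 0.12, 0.3):
            cov = CovarianceStructureSpec(
                structure="single",
                shared_factor_loading={"nonresponder": scale},
                ll_ct_slope={}, covariate_effect_sizes={},
            )
            ct = simulate_regional_ct(cohort, cov, seed=8)
            medians.append(offdiag_median(ct.to_numpy()))
        assert medians[0] < medians[1] < medians[2]

    def test_implied_correlation_solver_inverts(self):
        cov = CovarianceStructureSpec()
        base = base_loading_matrix(cov)
        for target in (0.41, 0.49, 0.66):
            c = loading_scale_for_median_r(target, base, cov.region_noise_sd)
            assert implied_median_r(c * base, cov.region_noise_sd) == pytest.approx(
                target, abs=1e-9
            )

    def test_group_loadings_ordering(self):
        scales = {
            g: np.abs(L).sum() for g, L in group_loadings(CovarianceStructureSpec()).items()
        }
        assert scales["control"] <= scales["responder"] < scales["nonresponder"]

    def test_unreachable_target_raises(self):
        cov = CovarianceStructureSpec(structure="blocks", n_blocks=4)
        with pytest.raises(ValueError, match="unreachable"):
            group_loadings(cov)

    def test_region_count_mismatch_rejected(self):
        cohort = generate_cohort(CohortSpec(seed=0))
        with pytest.raises(ValueError, match="parcellation"):
            simulate_regional_ct(
                cohort, CovarianceStructureSpec(n_regions=40), seed=0
            )

    def test_null_ll_slope_has_no_ll_association(self):
        spec = CohortSpec(n_nonresponder=800, n_responder=0, n_control=0, seed=9)
        cohort = generate_cohort(spec)
        cov = CovarianceStructureSpec(ll_ct_slope={}, covariate_effect_sizes={})
        ct = simulate_regional_ct(cohort, cov, seed=9)
        x = np.log(cohort["lesion_load"].to_numpy())
        x = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(x, ct.to_numpy(), rcond=None)
        resid = ct.to_numpy() - x @ beta
        se = np.sqrt(
            (resid**2).sum(0) / (len(x) - 2) * np.linalg.inv(x.T @ x)[1, 1]
        )
        t = beta[1] / se
        # null slopes: ~5% of regions beyond +-2 by chance
        assert (np.abs(t) > 2).mean() < 0.15


class TestQoL:
    def test_noiseless_flat_spec_constant_trajectories(self):
        cohort = generate_cohort(CohortSpec(seed=2))
        q = simulate_qol(
            cohort,
            QoLEffectSpec(responder_peak_gain=0, nonresponder_drift=0,
                          measurement_noise_sd=0),
            seed=2,
        )
        spread = q.groupby("subject_id")["score"].agg(lambda s: s.max() - s.min())
        assert (spread == 0).all()

    def test_noiseless_peak_gain_exact(self):
        cohort = generate_cohort(CohortSpec(seed=2))
        q = simulate_qol(
            cohort, QoLEffectSpec(responder_peak_gain=10, measurement_noise_sd=0),
            seed=2,
        )
        resp = cohort.loc[cohort["group"] == "responder", "subject_id"]
        for sid in resp.head(5):
            traj = q[q["subject_id"] == sid].sort_values("week")["score"].to_numpy()
            assert traj.max() - traj[0] == pytest.approx(10.0, abs=1e-12)
            assert traj[-1] == pytest.approx(traj[0], abs=1e-12)

    def test_duplicate_weeks_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            QoLEffectSpec(assessment_weeks=(0, 8, 8, 24, 32, 40, 48)).validate()

    def test_responder_gain_recovered_in_adjusted_auc(self):
        from placebonet import PlaceboResponseModel

        spec = CohortSpec(n_nonresponder=1000, n_responder=1000, n_control=0, seed=3)
        cohort = generate_cohort(spec)
        q = simulate_qol(cohort, QoLEffectSpec(), seed=3)
        res = PlaceboResponseModel(q).fit()
        t = res.table.merge(cohort[["subject_id", "group"]], on="subject_id")
        means = t.groupby("group")["residual"].mean()
        assert means["responder"] > means["nonresponder"]
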