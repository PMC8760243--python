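import numpy as np
import pandas as pd
import pytest

from placebonet import (
    CohortSpec,
    CovarianceStructureSpec,
    QoLEffectSpec,
    simulate_study,
)


@pytest.fixture(scope="session")
def study():
    """One default-size simulated study (45 NR / 43 R / 43 HC), seed 1."""
    return simulate_study(CohortSpec(seed=1), CovarianceStructureSpec(), QoLEffectSpec())


@pytest.fixture(scope="session")
def big_factor_sample():
    """n=2000 single-group CT draws for distributional checks (no covariate
    or lesion effects), with the non-responder factor structure."""
    spec = CohortSpec(
        n_nonresponder=2000, n_responder=0, n_control=0, seed=7,
    )
    cov = CovarianceStructureSpec(
        ll_ct_slope={}, covariate_effect_sizes={},
    )
    cohort, ct, _qol = _ct_only(spec, cov)
    return cohort, ct


def _ct_only(spec, cov):
    from placebonet import generate_cohort, simulate_regional_ct

    cohort = generate_cohort(spec)
    ct = simulate_regional_ct(cohort, cov, seed=spec.seed)
    return cohort, ct, None


def make_ct(spec, cov):
    """Helper: cohort + CT table only (skips QoL)."""
    return _ct_only(spec, cov)[:2]
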