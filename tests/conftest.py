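import numpy as np
import pytest

import cogclock as cc


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-participant cohort with the shipped default index specs."""
    return cc.generate_cohort(cc.CohortConfig(n_participants=60, seed=123))


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    mapping = cc.default_mapping(small_cohort.config.index_specs)
    return cc.build_quantifier_matrix(small_cohort, mapping)


def strong_signal_config(n=500, seed=0, response="linear", response_scale=12.0):
    """A cohort whose quantifiers carry a strong, low-noise age signal.

    Used for clock-recovery experiments: six time-valued indices with
    steep slopes and small trait/trial noise, plus a small latent
    acceleration so predictions are dominated by chronological age. With
    ``response="saturating"`` the age drift flattens after roughly
    ``response_scale`` years, giving a deliberately nonlinear cohort.
    """
    specs = tuple(
        cc.IndexSpec(f"RT{i}", kind="series", baseline=400 + 40 * i,
                     age_slope=8.0 + i, noise_sd=60, n_trials=12,
                     between_sd=40, summary="full",
                     response=response, response_scale=response_scale)
        for i in range(6)
    )
    return cc.CohortConfig(n_participants=n, index_specs=specs, accel_sd=2.0,
                           bio_clock_specs=(), seed=seed)
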