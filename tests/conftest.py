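"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from nafld_meta import (STAGES, SynthConfig, fit_snm, generate_cohort,
                        log_cpm, to_cpm)


@pytest.fixture(scope="session")
def small_cohort():
    """3 studies x 8 samples/stage, 80 features, default effects."""
    cfg = SynthConfig(n_features=80,
                      samples_per_study_per_stage={s: 8 for s in STAGES},
                      seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No effects at all: every feature is truth-null, no batch shifts."""
    cfg = SynthConfig(n_features=60,
                      samples_per_study_per_stage={s: 8 for s in STAGES},
                      effect_size_log2=0.0, batch_sd_log2=0.0,
                      frac_bmi_linked=0.0, bmi_confounding_slope=0.0,
                      seed=23)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_norm(small_cohort):
    profile, metadata, truth = small_cohort
    return fit_snm(log_cpm(to_cpm(profile)), metadata), metadata, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
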