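import numpy as np
import pandas as pd
import pytest

import fallrisk as fr


@pytest.fixture(scope="session")
def lexicon():
    return fr.default_lexicon()


@pytest.fixture(scope="session")
def small_cohort():
    """Default-noise cohort, small enough for fast end-to-end checks."""
    cfg = fr.CohortConfig(n_patients=600, seed=5)
    return fr.generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort: no distractor notes, so the detector must be exact."""
    cfg = fr.CohortConfig(
        n_patients=500,
        seed=7,
        note_noise=fr.NoteNoise(negated=0.0, traffic=0.0, homonym=0.0, unrelated_mean=0.5),
    )
    return fr.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_design(small_cohort):
    cfg = small_cohort.config
    return fr.assemble_design_matrix(
        small_cohort.patients,
        small_cohort.medications,
        small_cohort.diagnoses,
        small_cohort.notes,
        cfg.observation_window,
        cfg.followup_window,
    )


def toy_logistic(n=2000, p=5, beta=None, intercept=-1.0, seed=0, prevalence=0.3):
    """Independent binary predictors with a logistic outcome; returns X, y."""
    rng = np.random.default_rng(seed)
    X = (rng.random((n, p)) < prevalence).astype(float)
    beta = np.zeros(p) if beta is None else np.asarray(beta, dtype=float)
    lp = intercept + X @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
    cols = [f"x{j}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), y
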