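from __future__ import annotations

import numpy as np
import pytest

import frailmsm as fm
from frailmsm.model import intensity_matrix_from_rates


def random_generator_matrix(rng: np.random.Generator,
                            lo: float = 0.02, hi: float = 0.6) -> np.ndarray:
    """A random valid generator respecting the adjacency structure."""
    return intensity_matrix_from_rates(rng.uniform(lo, hi, size=7))


@pytest.fixture(scope="session")
def baseline_model():
    return fm.default_baseline_model()


@pytest.fixture(scope="session")
def small_panel(baseline_model):
    """Covariate-free synthetic cohort, 150 subjects, exact death times."""
    cfg = fm.SyntheticCohortConfig(n_subjects=150, seed=42,
                                   true_model=baseline_model)
    return fm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_panel_interval(baseline_model):
    cfg = fm.SyntheticCohortConfig(n_subjects=150, seed=43,
                                   true_model=baseline_model,
                                   death_convention="interval")
    return fm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_fit(baseline_model):
    """One moderately sized covariate-free fit shared across tests."""
    cfg = fm.SyntheticCohortConfig(n_subjects=2000, seed=7,
                                   true_model=baseline_model)
    panel = fm.generate_cohort(cfg)
    return panel, fm.fit_mle(panel)
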