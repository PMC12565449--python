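"""Shared fixtures: phantom cohorts and the study-scale CV run.

Heavy artefacts (the 60-case separable cohort and its 5-fold
cross-validation) are session-scoped so the evaluation-level tests share
one computation.
"""

import numpy as np
import pytest

from nodulefusion.phantom import preset_spec, generate_cases_in_memory
from nodulefusion.train_eval import (prepare_cases, reduced_config,
                                     run_cross_validation)


@pytest.fixture(scope="session")
def separable_spec():
    return preset_spec("separable")


@pytest.fixture(scope="session")
def case_g2(separable_spec):
    from nodulefusion.phantom import generate_case_full
    return generate_case_full(separable_spec, "G2", seed=7)


@pytest.fixture(scope="session")
def case_g1(separable_spec):
    from nodulefusion.phantom import generate_case_full
    return generate_case_full(separable_spec, "G1", seed=11)


@pytest.fixture(scope="session")
def cohort60(separable_spec):
    """60 separable phantoms (30 per class), seed 42, fully preprocessed."""
    raw = generate_cases_in_memory(separable_spec, 30, seed=42)
    return prepare_cases([(v, m, t.label) for v, m, t in raw]), raw


@pytest.fixture(scope="session")
def cv_result(cohort60):
    """The study-scale run: 5-fold CV of the fused classifier on the
    60-case separable cohort with the reduced configuration, seed 42."""
    cases, _ = cohort60
    cfg = reduced_config(seed=42)
    summary = run_cross_validation(cases, cfg, k=5)
    return summary, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
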