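"""Shared fixtures: the default synthetic cohort and its co-normalization,
computed once per session because several modules test recovery against the
same planted ground truth."""

import numpy as np
import pandas as pd
import pytest

from infantsep import conorm, synth
from infantsep.io import ExpressionMatrix

PIPELINE_SEED = 0


@pytest.fixture(scope="session")
def default_cohort():
    cohort, truth = synth.generate_cohort(synth.default_config(seed=PIPELINE_SEED))
    return cohort, truth


@pytest.fixture(scope="session")
def conormalized(default_cohort):
    cohort, truth = default_cohort
    params = conorm.estimate_params(cohort)
    post = conorm.apply(cohort, params)
    return cohort, truth, params, post


@pytest.fixture()
def rng():
    return np.random.default_rng(PIPELINE_SEED)


@pytest.fixture()
def small_expr(rng):
    vals = pd.DataFrame(
        rng.uniform(4, 12, size=(20, 10)),
        index=[f"G{i:03d}" for i in range(1, 21)],
        columns=[f"S{j:02d}" for j in range(1, 11)],
    )
    return ExpressionMatrix(vals)
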