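import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

from handclin import synthetic_cohort

hyp_settings.register_profile("deterministic", derandomize=True,
                              deadline=None)
hyp_settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def paper_config():
    return synthetic_cohort.paper_like_config()


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for unit tests that exercise the full pipeline."""
    return synthetic_cohort.paper_like_config(n_stroke=10, n_control=12)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synthetic_cohort.simulate_dataset(small_config, seed=7)


@pytest.fixture(scope="session")
def full_dataset(paper_config):
    return synthetic_cohort.simulate_dataset(paper_config, seed=11)


def make_trial_rows(subject_id, side, session, task, condition, values,
                    presented=None, reported=None, trial_base=0):
    """Hand-rolled long-format trial rows for table-level tests."""
    rows = []
    for k, v in enumerate(values):
        rows.append(dict(
            subject_id=subject_id, side=side, session=session, task=task,
            condition=condition, trial_idx=trial_base + k,
            presented_deg=np.nan if presented is None else presented[k],
            reported_deg=np.nan if reported is None else reported[k],
            value=v,
        ))
    return rows


@pytest.fixture
def trial_row_factory():
    return make_trial_rows


def trials_frame(rows):
    return pd.DataFrame(rows)
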