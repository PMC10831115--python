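import numpy as np
import pytest

import chemoresilience as cr
from chemoresilience.cohort import SECONDS_PER_DAY


@pytest.fixture(scope="session")
def small_cohort():
    """8-subject default-contrast cohort, shared across read-only tests."""
    return cr.generate_cohort(cr.CohortConfig(n_subjects=8, prop_nonresilient=0.5, seed=11))


@pytest.fixture(scope="session")
def study_tables():
    """Study-sized cohort (27 subjects, 14/13 split) as subject/biomarker tables."""
    return cr.simulate_tables(cr.CohortConfig(n_subjects=27, prop_nonresilient=13 / 27, seed=1))


@pytest.fixture
def make_day():
    """Factory for hand-built activity days from (state, duration) blocks.

    ``blocks`` need not cover 24 h; pass ``pad=True`` to fill the remainder
    with LYING so the day satisfies the full-day invariant.
    """

    def _make(blocks, step_times=(), pad=False, subject_id="T01", day_index=1):
        states = np.concatenate([np.full(int(d), s, dtype=np.int8) for s, d in blocks])
        if pad and states.size < SECONDS_PER_DAY:
            states = np.concatenate(
                [states, np.full(SECONDS_PER_DAY - states.size, cr.cohort.LYING, dtype=np.int8)]
            )
        return cr.ActivityDay.from_dense(
            subject_id, day_index, states, np.asarray(step_times, dtype=float)
        )

    return _make
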