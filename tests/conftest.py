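"""Shared fixtures: small synthetic cohorts and a trained tiny task.

Everything is generated programmatically and seeded, so the suite needs no
data files.
"""

import numpy as np
import pytest

from boldcast import (RoiTimeSeries, SyntheticConfig, VmdConfig,
                      decompose_cohort, generate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects, 4 regions, 300 timepoints, two low-frequency bands."""
    return generate_cohort(SyntheticConfig(n_subjects=3, m=4, T=300,
                                           noise_sigma=0.15, seed=11))


@pytest.fixture(scope="session")
def small_decomp(small_cohort):
    return decompose_cohort(small_cohort, VmdConfig(K=2), f_max_hz=0.05)


@pytest.fixture()
def toy_series():
    rng = np.random.default_rng(5)
    return RoiTimeSeries("toy", ["A", "B", "C"],
                         rng.standard_normal((3, 50)), 0.72)
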