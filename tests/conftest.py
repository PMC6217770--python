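"""Shared fixtures: one synthetic normal-weight cohort and its fitted chart.

The heavy objects (5,000-woman cohort, its GAMLSS fit, the exported grid)
are session-scoped so the fit runs once for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from gwgcharts.charts import export_parameter_grid
from gwgcharts.pipeline import prepare_group
from gwgcharts.preprocess import BMIGroup
from gwgcharts.smooth_fit import fit_gamlss_bct
from gwgcharts.synthetic_data import SyntheticConfig, default_truth, simulate_cohort

RECOVERY_SEED = 11
RECOVERY_N = 5000


@pytest.fixture(scope="session")
def normal_truth():
    return default_truth(BMIGroup.NORMAL)


@pytest.fixture(scope="session")
def normal_cohort():
    """Default synthetic normal-weight cohort, n = 5,000, fixed seed."""
    config = SyntheticConfig(n_women=RECOVERY_N, seed=RECOVERY_SEED)
    return simulate_cohort(config, groups=[BMIGroup.NORMAL])


@pytest.fixture(scope="session")
def normal_data(normal_cohort):
    """Nudged, offset gain records of the normal-weight cohort."""
    return prepare_group(normal_cohort, BMIGroup.NORMAL, nudge_seed=RECOVERY_SEED)


@pytest.fixture(scope="session")
def normal_chart(normal_data):
    """Default-spec BCT chart fitted to the normal-weight cohort."""
    return fit_gamlss_bct(normal_data, nudge_seed=RECOVERY_SEED)


@pytest.fixture(scope="session")
def normal_grid(normal_chart):
    return export_parameter_grid(normal_chart)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
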