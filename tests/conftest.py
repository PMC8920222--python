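import numpy as np
import pytest

import radsen as rs


@pytest.fixture(scope="session")
def noise_free_series():
    """All study series generated without noise, keyed by (condition, endpoint)."""
    design = rs.default_study_design(noise_cv=0.0, seed=0)
    return {(s.condition, s.endpoint): s for s in rs.generate_timeseries(design)}


@pytest.fixture
def study_conditions():
    """The four proteomics time points forming the two isodose comparisons."""
    return [
        rs.ExposureCondition("1.4mGyh_10wk", 1.4, 10),
        rs.ExposureCondition("4.1mGyh_3wk", 4.1, 3),
        rs.ExposureCondition("2.4mGyh_10wk", 2.4, 10),
        rs.ExposureCondition("4.1mGyh_6wk", 4.1, 6),
    ]


@pytest.fixture
def growth_rate_points():
    """Fitted growth rate r vs dose rate, with reported SDs."""
    return [
        rs.RatePoint(0.0, 1.450, 0.022),
        rs.RatePoint(1.4, 1.164, 0.015),
        rs.RatePoint(2.4, 1.052, 0.041),
        rs.RatePoint(4.1, 0.960, 0.043),
    ]


@pytest.fixture
def senescence_rate_points():
    """Fitted senescence rate p vs dose rate, with reported SDs."""
    return [
        rs.RatePoint(0.0, 0.184, 0.027),
        rs.RatePoint(1.4, 0.215, 0.017),
        rs.RatePoint(2.4, 0.252, 0.037),
        rs.RatePoint(4.1, 0.532, 0.102),
    ]
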