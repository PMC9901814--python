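import numpy as np
import pandas as pd
import pytest

from paleoscape import CalibrationCurve, simulate_calibration_curve


@pytest.fixture(scope="session")
def identity_curve():
    """Curve with mu(t) = t and negligible curve error."""
    grid = np.arange(0.0, 20_000.0, 10.0)
    return CalibrationCurve(grid, grid.copy(), np.full(grid.size, 1e-6))


@pytest.fixture(scope="session")
def wiggly_curve():
    return simulate_calibration_curve(cal_min=0, cal_max=30_000, step=20, seed=42)


@pytest.fixture()
def sample_rows():
    """Three well-formed records covering the mandatory schema."""
    return pd.DataFrame(
        {
            "sample_id": ["a1", "a2", "a3"],
            "site_id": ["s1", "s1", "s2"],
            "latitude": [45.0, 45.0, 50.5],
            "longitude": [5.0, 5.0, 12.25],
            "taxon": ["Equus sp.", "Equus sp.", "Cervus elaphus"],
            "element": ["bone", "bone", "bone"],
            "age_class": ["adult", "adult", "adult"],
            "d15N": [4.2, 5.1, 2.9],
            "cn_atomic": [3.2, 3.1, 3.4],
            "taxon_certain": [True, True, True],
            "dating_basis": ["direct", "direct", "context"],
            "c14_age": [12000.0, 12500.0, np.nan],
            "c14_error": [60.0, 55.0, np.nan],
            "context_age_bin": [np.nan, np.nan, "LGM"],
        }
    )


@pytest.fixture()
def small_aggregates():
    rng = np.random.default_rng(5)
    n = 12
    return pd.DataFrame(
        {
            "site_id": [f"S{i}" for i in range(n)],
            "lon": rng.uniform(0, 10, n),
            "lat": rng.uniform(0, 10, n),
            "n_obs": rng.integers(1, 6, n),
            "mean_d15N": rng.normal(4, 2, n),
            "var_d15N": rng.uniform(0.5, 3.0, n),
        }
    )
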