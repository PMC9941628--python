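import numpy as np
import pandas as pd
import pytest

from sanqitrace.spectra import SpectrumSeries
from sanqitrace.synthetic import ClimateSimConfig, SpectraSimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spectra_config():
    """A few coarse-grid samples: fast but structurally faithful."""
    return SpectraSimConfig(n_per_class=4, resolution=40.0, seed=7)


@pytest.fixture
def noiseless_climate():
    cfg = ClimateSimConfig(n_samples=60, noise_sd=0.0, seed=3)
    from sanqitrace.synthetic import simulate_climate_table

    return simulate_climate_table(cfg)


@pytest.fixture
def series(rng):
    grid = np.arange(9000.0, 3999.0, -500.0)
    inten = rng.normal(size=(5, grid.size))
    return SpectrumSeries(grid, inten, {"sample_id": "s1"})


@pytest.fixture
def table1_groups():
    """Per-origin tables whose per-saponin means equal printed content
    values (two identical rows per group, so means are exact)."""
    printed = {
        "DDB": (8.26, 31.28, 19.95, 6.71),
        "DZ": (11.01, 36.67, 26.43, 12.01),
        "XC": (15.41, 53.25, 41.83, 20.64),
        "QB": (7.73, 34.52, 31.62, 14.28),
    }
    rows = []
    for g, (a, b, c, d) in printed.items():
        for _ in range(2):
            rows.append(
                {"group": g, "NG-R1": a, "G-Rg1": b, "G-Rb1": c, "G-Rd": d}
            )
    return pd.DataFrame(rows), printed
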