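import numpy as np
import pandas as pd
import pytest

from cdtox.kinetics_net import PeakTable
from cdtox.simdata import SimConfig, simulate_peak_table, simulate_viability, viability_table


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(seed=11, n_genes=120, n_products=120)


@pytest.fixture(scope="session")
def peak_study(small_cfg):
    """Peak table + truth + viability, generated once per session."""
    peaks_df, truth = simulate_peak_table(small_cfg)
    pt = PeakTable(peaks_df,
                   {f"i{t:g}": t for t in small_cfg.timepoints}, "control")
    od, _ = simulate_viability(small_cfg)
    return pt, truth, viability_table(od)


@pytest.fixture()
def rht_concentrations() -> np.ndarray:
    return np.sort(np.array([300.0 / 5**i for i in range(7)]))
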