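import numpy as np
import pytest

from chipdecay.io_formats import CoverageTrack
from chipdecay.synthetic_data import SimulationConfig, simulate_timecourse, simulate_tracks


@pytest.fixture(scope="session")
def small_noiseless():
    """30-peak noiseless experiment: (config, sample sheet, counts, truth)."""
    cfg = SimulationConfig(seed=101, n_peaks=30, noise="none")
    sample_sheet, counts, truth = simulate_timecourse(cfg)
    return cfg, sample_sheet, counts, truth


@pytest.fixture(scope="session")
def small_noisy():
    """60-peak negative-binomial experiment with tracks."""
    cfg = SimulationConfig(seed=202, n_peaks=60, noise="negbin")
    sample_sheet, counts, truth = simulate_timecourse(cfg)
    h3, netseq, transcripts, taf1 = simulate_tracks(truth, cfg)
    return cfg, sample_sheet, counts, truth, h3, netseq, transcripts, taf1


@pytest.fixture()
def constant_track():
    """Constant coverage 2.0 over one 10-kb chromosome."""
    return CoverageTrack({"chrI": (np.array([0]), np.array([10_000]), np.array([2.0]))})
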