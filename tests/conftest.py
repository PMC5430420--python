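import numpy as np
import pytest

from ovicnv import qc
from ovicnv.core import MarkerMap
from ovicnv.synthetic_data import SimulationConfig, simulate_signals, simulate_truth


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-sample synthetic cohort at the stated recovery conditions."""
    cfg = SimulationConfig(seed=7, n_samples=20)
    truth, marker_map, genome = simulate_truth(cfg)
    signals = simulate_signals(truth, marker_map, cfg)
    marker_map = qc.compute_pfb(signals, marker_map)
    return {
        "config": cfg,
        "truth": truth,
        "marker_map": marker_map,
        "genome": genome,
        "signals": signals,
    }


@pytest.fixture
def tiny_map():
    """Three markers on one chromosome, flat PFB 0.5."""
    return MarkerMap(
        ids=["m1", "m2", "m3"],
        chrom=["1", "1", "1"],
        pos=[100, 200, 300],
        pfb=[0.5, 0.5, 0.5],
    )
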