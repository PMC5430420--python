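"""Shared cohort construction for the numbered analysis drivers.

Every driver regenerates the same deterministic synthetic cohort from the
library (a few seconds), so each can be run standalone and in any order.
"""

from pathlib import Path

from ovicnv import qc
from ovicnv.synthetic_data import SimulationConfig, simulate_signals, simulate_truth

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

SEED = 2024
COHORT_CONFIG = SimulationConfig(seed=SEED)  # 48 samples, 75 Mb genome


def get_cohort(config: SimulationConfig = COHORT_CONFIG):
    truth, marker_map, genome = simulate_truth(config)
    signals = simulate_signals(truth, marker_map, config)
    marker_map = qc.compute_pfb(signals, marker_map)
    return {
        "config": config,
        "truth": truth,
        "marker_map": marker_map,
        "genome": genome,
        "signals": signals,
    }


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
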