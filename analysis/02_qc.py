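#!/usr/bin/env python
"""Sample- and marker-level quality control on the synthetic cohort.

Adds two deliberately corrupted samples (noisy LRR; BAF drift) to show the
filters firing, then runs marker QC (missingness / MAF / Hardy-Weinberg).
"""

import dataclasses

import numpy as np
import pandas as pd

from common import RESULTS, ensure_dirs, get_cohort
from ovicnv import qc
from ovicnv.core import SampleSignal
from ovicnv.synthetic_data import SimulationConfig, simulate_signals


def corrupted_samples(cohort):
    base_cfg = cohort["config"]
    noisy_cfg = dataclasses.replace(base_cfg, seed=base_cfg.seed + 1,
                                    n_samples=1, lrr_sd=0.45)
    drift_cfg = dataclasses.replace(base_cfg, seed=base_cfg.seed + 2,
                                    n_samples=1, baf_drift=0.03)
    mm = cohort["marker_map"]
    (noisy,) = simulate_signals([], mm, noisy_cfg)
    (drift,) = simulate_signals([], mm, drift_cfg)
    return [
        SampleSignal("BAD_noisy_lrr", noisy.lrr, noisy.baf, noisy.genotype),
        SampleSignal("BAD_baf_drift", drift.lrr, drift.baf, drift.genotype),
    ]


def main():
    ensure_dirs()
    cohort = get_cohort()
    mm = cohort["marker_map"]
    signals = cohort["signals"] + corrupted_samples(cohort)

    rows = []
    for sig in signals:
        r = qc.compute_sample_qc(sig, mm)
        rows.append(
            {"sample": r.sample, "call_rate": round(r.call_rate, 4),
             "sd_lrr": round(r.sd_lrr, 4), "baf_drift": round(r.baf_drift, 4),
             "waviness": round(r.waviness, 4), "pass": r.passed}
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "02_sample_qc.tsv", sep="\t", index=False)
    n_fail = int((~df["pass"]).sum())
    print(f"sample QC: {len(df) - n_fail}/{len(df)} pass "
          f"({n_fail} removed: {', '.join(df.loc[~df['pass'], 'sample'])})")

    geno = np.vstack([s.genotype for s in cohort["signals"]])
    marker_res = qc.compute_marker_qc(geno, mm)
    passed = sum(1 for r in marker_res if r.passed)
    fail_reasons = {
        "missingness": sum(1 for r in marker_res if r.missingness > qc.MISSINGNESS_MAX),
        "maf": sum(1 for r in marker_res if r.maf < qc.MAF_MIN),
        "hwe": sum(1 for r in marker_res if r.hwe_p < r.hwe_threshold),
    }
    pd.DataFrame([{"n_markers": len(marker_res), "n_pass": passed, **fail_reasons}]).to_csv(
        RESULTS / "02_marker_qc_summary.tsv", sep="\t", index=False
    )
    print(f"marker QC: {passed}/{len(marker_res)} pass "
          f"(failures by reason: {fail_reasons})")


if __name__ == "__main__":
    main()
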