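#!/usr/bin/env python
"""Generate the synthetic cohort and write its on-disk artifacts.

Produces a 48-sample cohort on a 75-Mb, 5-autosome genome with ~10:1
loss:gain odds, writes the signal table / PFB / truth files (large,
regenerable -> scratch/) and a small truth summary (results/).
"""

import json

import pandas as pd

from common import RESULTS, SCRATCH, ensure_dirs, get_cohort
from ovicnv import io_formats as iof


def main():
    ensure_dirs()
    cohort = get_cohort()
    truth, mm = cohort["truth"], cohort["marker_map"]

    out = SCRATCH / "synthetic"
    out.mkdir(exist_ok=True)
    iof.write_signal_table(out / "signals.tsv", mm, cohort["signals"])
    iof.write_pfb(out / "markers.pfb", mm)
    pd.DataFrame(
        [
            {"sample": t.sample, "chr": t.chrom, "start": t.start,
             "end": t.end, "cn": t.cn, "state": t.state}
            for t in truth
        ]
    ).to_csv(out / "truth.tsv", sep="\t", index=False)

    n_loss = sum(1 for t in truth if t.state == "loss")
    summary = {
        "n_samples": cohort["config"].n_samples,
        "n_markers": len(mm),
        "n_truth_cnvs": len(truth),
        "n_loss": n_loss,
        "n_gain": len(truth) - n_loss,
        "loss_fraction": round(n_loss / len(truth), 4),
        "mean_length_kb": round(
            sum(t.length for t in truth) / len(truth) / 1e3, 1
        ),
    }
    (RESULTS / "01_truth_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"cohort: {summary['n_samples']} samples, {summary['n_markers']} markers")
    print(
        f"injected {summary['n_truth_cnvs']} CNVs "
        f"({summary['n_loss']} losses / {summary['n_gain']} gains, "
        f"loss fraction {summary['loss_fraction']})"
    )
    print(f"signal table, PFB and truth written under {out}")


if __name__ == "__main__":
    main()
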