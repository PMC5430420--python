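#!/usr/bin/env python
"""Merge the per-sample CNV calls into CNVRs and summarise their distribution.

Reads the rawcnv written by 03_call_cnvs.py (regenerating it if absent),
applies the 1-bp union merge and the 1-kb length filter, and reports state
counts, the carrier-frequency range, the length histogram, per-chromosome
coverage/spacing, and the count-vs-length regression.
"""

import json
import subprocess
import sys
from pathlib import Path

from common import RESULTS, ensure_dirs, get_cohort
from ovicnv import io_formats as iof
from ovicnv.cnvr_pipeline import merge_to_cnvrs, summarize


def main():
    ensure_dirs()
    rawcnv = RESULTS / "03_calls.rawcnv"
    if not rawcnv.exists():
        subprocess.run(
            [sys.executable, str(Path(__file__).parent / "03_call_cnvs.py")],
            check=True,
        )
    calls = iof.read_rawcnv(rawcnv)
    cohort = get_cohort()

    cnvrs = merge_to_cnvrs(calls, cohort_size=cohort["config"].n_samples)
    iof.write_cnvr_table(RESULTS / "04_cnvrs.tsv", cnvrs)

    summ = summarize(cnvrs, cohort["genome"])
    summ.table.to_csv(RESULTS / "04_chrom_summary.tsv", sep="\t", index=False)

    states = {s: sum(1 for r in cnvrs if r.state == s) for s in ("loss", "gain", "both")}
    freqs = [r.frequency for r in cnvrs]
    genome_len = cohort["genome"].total_length()
    report = {
        "n_cnvs": len(calls),
        "n_cnvrs": len(cnvrs),
        "states": states,
        "frequency_range_pct": [round(min(freqs), 1), round(max(freqs), 1)],
        "genome_coverage_pct": round(
            100 * sum(r.length for r in cnvrs) / genome_len, 2
        ),
        "length_histogram_kb": {
            k: round(v, 3) for k, v in summ.length_histogram.items()
        },
        "count_vs_length_r2": round(summ.r_squared, 3),
    }
    (RESULTS / "04_summary.json").write_text(json.dumps(report, indent=2))
    print(f"{report['n_cnvs']} CNVs merged into {report['n_cnvrs']} CNVRs "
          f"({states['loss']} loss / {states['gain']} gain / {states['both']} both)")
    print(f"carrier frequency {report['frequency_range_pct'][0]}-"
          f"{report['frequency_range_pct'][1]}%, "
          f"genome coverage {report['genome_coverage_pct']}%, "
          f"count~length R^2 {report['count_vs_length_r2']}")


if __name__ == "__main__":
    main()
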