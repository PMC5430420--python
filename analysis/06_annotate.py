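#!/usr/bin/env python
"""Overlap the CNVRs with synthetic genes, QTLs and assembly gaps; run a
hypergeometric enrichment over synthetic gene sets.

All annotation tracks here are synthetic stand-ins generated on the same
75-Mb genome; the overlap and enrichment machinery is what real tracks
would go through.
"""

import json

import numpy as np

from common import RESULTS, SEED, ensure_dirs, get_cohort
from ovicnv import annotation as ann
from ovicnv import io_formats as iof
from ovicnv.core import IntervalRecord
from ovicnv.cnvr_pipeline import merge_to_cnvrs
from ovicnv.cnv_caller import viterbi_segment


def synthetic_tracks(genome, rng):
    genes, qtls, gaps = [], [], []
    gid = 0
    for chrom, length in genome.lengths.items():
        for _ in range(int(length / 1e6 * 12)):  # ~12 genes / Mb
            s = int(rng.integers(1, length - 60_000))
            genes.append(
                IntervalRecord(chrom, s, s + int(rng.integers(2_000, 60_000)),
                               f"GENE{gid:04d}", "gene")
            )
            gid += 1
        for cat in ("meat", "milk", "wool", "reproduction"):
            for _ in range(int(length / 1e6)):
                s = int(rng.integers(1, length - 500_000))
                qtls.append(
                    IntervalRecord(chrom, s, s + int(rng.integers(100_000, 500_000)),
                                   f"QTL_{cat}_{len(qtls)}", cat)
                )
        for _ in range(int(length / 1e6 * 2)):
            s = int(rng.integers(1, length - 10_000))
            gaps.append(
                IntervalRecord(chrom, s, s + int(rng.integers(200, 10_000)),
                               f"gap{len(gaps)}", "gap")
            )
    return genes, qtls, gaps


def main():
    ensure_dirs()
    rng = np.random.default_rng([SEED, 6])
    cohort = get_cohort()
    mm = cohort["marker_map"]
    calls = []
    for sig in cohort["signals"]:
        calls.extend(viterbi_segment(sig, mm))
    cnvrs = merge_to_cnvrs(calls, cohort_size=cohort["config"].n_samples)

    genes, qtls, gaps = synthetic_tracks(cohort["genome"], rng)
    iof.write_bed_like(RESULTS / "06_genes.synthetic.bed", genes)

    gene_res = ann.overlap_features(cnvrs, genes)
    qtl_res = ann.overlap_features(cnvrs, qtls, gene_category="__none__")
    gap_res = ann.gap_overlap(calls, gaps, min_gap=1_000)

    hit_genes = sorted({f.id for hits in gene_res.hits for f in hits})
    universe = [g.id for g in genes]
    # synthetic gene sets: one enriched set seeded with CNVR-hit genes
    set_rng = np.random.default_rng([SEED, 7])
    sets = {
        f"random_set_{i}": list(set_rng.choice(universe, size=40, replace=False))
        for i in range(5)
    }
    seed_hits = hit_genes[:30] if len(hit_genes) >= 30 else hit_genes
    sets["cnv_biased_set"] = list(
        dict.fromkeys(seed_hits + list(set_rng.choice(universe, size=10, replace=False)))
    )
    enrich_df = ann.enrich(hit_genes, sets, universe)
    enrich_df.to_csv(RESULTS / "06_enrichment.tsv", sep="\t", index=False)

    report = {
        "n_cnvrs": len(cnvrs),
        "genic": gene_res.genic_count,
        "intergenic": gene_res.intergenic_count,
        "genic_pct": round(100 * gene_res.genic_count / len(cnvrs), 1),
        "qtl_category_counts": qtl_res.category_counts,
        "gap_overlap": gap_res,
        "top_enriched_set": enrich_df.iloc[0]["set"],
        "top_enrichment_p": float(enrich_df.iloc[0]["p_value"]),
    }
    (RESULTS / "06_annotation.json").write_text(json.dumps(report, indent=2))
    print(f"{report['genic']}/{report['n_cnvrs']} CNVRs genic "
          f"({report['genic_pct']}%); QTL hits by category: "
          f"{report['qtl_category_counts']}")
    print(f"calls overlapping >=1-kb gaps: {gap_res['n_calls_overlapping']}"
          f"/{gap_res['n_calls']} (touching {gap_res['n_gaps_hit']} gaps)")
    print(f"most enriched gene set: {report['top_enriched_set']} "
          f"(P = {report['top_enrichment_p']:.2e})")


if __name__ == "__main__":
    main()
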