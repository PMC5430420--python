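"""Readers and writers for the on-disk dialects the pipeline touches.

Dialects supported:

* GenomeStudio-style "final report" signal tables: tab-delimited, columns
  ``Name``, ``Chr``, ``Position`` plus per-sample ``<id>.Log R Ratio``,
  ``<id>.B Allele Freq`` and optional ``<id>.GType``.
* PFB tables: ``Name``, ``Chr``, ``Position``, ``PFB``.
* PennCNV "rawcnv" call lists, e.g.
  ``chr1:1000-2000 numsnp=5 length=1001 state2,cn=1 sampleA startsnp=r1 endsnp=r5``.
* BED-like feature files (0-based half-open on disk, converted to the
  internal 1-based inclusive convention on read and back on write).
* Study CNVR tables: TSV with study, chr, start, end, state columns.

Internal coordinates are always 1-based inclusive.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import (
    CNVCall,
    CNVR,
    IntervalRecord,
    MarkerMap,
    Region,
    SampleSignal,
    StudyDataset,
    normalize_chrom,
)

__all__ = [
    "read_signal_table",
    "write_signal_table",
    "read_pfb",
    "write_pfb",
    "read_rawcnv",
    "write_rawcnv",
    "read_bed_like",
    "write_bed_like",
    "read_study_table",
    "write_study_table",
    "write_cnvr_table",
]

_LRR_SUFFIX = ".Log R Ratio"
_BAF_SUFFIX = ".B Allele Freq"
_GT_SUFFIX = ".GType"
_MISSING_GT = "NC"


def read_signal_table(path, marker_map: MarkerMap) -> list[SampleSignal]:
    """Read a final-report signal table into SampleSignals aligned to *marker_map*.

    Rows may appear in any order; they are re-aligned to the marker map.
    Markers present in the map but absent from the file are recorded as
    missing (NaN LRR/BAF, ``NC`` genotype), never as zero.
    """
    df = pd.read_csv(path, sep="\t", dtype={"Name": str, "Chr": str})
    for col in ("Name", "Chr", "Position"):
        if col not in df.columns:
            raise ValueError(f"signal table missing required column {col!r}")
    idx = marker_map.id_index()
    rows = np.empty(len(df), dtype=np.int64)
    for i, name in enumerate(df["Name"]):
        if name not in idx:
            raise ValueError(f"unknown marker id {name!r} in {path}")
        rows[i] = idx[name]

    samples = []
    for col in df.columns:
        if col.endswith(_LRR_SUFFIX):
            samples.append(col[: -len(_LRR_SUFFIX)])
    out = []
    n = len(marker_map)
    for s in samples:
        lrr_col, baf_col = s + _LRR_SUFFIX, s + _BAF_SUFFIX
        if baf_col not in df.columns:
            raise ValueError(f"sample {s!r} has LRR but no BAF column")
        lrr = np.full(n, np.nan)
        baf = np.full(n, np.nan)
        for col, dest in ((lrr_col, lrr), (baf_col, baf)):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
            if bad.any():
                line = int(bad.idxmax()) + 2  # 1-based, after header
                raise ValueError(
                    f"non-numeric value {df[col][bad.idxmax()]!r} in column "
                    f"{col!r} at line {line}"
                )
            dest[rows] = vals.to_numpy()
        gt = None
        gt_col = s + _GT_SUFFIX
        if gt_col in df.columns:
            gt = np.full(n, _MISSING_GT, dtype=object)
            gt[rows] = df[gt_col].fillna(_MISSING_GT).to_numpy()
        out.append(SampleSignal(sample=s, lrr=lrr, baf=baf, genotype=gt))
    return out


def write_signal_table(path, marker_map: MarkerMap, signals: Iterable[SampleSignal]):
    """Write SampleSignals to the final-report dialect read_signal_table parses."""
    data = {
        "Name": marker_map.ids,
        "Chr": marker_map.chrom,
        "Position": marker_map.pos,
    }
    for sig in signals:
        if len(sig) != len(marker_map):
            raise ValueError(f"signal {sig.sample} not aligned to marker map")
        data[sig.sample + _LRR_SUFFIX] = np.round(sig.lrr, 6)
        data[sig.sample + _BAF_SUFFIX] = np.round(sig.baf, 6)
        if sig.genotype is not None:
            data[sig.sample + _GT_SUFFIX] = sig.genotype
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_pfb(path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype={"Name": str, "Chr": str})
    need = {"Name", "Chr", "Position", "PFB"}
    if not need.issubset(df.columns):
        raise ValueError(f"PFB table must have columns {sorted(need)}")
    return MarkerMap(df["Name"], df["Chr"], df["Position"], df["PFB"])


def write_pfb(path, marker_map: MarkerMap):
    pd.DataFrame(
        {
            "Name": marker_map.ids,
            "Chr": marker_map.chrom,
            "Position": marker_map.pos,
            "PFB": np.round(marker_map.pfb, 6),
        }
    ).to_csv(path, sep="\t", index=False)


_RAWCNV_RE = re.compile(
    r"^(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>[\d,]+)\s+length=(?P<length>[\d,]+)\s+"
    r"state(?P<state>\d+),cn=(?P<cn>\d+)\s+(?P<sample>\S+)"
    r"(?:\s+startsnp=(?P<startsnp>\S+))?(?:\s+endsnp=(?P<endsnp>\S+))?"
)


def read_rawcnv(path) -> list[CNVCall]:
    """Parse a PennCNV-dialect rawcnv file into CNVCalls.

    The redundant ``length=`` field is cross-checked against
    ``end - start + 1``; on mismatch a warning is emitted and the
    coordinates are trusted.
    """
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            m = _RAWCNV_RE.match(line)
            if m is None:
                raise ValueError(f"malformed rawcnv line {lineno}: {line!r}")
            start, end = int(m["start"]), int(m["end"])
            length = int(m["length"].replace(",", ""))
            if length != end - start + 1:
                warnings.warn(
                    f"line {lineno}: length field {length} != end-start+1 "
                    f"({end - start + 1}); trusting coordinates"
                )
            calls.append(
                CNVCall(
                    sample=m["sample"],
                    chrom=normalize_chrom(m["chrom"]),
                    start=start,
                    end=end,
                    cn=int(m["cn"]),
                    num_snps=int(m["numsnp"].replace(",", "")),
                )
            )
    return calls


def write_rawcnv(path, calls: Iterable[CNVCall]):
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"chr{c.chrom}:{c.start}-{c.end} numsnp={c.num_snps} "
                f"length={c.length} state{c.cn + 1 if c.cn < 2 else c.cn + 2},"
                f"cn={c.cn} {c.sample}\n"
            )


def read_bed_like(path) -> list[IntervalRecord]:
    """Read a BED-like file (0-based half-open) into 1-based inclusive records.

    Columns: chrom, start, end, optional id, optional category.
    Conversion: internal start = BED start + 1, internal end = BED end.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line {lineno} has fewer than 3 columns")
            chrom, bed_start, bed_end = parts[0], int(parts[1]), int(parts[2])
            start, end = bed_start + 1, bed_end
            if start > end:
                raise ValueError(
                    f"BED line {lineno}: empty/invalid interval after conversion "
                    f"([{start},{end}] 1-based)"
                )
            records.append(
                IntervalRecord(
                    chrom=chrom,
                    start=start,
                    end=end,
                    id=parts[3] if len(parts) > 3 else "",
                    category=parts[4] if len(parts) > 4 else "",
                )
            )
    return sorted(records, key=lambda r: (r.chrom, r.start, r.end))


def write_bed_like(path, records: Iterable[IntervalRecord]):
    """Write IntervalRecords back to BED (exact inverse of read_bed_like)."""
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: (r.chrom, r.start, r.end)):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.id}\t{r.category}\n")


def read_study_table(path, label: Optional[str] = None) -> list[StudyDataset]:
    """Read a CNVR study table (TSV: study, chr, start, end, state).

    Returns one StudyDataset per distinct study label, sorted by
    (chromosome, start).  An empty file yields an empty list.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"study": str, "chr": str, "state": str})
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    need = {"study", "chr", "start", "end"}
    if not need.issubset(df.columns):
        raise ValueError(f"study table must have columns {sorted(need)}")
    out = []
    for study, grp in df.groupby("study", sort=True):
        if label is not None and study != label:
            continue
        regions = []
        for _, row in grp.iterrows():
            if row["start"] > row["end"]:
                raise ValueError(
                    f"study {study}: start {row['start']} > end {row['end']}"
                )
            state = row.get("state")
            regions.append(
                Region(
                    chrom=row["chr"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    state=None if pd.isna(state) else str(state),
                )
            )
        out.append(StudyDataset(label=str(study), regions=regions))
    return out


def write_study_table(path, datasets: Iterable[StudyDataset]):
    rows = []
    for ds in datasets:
        for r in ds.regions:
            rows.append(
                {
                    "study": ds.label,
                    "chr": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "state": r.state if r.state is not None else "",
                }
            )
    pd.DataFrame(rows, columns=["study", "chr", "start", "end", "state"]).to_csv(
        path, sep="\t", index=False
    )


def write_cnvr_table(path, cnvrs: Iterable[CNVR]):
    rows = [
        {
            "chr": r.chrom,
            "start": r.start,
            "end": r.end,
            "length": r.length,
            "state": r.state,
            "n_cnvs": r.n_cnvs,
            "n_samples": len(r.samples),
            "frequency_pct": round(r.frequency, 4),
            "samples": ",".join(r.samples),
        }
        for r in cnvrs
    ]
    pd.DataFrame(
        rows,
        columns=[
            "chr", "start", "end", "length", "state",
            "n_cnvs", "n_samples", "frequency_pct", "samples",
        ],
    ).to_csv(path, sep="\t", index=False)
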