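# ovicnv

Genome-wide detection and comparison of copy-number variants (CNVs) from
SNP-array intensity data, written for livestock (ovine) genomics but generic
over any autosomal genome. The package reimplements the classic
high-density-array CNV workflow as a tested, reusable library with a fully
synthetic test bed:

1. **Quality control** — per-sample call rate ≥ 90%, SD(LRR) < 0.30,
   BAF drift < 0.01, waviness factor < 0.05; per-marker missingness ≤ 10%,
   MAF ≥ 0.05 and a Bonferroni-adjusted Hardy–Weinberg chi-square filter
   (raw P ≥ 10⁻⁵ / #markers).
2. **CNV calling** — a five-state hidden Markov model over copy numbers
   0–4. Per marker the emission combines a Gaussian Log R Ratio (LRR) term,
   mean μ_cn ∈ {−3.5, −0.66, 0, +0.40, +0.68}, with a B-allele-frequency
   (BAF) mixture over the genotype clusters each copy number allows,
   weighted Binomial(cn, PFB) over B-allele dosage (PFB = population
   frequency of the B allele, the per-marker mean BAF). Transitions decay
   with inter-marker distance, P(stay) = 1 − (1 − p)·(1 − e^(−d/d₀)) with
   p = 0.999, d₀ = 100 kb; Viterbi decoding in log space; calls need ≥ 3 SNPs.
3. **CNVR construction** — copy-number-variable regions are the transitive
   union of calls overlapping by ≥ 1 bp across samples; merged regions
   < 1 kb are dropped; state is loss/gain/both; frequency is the percentage
   of the cohort carrying an overlapping CNV.
4. **Cross-study comparison** — novelty classification against published
   CNVR tables, a composite union set, PCA and average-linkage/Jaccard
   clustering of the study×region presence matrix, and breed-specific
   regions (≥ 100 kb, private to one dataset).
5. **Annotation** — ≥ 1 bp overlap with genes/QTLs/assembly gaps and
   hypergeometric gene-set enrichment with Benjamini–Hochberg correction.
6. **qPCR validation arithmetic** — the 2^(−ΔΔCT) method with the
   diploid-normalized ratio NR = 2·2^(−ΔΔCT): NR ≈ 2 normal, ≈ 1 one copy
   lost, ≈ 0 both lost, ≳ 3 gained.

A synthetic-data module generates genomes, marker maps, ground-truth CNVs
(with the ~10:1 loss:gain excess typical of array studies), LRR/BAF signals
and multi-study CNVR tables, so the whole pipeline runs and is validated
without any external data.

## Worked example

The numbered drivers under `analysis/` run the pipeline end-to-end on the
default synthetic cohort (48 samples, 5 autosomes / 75 Mb, 230 markers/Mb)
and write their tables under `results/`:

```bash
cd analysis
python 01_simulate.py && python 03_call_cnvs.py && python 04_cnvrs.py
```

prints (deterministic for the shipped seed):

```
cohort: 48 samples, 17250 markers
injected 141 CNVs (132 losses / 9 gains, loss fraction 0.9362)
140 CNV calls across 48 samples (131 losses / 9 gains)
vs 141 truth events: precision 1.000, recall 0.993 (+/-2-marker tolerance)
140 CNVs merged into 116 CNVRs (107 loss / 7 gain / 2 both)
carrier frequency 2.1-8.3%, genome coverage 21.51%, count~length R^2 0.857
```

That is: the HMM recovers essentially every injected CNV with exact-to-±2
marker breakpoints; merging yields 116 CNVRs dominated by losses (the
generator's 10:1 odds survive the pipeline); the rarest CNVR is carried by
1/48 animals (2.1%); and per-chromosome CNVR counts scale linearly with
chromosome length. `02_qc.py` shows the QC filters flagging deliberately
corrupted samples, `05`–`07` run the cross-study comparison, annotation and
qPCR stages (e.g. `07_qpcr.py`: 10/10 simulated assays confirm the array
call, CN~NR Pearson r = 0.996).

As a library:

```python
from ovicnv import qc
from ovicnv.synthetic_data import SimulationConfig, simulate_truth, simulate_signals
from ovicnv.cnv_caller import viterbi_segment
from ovicnv.cnvr_pipeline import merge_to_cnvrs

cfg = SimulationConfig(seed=7, n_samples=20)
truth, markers, genome = simulate_truth(cfg)
signals = simulate_signals(truth, markers, cfg)
markers = qc.compute_pfb(signals, markers)
calls = [c for s in signals for c in viterbi_segment(s, markers)]
cnvrs = merge_to_cnvrs(calls, cohort_size=cfg.n_samples)
```

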