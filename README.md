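# repseq-compare

Paired tumor/normal TCR-β repertoire comparison for AIRR-seq clonotype
tables: clone accounting, clone-size frequency spectra, highly-expanded-clone
(HEC) rates, TOP-N cumulative frequency, inverse Simpson diversity, tissue
overlap, TRBV/TRBJ gene usage with differential testing, exact nonparametric
cohort tests, and diversity-stratified survival — plus a synthetic
paired-cohort generator so the whole pipeline can be exercised and validated
without access to raw sequencing data.

## Who this is for

Groups analyzing bulk TCR-β CDR3 sequencing of matched tissue pairs (e.g.
tumor and adjacent normal tissue from the same patients) who already have
clonotype tables from an upstream caller (MiTCR/VDJtools/AIRR-style output)
and want a reproducible, tested downstream comparison of the two tissue
compartments across a cohort.

## The statistics at the core

For a sample with clone read counts $c_1,\dots,c_N$ and frequencies
$p_i = c_i / \sum_j c_j$:

- **Inverse Simpson diversity index** $DI = 1 / \sum_i p_i^2$ — the
  effective number of equally abundant clones. $DI = N$ for a perfectly even
  repertoire, and approaches 1 under clonal dominance.
- **HEC rate** — the fraction of *unique clones* whose frequency is strictly
  above 0.1% of reads (threshold configurable).
- **TOP-N cumulative frequency** — the percentage of reads carried by the N
  most abundant clones (deterministic tie-breaking).
- **Overlap rate** — per tissue, $100 \cdot |A \cap B| / |A|$, where the
  intersection is exact CDR3 identity at nucleotide or amino-acid
  resolution.
- **Differential V/J usage** — per segment, a paired two-tailed t-test on
  per-sample usage frequencies; a segment is called only when the fold
  change of means exceeds 1.5 in either direction *and* p < 0.05.
- **Cohort tests** — Wilcoxon signed-rank (paired tissues) and
  Mann-Whitney U (group comparisons) with *exact* small-sample p-values from
  full enumeration of the null, plus Kaplan–Meier/log-rank survival for a
  median split of tumor diversity.

## Worked example

Generate a small synthetic cohort of 5 patients and compare the paired
tissues:

```python
from repseq_compare import (SyntheticCohortConfig, generate_paired_cohort,
                            inverse_simpson, hec_rate, overlap_rate,
                            wilcoxon_signed_rank)

cfg = SyntheticCohortConfig(n_patients=5, clones_tumor=5000, clones_normal=4000,
                            reads_per_sample=50_000, seed=7)
cohort = generate_paired_cohort(cfg)

di_t, di_n = [], []
for pid in cohort.metadata["patient_id"]:
    tumor = cohort.repertoire(pid, "tumor")
    normal = cohort.repertoire(pid, "normal")
    di_t.append(inverse_simpson(tumor).inverse_simpson_di)
    di_n.append(inverse_simpson(normal).inverse_simpson_di)
    ov = overlap_rate(tumor, normal, key_level="nt")
    print(f"{pid}: DI tumor={di_t[-1]:.1f} normal={di_n[-1]:.1f} "
          f"HEC% tumor={100*hec_rate(tumor):.3f} normal={100*hec_rate(normal):.3f} "
          f"overlap% tumor={ov.rate_tumor:.2f} normal={ov.rate_normal:.2f}")

res = wilcoxon_signed_rank([t - n for t, n in zip(di_t, di_n)])
print(f"paired signed-rank on DI: W+={res.statistic}, p={res.p_two_tailed:.4f}")
```

Output:

```
P01: DI tumor=15.6 normal=12.6 HEC% tumor=2.731 normal=3.605 overlap% tumor=12.23 normal=16.33
P02: DI tumor=36.9 normal=12.5 HEC% tumor=2.679 normal=3.407 overlap% tumor=12.34 normal=20.03
P03: DI tumor=15.3 normal=12.6 HEC% tumor=2.593 normal=3.184 overlap% tumor=13.11 normal=16.88
P04: DI tumor=15.3 normal=12.3 HEC% tumor=3.027 normal=2.907 overlap% tumor=14.14 normal=14.93
P05: DI tumor=37.0 normal=12.3 HEC% tumor=2.746 normal=3.114 overlap% tumor=12.76 normal=19.79
paired signed-rank on DI: W+=15.0, p=0.0625
```

Tumor diversity exceeds normal diversity in every patient (the generator's
default tumor abundance law is flatter), the HEC rate runs the other way,
and the tumor overlap rate is the smaller of the two because the tumor
repertoire holds more unique clones. With only 5 pairs the most extreme
attainable two-tailed exact p-value is $2/2^5 = 0.0625$ — exactly what the
signed-rank test reports for 5/5 concordant differences.

The same analysis runs end to end from the shell:

```bash
repseq-compare simulate --config cohort.yaml --out data/ --seed 7
repseq-compare run --clonotype-dir data/ --metadata data/metadata.tsv --out report/
```

which writes `sample_metrics.tsv`, `overlap.tsv`, `usage_*.tsv`,
`differential_usage_*.tsv`, `cohort_comparisons.tsv`,
`survival_curves.tsv` and a machine-readable `summary.json`.

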