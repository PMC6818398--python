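# Methods

## Scope and data model

The package consumes clonotype tables — one tab-separated file per sample
with the CDR3 nucleotide sequence, its amino-acid translation, V and J
segment calls and a read count — and a per-patient metadata table with
clinical covariates and optional right-censored survival fields. It does not
process raw reads or call V(D)J rearrangements; those belong to upstream
tools whose outputs it accepts in three header dialects (`native`,
`vdjtools`, `airr`). Frequency columns in input files are ignored and
recomputed, so upstream normalization is never trusted.

A clonotype's identity ("key level") is configurable: nucleotide sequence
plus V/J call (`nt+VJ`, the default and the finest), nucleotide sequence
alone (`nt`), or amino-acid sequence (`aa`). Re-aggregation to a coarser key
sums counts and can only shrink the unique-clone count. Rows that are not
productive (a stop codon in the CDR3) or structurally invalid are dropped
and tallied per reason rather than aborting the read — the analysis is
defined over productive rearrangements only. Allele suffixes (`*01`) are
stripped at read time because all downstream analysis is at segment level.
Duplicate keys within one file are merged by summing counts, since upstream
tools differ in their own aggregation level.

## Per-sample statistics

All statistics are plug-in estimates over the clone frequency vector
p_i = c_i / Σc_j:

- **Inverse Simpson diversity** DI = 1/Σp². No Chao-type or rarefaction
  correction is applied; DI is computed at the repertoire's active key
  level (default `nt+VJ`).
- **HEC rate**: unique clones with frequency *strictly* above the threshold
  (default 0.1%), divided by the number of unique clones. The unique-clone
  denominator (rather than reads) is deliberate: it is the only convention
  under which published tissue HEC rates of order 10⁻⁴ are consistent with
  10⁵–10⁶ unique clones and order-10² expanded clones.
- **Frequency spectrum**: unique-clone shares across percent-scale bins
  (default edges 0.0001 / 0.001 / 0.01 / 0.1%). A clone exactly on an edge
  belongs to the lower bin, so the open top bin coincides with the strict
  HEC definition and the two agree identically.
- **TOP-N cumulative frequency**: ties in counts are broken by clonotype key
  (ascending), making listings deterministic across runs and platforms.
- **CDR3 spectratype**: length distribution weighted by unique clones by
  default (read-weighted optional).

## Tissue overlap

Shared clones are exact string matches at `nt` or `aa` resolution
(presence/absence only; no abundance-weighted index). The overlap rate is
normalized per tissue — 100·|A∩B|/|A| for tissue A — so for a fixed
intersection the tissue with the larger repertoire reports the smaller rate.
This is the convention under which published paired-tissue numbers (lower
overlap in the tissue with more unique clones) are internally consistent.
Amino-acid overlap can only gain shared items relative to nucleotide overlap
through convergent (synonymous) rearrangements, and can only lose them when
two distinct shared nucleotide clones collapse onto one amino-acid clone;
with realistic repertoires the first effect dominates.

## Gene usage

Usage frequencies are read-weighted by default (a segment's share of
repertoire mass; clone-weighted optional). Families are segment names
truncated before the sub-family number. Differential usage across paired
samples uses a per-segment paired two-tailed t-test, fold change of means
(tumor/normal) with a 10⁻⁶ pseudo-frequency floor against division by zero,
and the conjunction rule FC > 1.5 or FC < 1/1.5 *and* p < 0.05. No
multiple-testing correction is applied by default, matching common practice
for per-segment screens at this cohort size; Benjamini–Hochberg q-values
are available behind a flag. Identical paired profiles are treated as a
clean null (p = 1) rather than propagating the 0/0 t-statistic.

## Cohort tests

The signed-rank and rank-sum tests are implemented from their defining null
distributions so that small-cohort p-values are exact rather than
asymptotic:

- **Wilcoxon signed-rank**: zero differences dropped, midranks for tied
  absolute differences, and for n ≤ 25 effective pairs the exact two-tailed
  p from the full sign-flip null (subset-sum counting over all 2ⁿ sign
  vectors). Beyond 25, a normal approximation with tie and continuity
  corrections.
- **Mann-Whitney U**: exact when the pooled sample is ≤ 20 and tie-free
  (rank-sum distribution over all group labelings), tie-corrected normal
  approximation otherwise.
- Two-tailed p-values are symmetric-tail probabilities
  P(|T−center| ≥ |t_obs−center|), which are attained exactly by the
  enumeration oracles used in the tests.

Both the paired signed-rank and the unpaired Mann-Whitney U are reported
for the tumor-vs-normal diversity contrast: the unpaired test is reported
for comparability with prior practice on this design, the paired test as
the statistically appropriate companion. Covariate comparisons use
Mann-Whitney U for two groups (age dichotomized at 60 years) and
Kruskal–Wallis for more than two (TNM stage, differentiation; unknown
differentiation is excluded). Group summaries are reported as mean ± SD.

The median split of tumor diversity assigns values equal to the median to
the "low" group, which is deterministic and yields an 8/7 split for 15
patients. Survival uses the Kaplan–Meier product-limit estimator with
right censoring and a standard two-group log-rank chi-square (1 df);
no Cox regression or multivariate adjustment.

## Synthetic cohorts

The generator's purpose is to produce paired cohorts carrying the
statistical structure the analysis is designed to detect, at a scale where
the full pipeline runs in seconds:

- **Clone identity**: CDR3 nucleotide sequences sampled codon-wise from the
  61 sense codons, so productivity and nt/aa consistency hold by
  construction; amino-acid lengths follow a discretized Gaussian on 8–23
  peaking at 15. V/J calls are drawn from a default profile anchored on the
  dominant lung-repertoire segments (TRBV11-2 15.25%, TRBV29-1 10.08%,
  TRBV20-1 8.16%, TRBV6-5 7.07%, TRBV12-3 6.81%; TRBJ2-1 18.78%, TRBJ2-7
  17.58%, TRBJ2-3 11.67%, TRBJ2-5 9.95%), with the remainder decaying
  geometrically over the other functional segments. The default V list has
  46 segments merging to 23 families; the J list is the standard 13
  segments in 2 families.
- **Abundance**: Zipf (p_r ∝ r^−α) or lognormal ranks, assigned to clones
  in random order, then multinomial read sampling; clones drawn zero times
  are unseen, as in real sequencing. Defaults: α = 1.05 (tumor) vs 1.25
  (normal), 5×10⁴ / 4×10⁴ unique clones, 5×10⁵ reads per sample with ±20%
  per-sample depth jitter. These are desk-scale analogues (roughly one
  tenth) of study-scale repertoires; the laws, not the absolute scale,
  carry the tested structure, so diversity and HEC values are smaller in
  magnitude than tissue-scale reports while preserving every directional
  contrast (tumor DI > normal DI, normal HEC rate > tumor HEC rate, smaller
  overlap rate on the tumor side).
- **Sharing**: a configurable fraction (default 0.25) of each normal pool
  is embedded in the matched tumor pool with identical sequences; abundances
  are drawn independently per tissue because sharing is analyzed as
  presence/absence. The default produces observed overlap rates in the
  9–16% range.
- **Covariates and survival**: patients older than 60 get a tumor Zipf
  exponent steepened by a configurable factor (default +15%), planting the
  age–diversity association. Survival times are exponential with a baseline
  hazard of 0.02/month, a hazard ratio (default 3) for the high-diversity
  half of the cohort, and exponential censoring at 0.01/month; real paired
  survival data for this design are unpublished, so these targets are
  directional only and the magnitudes are acknowledged as arbitrary.
- **Determinism**: one `numpy` generator seeded from the config drives all
  draws; identical configs produce byte-identical output tables.

What the generator does *not* emulate: biophysical V(D)J recombination
(insertion/deletion profiles), thymic selection, convergent recombination
(amino-acid sharing beyond what random codon synonymy produces), sequencing
error, or PCR amplification bias. Passing the parameter-recovery tests
therefore demonstrates that the pipeline detects the planted contrasts
under the assumed generative laws — not that real tissue pairs follow those
laws.

## Numerical and design choices

- Clone frequencies always renormalize from raw counts; sums are exact to
  machine precision and asserted to 10⁻¹² in tests.
- Degenerate inputs are first-class: all-zero paired differences raise a
  degenerate-data error at the API level and are reported as NaN p-values
  by the pipeline; empty repertoires and refinement requests
  (aa → nt) raise typed errors; a Zipf exponent of zero is the valid
  uniform limit (only negative exponents are rejected).
- Problem sizes in the test suite: exact-test oracles enumerate up to 2¹⁰
  sign vectors and C(10,5) labelings; parameter recovery runs 20 cohorts at
  the default scale and null calibration 40 cohorts at reduced scale
  (2×10³ clones, 2×10⁴ reads), chosen so the full suite completes in about
  two minutes on one core.
- Figure rendering is intentionally out of scope; all reports are TSV plus
  one JSON summary so downstream checks can assert on numbers directly.

## Known limitations

- Diversity is a plug-in estimate and depends on sequencing depth;
  cross-study comparisons should fix depth or use the provided multinomial
  downsampling helper.
- Exact tests fall back to normal approximations beyond their enumeration
  limits; at n around 25–30 the continuity-corrected approximation is
  accurate to a few times 10⁻³ in p.
- The overlap analysis is within-patient only; cross-patient public-clone
  analysis is out of scope.
- Survival analysis supports right censoring only (no competing risks) and
  an unadjusted two-group comparison.
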