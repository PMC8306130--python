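# Methods

This note documents the models, conventions and design choices behind
`gnas_imprint`, in the order data flow through the pipeline.

## Biological setting and assumptions

The *GNAS* locus (20q11) is imprinted: in the pituitary, *GNAS* is expressed
from the maternal allele only, controlled by maternal methylation of the A/B
DMR upstream of the *GNAS* promoter. The package models three tumor states:
gsp-positive (activating Gsα mutation at Arg201/Gln227), gsp-negative with
intact imprinting, and gsp-negative with relaxed imprinting (re-expression
of the normally silent allele). Key assumptions inherited from the assay
design:

* Allelic quantification at rs7121 cannot assign parental origin — it sees a
  minor/major split only. Accordingly, all relaxation logic uses the
  minor-allele convention (AQ ∈ [0, 50]) and no phasing is attempted.
* Relaxation is only observable in rs7121 heterozygotes; homozygous
  gsp-negative tumors are structurally unclassifiable (G2 vs G3) and are
  reported as `unclassified`, never imputed.
* One bulk measurement per sample per assay; no mosaicism or purity model.

## Methylation

The region methylation level (ML, percent) is the arithmetic mean of the 6
pyrosequenced CpGs; the array-mode methylation index (MI, beta fraction) is
the mean of 3 EPIC probes. Every value carries a unit tag (`percent` vs
`fraction`); classification against a range with a different tag raises
rather than silently mixing scales (the two scales differ by exactly ×100
and both appear in routine reporting, which makes silent mixing the main
practical hazard). Classification bounds are inclusive toward `normo`: a
value exactly at a bound is within the threshold of normal values. The exact
genomic coordinates of the 6 CpGs within the 101-bp window are not published
by the assay vendor; the data model stores positions and validates only
containment in chr20:57,463,600–57,463,700 (GRCh37, 1-based inclusive; BED
export converts to 0-based half-open).

## Allelic quantification and relaxation

* Heterozygosity gate: gDNA minor-allele AQ ≥ 50 − tolerance, with tolerance
  defaulting to 15 percentage points. No tolerance is published; 15 admits
  realistic PCR allele skew while rejecting homozygotes by a wide margin
  (simulated homozygote background sits below 2%). Configurable.
* Relaxation: minor allele strictly greater than the threshold share of
  total cDNA signal. The strict inequality is deliberate — the operational
  rule is "greater than 20%", so AQ exactly 20 stays unrelaxed.
* Threshold derivation from normal pituitaries: mean + 2·SD of their cDNA
  AQ (monoallelic background). The operational threshold is
  max(derived, 20): a derived value above 20 is used (and logged), a lower
  one never silently relaxes the published 20% rule. Fewer than two usable
  heterozygous normals leaves the 20% default in place, logged.
* No PCR allele-bias correction is applied to AQ; none is published for the
  assay.

## Expression

Standard curves are ordinary least squares of Cq on log₁₀ input copies
(≥ 3 points spanning ≥ 2 decades, slope necessarily negative); amplification
efficiency is 10^(−1/slope) − 1, and quantification inverts
copies = 10^((Cq − intercept)/slope). Normalized expression is
value_k = (copies_gene / copies_BGUS) / 1000, i.e. the
"× 1000 copies per copy BGUS" reporting scale; values are stored at full
precision and the scale is purely an I/O convention. Samples without a
usable BGUS quantification are flagged and excluded listwise from expression
comparisons (no imputation). *GNAS* overexpression uses a strict upper
cut-off at mean + 1·SD of the gsp-positive reference; the asymmetry with the
2·SD methylation rule is preserved as the analysis convention it is, not
harmonized.

## gsp calling

Input is a CDS-aligned coding-strand sequence (codon 1 = first codon), which
keeps the caller independent of the sequencing assay. Any missense change at
codon 201 (reference Arg) or 227 (reference Gln) is positive; synonymous
changes and variants elsewhere are negative; an N or stop at a hotspot is
undetermined. The hotspot set {201: R, 227: Q} is an explicit, overridable
allow-list. The bundled reference CDS is synthetic (240 codons, no internal
stops, hotspots pinned to CGT/CAG): the caller inspects only the two hotspot
codons, so a synthetic backbone keeps the package self-contained without
loss.

## Statistics

* **Normality omnibus**: K² = Z₁² + Z₂² with the standard transformed-moment
  statistics (D'Agostino 1970 skewness; Anscombe–Glynn 1983 kurtosis),
  p from χ²(2). Requires n ≥ 8; degenerate (constant) input is an error.
  This is the omnibus implemented by the desk-statistics software commonly
  used for such cohorts, which is why it gates the reference ranges.
* **Reference ranges**: mean ± k·SD with the n−1 sample SD, only when the
  omnibus does not reject at α = 0.05; otherwise empirical 2.5/97.5
  percentiles with a `fallback` flag that propagates into reports. k = 2 for
  the methylation normal range, k = 1 (upper bound only) for overexpression.
* **Mann–Whitney**: average ranks for ties. Exact two-sided p by full
  enumeration of the U null distribution when n₁+n₂ ≤ 20 and the pooled
  data are tie-free; the two-sided definition is
  P(min(U, n₁n₂−U) ≤ observed min), which for the symmetric tie-free null
  equals doubling the smaller tail. Otherwise: normal approximation with
  tie-corrected variance and a 0.5 continuity correction. The switch point
  (20) mirrors common desk-stat behavior so small-cohort p-values are exact.
* **Fisher**: two-sided by the minimum-likelihood convention (sum of
  hypergeometric probabilities of all same-margin tables at most as probable
  as the observed one), with a 1e−7 relative tolerance on the comparison to
  absorb floating-point near-ties; a zero margin gives p = 1. This is the
  convention of the cited analysis software; the doubling convention would
  differ on asymmetric tables.
* No multiple-testing correction is applied (matching the analysis being
  reproduced); significance flags use a configurable α (default 0.05) and
  p-values are always reported in full.

## Synthetic cohorts

The generator emulates the statistical structure of the target cohorts; its
defaults are the study conditions, not tuning knobs:

* gsp prevalence 0.25; rs7121 minor-allele frequency 0.35 (heterozygosity
  2·maf·(1−maf) ≈ 0.455); relaxation in 44% of gsp-negative tumors; 18% of
  tumors SSA-pretreated (with no expression effect, as observed).
* Methylation: sample-level ML Gaussian per stratum — normals and
  gsp-positive N(40, 2.5); gsp-negative a mixture of normo N(40, 2.5),
  hyper N(60, 6) at weight 0.20 and hypo N(27, 2) at weight 0.03 — with
  additive per-CpG Gaussian noise (SD 3) truncated to [0, 100]. Ground-truth
  class labels record the mixture component drawn, so classification
  accuracy against truth includes the irreducible overlap between the normo
  component and a mean ± 2SD range (~5% of normo draws fall outside it).
* Expression (value_k scale): gsp-positive *GNAS* is a truncated-at-zero
  Gaussian with mean 293 and SD 224 — the published median and
  overexpression threshold are mutually consistent under normality
  (293 + 224 = 517), and the threshold construction requires an (approximately)
  normal reference, so this stratum is deliberately not log-normal. All
  other gene × group strata are log-normal with medians anchored to the
  published group medians (*GNAS* 755/405, *SSTR2* 106/634/203, *AIP*
  102.7/207.5/105.1 for gsp-positive / unrelaxed / relaxed as applicable)
  and a common log-scale σ = 0.5 — dispersions are not published, so σ is a
  documented free knob. Zero-truncation of the gsp-positive stratum biases
  its population mean + SD upward by about 1.5% (≈ 525 vs 517), well inside
  the n = 19 sampling error the recovery checks use.
* qPCR encoding: per-gene standard curves at the perfect-doubling slope
  −1/log₁₀2 with small point noise (SD 0.05 cycles); sample Cq values carry
  technical-replicate noise only (SD 0.05 cycles). The stratum distributions
  above describe *observed* normalized expression — between-tumor spread
  including assay error — so the Cq encoding must not add biological-scale
  noise on top of them; quantification robustness to larger noise is a
  property of the inversion and is tested separately (σ = 0.2 Cq noise
  recovers log₁₀ copies with RMSE < 0.1).
* Allelic signals: heterozygous gDNA splits near 50/50 (SD 2 percentage
  points); cDNA minor-allele fractions are Beta-shaped on disjoint supports,
  [0, 10]% for unrelaxed/normal samples and [20, 50]% for relaxed ones, with
  small additive signal noise. Parental origin of the expressed allele is
  drawn internally and never exported — the emitted observables carry
  exactly the information the assays can see.
* Sequences: gsp-positive samples carry one of R201C/R201H/Q227R/Q227L on
  the synthetic reference backbone; everything else is the reference.
* Determinism: one global seed spawns an independent substream per sample
  from (seed, sample index), so identical seed + config is bit-identical and
  resizing a cohort preserves shared samples. Expression-to-relaxation
  coupling is purely through distinct stratum location parameters, not a
  mechanistic dose–response (only group medians are published).

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: tumor purity and stromal admixture,
pyrogram- or array-level artifacts, PCR allele bias in AQ, correlated
multi-gene expression programs, copy-number gains on 20q, and any clinical
covariate beyond the SSA flag. Accuracy numbers against ground truth are
statements about the generative model's separability at its configured
noise, not about clinical performance.

## Pipeline conventions

* Thresholds are derived within-cohort from designated reference groups
  (gsp-positive tumors; heterozygous normals), each requiring n ≥ 8 for the
  normality-gated ranges; a too-small reference raises an error naming the
  failing reference. The published cut-offs (517; 42.4 ± 11.4%; 20%) are
  available as a fixed `PRINTED_THRESHOLDS` set, because an independent
  cohort will not reproduce another study's reference group.
* G1 membership follows gsp status alone; relaxation status is reported for
  gsp-positive tumors but does not affect their group. Both the full
  gsp-positive count and the rs7121-informative subset are reported, since
  downstream tabulations may legitimately use either denominator.
* Group assignment is total and deterministic; removing unclassified
  samples and re-summarizing leaves G1/G2/G3 statistics unchanged.
* Every gating decision (uninformative samples, missing BGUS, normality
  fallbacks, threshold flooring) is appended to a run log written alongside
  the outputs; reports carry the seed, a config hash and the package
  version, and contain no timestamps, so fixed-seed runs are byte-identical.

## Problem sizes

Default validation sizes: 200-tumor cohorts for end-to-end accuracy, 500 for
relaxed-fraction recovery, 15 replicates of n = 19 reference groups for
threshold recovery (n = 19 is the gsp-positive reference size the published
thresholds come from; medians over replicates are compared against the n=19
Monte-Carlo sampling error, ~2.4 percentage points for the methylation
bounds and ~60 value_k units for the expression threshold), 10,000
replicates for normality-test calibration, and 10⁵ draws for the 2·SD
coverage check. All complete in seconds on one CPU.

## Known limitations

* The exact Mann–Whitney path requires tie-free data; tied small samples
  fall back to the approximation, which is anti-conservative for very small
  n with heavy ties.
* The minimum-likelihood Fisher p is one of several two-sided conventions;
  comparisons against software using tail-doubling will differ on
  asymmetric tables.
* The normality gate at n = 19 has low power against moderate skew, so the
  parametric range is occasionally used on mildly non-Gaussian references —
  faithful to the reproduced procedure, but worth remembering when
  interpreting fallback flags.
* Other transcripts of the locus (NESP, XL, GNAS-AS1) and their DMRs are
  out of scope, as are copy-number analysis and transcriptomic
  classification.
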