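# Methods

## Problem

SNP microarrays and pooling (SNP-MaP) estimates group allele frequencies by
hybridizing pooled DNA from many individuals to a genotyping array instead of
genotyping each person. The per-SNP readout is the relative allele signal
(RAS) score, the ratio of allele-A signal to total signal, A/(A+B), which
serves as an estimate of the pool's allele-A frequency. A case-control scan
then compares case-pool and control-pool RAS scores per SNP.

This package implements that whole workflow — pool construction,
probe-intensity simulation, RAS allelotyping, the pool-level t-test scan and
the validation statistics — driven by a synthetic-data generator, because the
cohort the design is modeled on (a depression case-control sample of 1418
cases and 1301 controls pooled into 57 pools) is not publicly deposited.

## The intensity model

For pool *p* with true pooled allele-A frequency *f* at a SNP, probe *j* with
affinity φⱼ, and DNA-quality multipliers (m_sig, m_bg, m_noise):

    PM_A = m_sig · S · φⱼ · (f + κ(1−f)) + m_bg · b + ε
    PM_B = m_sig · S · φⱼ · ((1−f) + κf) + m_bg · b + ε′
    MM_A = MM_B = m_bg · b + ε″          (only when the array has MM probes)

* **S** (`signal_scale`, default 1000 intensity units) sets the allele-specific
  signal; only ratios matter downstream, so its absolute value is arbitrary.
* **b** (`background_level`, default 300) is nonspecific background shared by
  both allele channels. It is the mechanistic source of the "slump": in
  PM-only mode RAS = (S·φ·f + b)/(S·φ + 2b) is pulled toward 0.5, more
  strongly as b grows. Mismatch probes see exactly this background, so
  subtracting MM from PM before forming the ratio undoes the slump — which is
  why arrays that dropped MM probes give biased absolute frequency estimates.
* **κ** (`cross_hyb_fraction`, default 0.05) is cross-hybridization of each
  allele's target onto the other allele's probes; it compresses RAS toward
  0.5 multiplicatively and survives MM subtraction (RAS → (f+κ(1−f))/(1+κ)).
* **φⱼ** are i.i.d. lognormal with unit median (`probe_affinity_sigma`,
  default 0.3), the standard multiplicative probe-effect assumption. They are
  properties of the array design, so they are fixed across hybridizations.
* **ε** is zero-mean normal per channel with SD = `noise_cv` · m_noise ·
  (channel mean), clamped at zero — multiplicative measurement error, because
  array noise scales with signal. Default `noise_cv` 0.1.
* **Quality presets**: blood = (1.0, 1.0, 1.0); buccal (cheek-swab) =
  (0.4, 2.0, 2.0) — attenuated specific signal, doubled background and noise.
  The buccal values are stand-ins chosen so that cheek-swab runs land in a
  visibly degraded regime; both presets are config-overridable. No parameter
  of this model is an estimate of any real array platform; all are documented
  assumptions.
* Each SNP is interrogated by 6–8 probes (uniform draw), matching a modern
  high-density design; 24- or 40-probe designs can be emulated by config.

Technical replicates share the pool's realized contribution weights and true
frequencies and redraw only ε — that is exactly what hybridizing one pool to
two arrays varies.

## Cohort and pooling

Genotypes are Hardy-Weinberg draws: control allele-A frequency
f ~ Uniform(0.05, 0.5) per SNP; case frequency equals f except at designated
effect SNPs, where an allele-level odds ratio acts:
f_case = OR·f / (OR·f + 1 − f). SNPs are independent (no linkage
disequilibrium). Individuals carry sex (50/50), a three-level covariate
stratum (uniform; the analogue of BMI bands) and a DNA source — cases all
blood, controls 10/28 blood by default, mirroring the emulated study's pool
composition.

Pools are built within each (phenotype, sex, stratum, dna_source) cell:
members are randomly partitioned into round(n/48) pools whose sizes differ by
at most one, so pool size is a distribution around the target, as in the
emulated design (mean 47.67, SD 9.39). Contribution weights model pipetting
error as gamma draws with CV = `pipetting_cv` (default 0.05, a realistic
liquid-handling error) renormalized to sum to 1; gamma keeps weights positive
at any CV. A pool's true frequency is the weight-weighted mean genotype
dose / 2.

## Allelotyping

Per probe, ras_j = A/(A+B) (PM-only) or, in mismatch mode,
a = max(PM_A − MM_A, 0), b = max(PM_B − MM_B, 0), ras_j = a/(a+b). The
SNP-level score is the unweighted mean of per-probe ratios. Mean-of-ratios is
chosen to match the lineage of RAS scoring, which averages per-quartet
scores; the ratio-of-summed-intensities alternative is available via
`summarization="ratio_of_sums"` and covered by tests. Zero-denominator probes
are dropped rather than imputed at 0.5 (imputation would manufacture slump);
a SNP whose probes are all dropped is reported missing (NaN) and is skipped,
not propagated, by downstream statistics.

## Scan

Technical replicate arrays are averaged into one RAS value per pool before
testing: arrays are repeated measures of one pool, so the pool count — not
the array count — sets the degrees of freedom. Per SNP, case pools vs control
pools are compared with the independent two-sample Student's t-test (pooled
variance, df = n₁ + n₂ − 2); Welch's test is a config option. The MAF used
for the < 0.05 exclusion is the folded mean RAS over all hybridizations
(min(f̂, 1 − f̂)); an external MAF table can be supplied instead. The
genome-wide threshold defaults to 7.2e-8 and is a parameter, not a constant.
Degenerate SNPs with zero pooled variance and unequal means return the
smallest representable positive p with a logged warning. No correction beyond
the fixed threshold is applied.

## Validation statistics

* **Replicate correlations**: Pearson r between the RAS vectors of a
  duplicated pool's two arrays (technical), and mean pairwise r among pools
  of the same phenotypic cell (biological). Computed over all scored SNPs;
  constant vectors are skipped with a warning.
* **RAS vs truth**: per (phenotype, dna_source) stratum, Pearson r between
  SNP-level mean RAS across the stratum's pools and the mean true weighted
  pooled frequency of the same pools.
* **Ratio of ratios**: per follow-up SNP,
  R = (f̄_ctrl/f̄_case) / (RAS̄_ctrl/RAS̄_case). Both sides are means over the
  same pools — truth as the mean of weighted pooled genotype frequencies,
  RAS as the mean of pool-level scores. The matched construction is
  deliberate: with unequal pool sizes, an individual-level group frequency
  differs slightly from the mean over pools, and a perfect estimator would
  not return R = 1 exactly; under the matched construction it does. Reported
  are mean(R), sample (n−1) SD, and the percentage of SNPs within one SD of
  the mean; SNPs with any guard denominator below 1e-6 are excluded and
  counted. The follow-up panel emulates top-hit confirmation: every
  genome-wide-significant SNP plus a random fill from the non-excluded SNPs
  up to the configured size (110 by default).

## Randomness and determinism

All randomness flows from one top-level seed through named substreams
(CRC-32 of the stage name folded into a `SeedSequence`), so each stage is
reproducible in isolation and drawing from one stream never perturbs another.
The pipeline manifest records the SHA-256 of every output file and contains
no timestamps; a rerun with the same config is byte-identical.

## What the simulation does and does not show

The generator reproduces the statistical structure the analysis assumes:
Hardy-Weinberg sampling into finite pools, pipetting variance, probe-set
redundancy, additive background with and without MM rescue,
quality-dependent attenuation, and replicate structure. It does not model
linkage disequilibrium, probe-sequence effects, spatial artifacts, batch
effects, or the actual chemistry of any platform — so passing tests
demonstrate internal consistency of the method and the direction and
mechanism of the design effects, not quantitative agreement with any real
array. Headline numbers from real pooled studies (e.g. specific correlation
values) are not reproduction targets, because the underlying cohort data are
private; the package's checks are property-based instead.

One emergent behaviour deserves emphasis: in the emulated design all case
pools are blood DNA while most control pools are cheek-swab DNA. Because the
slump depends on DNA quality, a null simulation of this confounded design
yields hundreds of spurious genome-wide hits, while a blood-only rescan of
the same data is calibrated (analysis/03). The type-I-error check is
therefore run source-matched.

## Problem sizes

Defaults keep the emulated cohort (1418/1301, pools of ~48) but scale the
marker panel to 10,000 SNPs; the analysis drivers use 2,000 and the
acceptance checks use 200–10,000 per property. These sizes give Monte-Carlo
error small enough for every property asserted (e.g. 3 binomial SEs of the
nominal rate at 10,000 SNPs is ±0.65 percentage points) while keeping any
single run in seconds.

## Known limitations

* The RAS-based MAF estimate is itself slumped toward 0.5, so under heavy
  background the MAF < 0.05 exclusion rarely fires even for truly rare
  variants; supplying an external MAF table is the remedy.
* `estimate_maf` averages over arrays (not collapsed pools), so duplicated
  pools weigh slightly more in the exclusion decision.
* The degenerate zero-variance p-value sentinel is a pragmatic choice; those
  SNPs should be treated as artifacts, not discoveries.
* Buccal presets are illustrative; the real blood/buccal gap in any given
  experiment depends on extraction chemistry the model does not capture.
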