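# Methods

## Data model and censoring

The unit of observation is one crustacean sample (freshwater shrimp,
marine prawn or marine crab, with a production region, month and year)
measured for 22 OPE congeners in μg/kg wet weight. Measurements below
the method detection limit are *nondetects*: the table stores an
explicit detect flag per cell rather than a sentinel value, because the
censoring pattern is itself informative (detection frequencies are a
first-class output) and because downstream statistics must be able to
change the substitution convention without re-reading the data.

Substitution policies: `zero` (default, the convention of the survey
this package reimplements), `half_lod`, `lod`. Per-congener LODs
default to 0.5 μg/kg ww — the midpoint of the survey's published
0.2–0.9 range — except TMPP at its published 0.21. LODs only matter
for the non-default policies; all shipped results use `zero`, under
which most congeners' medians are exactly 0, as in the survey tables.
The detected/nondetect dichotomy is deliberately binary: the package
does not distinguish below-LOQ-above-LOD values, which the source data
do not either.

## Synthetic cohort generator

Each (species, congener) concentration is zero-inflated lognormal:

    X = B · L · m_region · m_month,   B ~ Bernoulli(p_detect),
    L ~ Lognormal(μ, σ),   μ = ln(overall_mean / p_detect) − σ²/2

so that E[X] = overall_mean exactly (before region/month effects) and
nondetects are exact zeros, matching the substitution-by-0 convention.
The lognormal positive part is the standard exposure-assessment choice
for nonnegative, heavily right-skewed residue data (published means far
exceed medians of 0). Defaults:

- `sigma` = 1.0 (log-scale SD of the positive part) unless calibration
  against a published maximum is requested, in which case σ solves
  m_pos·exp(zσ − σ²/2) = maximum with z = Φ⁻¹(1 − 1/n) (smaller root,
  capped at z when the maximum exceeds the attainable quantile).
- month effects = 1 for all months: the survey found no seasonal
  signal, so the generator's null is the study condition.
- "survey-calibrated" region multipliers are the published regional ΣOPE means
  over the overall mean 5.74 (e.g. Zhoushan 15.3/5.74 ≈ 2.67,
  Quzhou 1.2/5.74 ≈ 0.21).
- detection probabilities use the published species-specific rates
  where available (e.g. TEP 53.12% / 43.9% / 14.29% in shrimp / prawn /
  crab); congeners whose rates were not published default to values
  inside the published group ranges (DPhP 0.35, TiBP 0.24, chlorinated
  congeners 0.10–0.18, others 0.15), and never-detected congeners
  (DoCP, TiPP, TDBPP) to 0. These defaults exist for demonstration
  runs; no quantitative claim rests on them.

Random streams are derived per (species, region, month, year, congener)
by SHA-256 hashing of the key into a `numpy` `SeedSequence` together
with the master seed, so adding strata to a design never perturbs the
draws of existing strata, and any cohort is bit-reproducible from its
seed.

What the generator does *not* emulate: measurement error and recovery
correction, between-batch drift, within-stratum overdispersion beyond
the lognormal, spatial correlation between nearby regions, and
inter-congener dependence (cells are independent given the stratum).
Tests that pass on synthetic cohorts therefore validate the analysis
machinery under the stated distributional model, not the field
properties of real monitoring data.

## Descriptive statistics

Summaries (n, mean, min, median, max, SD with ddof=1, detection
frequency) are computed over substituted values; for ΣOPEs summaries a
sample counts as "detected" if any congener was detected. Class and
congener shares are ratios of sums of per-congener means, hence
invariant to sample order and overall rescaling. The survey's narrative
class shares (51.5/38.8/9.7% chlorinated/alkyl/aryl) are inconsistent
with its own printed per-congener means, which give ≈39.0/55.2/5.8%;
this package reports the means-based shares, and the dominant-trio
share TiBP+TEP+TCEP = 68.1% which is consistent with both.

## Comparison, correlation, clustering

- Normality: Shapiro–Wilk; constant vectors are rejected as degenerate
  rather than returning a meaningless p.
- Kruskal–Wallis: tie-corrected H (censoring produces massive zero
  ties); p from the χ²(g−1) null, or an exact enumeration of all
  assignments of the pooled values to the group sizes for pooled
  n ≤ 12. When all pooled values are identical the test returns
  (H=0, p=1) by convention instead of dividing by a zero tie term.
  The exact oracle is compared to the χ² route at pooled n = 10
  (groups 3+3+4), the largest design it enumerates cheaply; at smaller
  n the χ² approximation's lattice error can exceed 0.05 in the mid-p
  range, a property of the approximation, not of either implementation.
- Spearman: average-rank correlation over per-sample concentration
  vectors, pooled across species by default (a per-species restriction
  is available). Congeners with zero variance are listed as excluded —
  rank correlation is undefined for constant vectors, so correlations
  reported elsewhere for never-detected congener pairs cannot be
  reproduced and are not attempted.
- Clustering: agglomerative on d(i,j) = 1 − |ρ(i,j)| with average
  linkage and k = 3 by default. Correlation-magnitude distance matches
  the source-apportionment reading (congeners from a common source
  co-vary); average linkage is the least shape-committal of the three
  offered (average/ward/complete). Cluster ids are renumbered by first
  appearance in label order, making assignments canonical up to the
  label set.
- No multiple-testing correction is applied to the survey-mirroring
  report (α = 0.05 per test); a Holm-adjusted column is emitted
  alongside for transparency.

## Risk assessment

EDI = C·IR/BW, THQ = EDI/RfD, HI = ΣTHQ, with C the congener mean
(μg/kg ww), IR in g/day (children 11.85, teens 24.23, adults 33.32) and
BW in kg (16.68, 46.25, 57.03). The arithmetic keeps IR numerically in
g/day — the published risk table is on that scale (e.g. TEP children:
1.089 × 11.85 / 16.68 ≈ 0.774 point estimate against a published Monte
Carlo median of 0.581) — so EDI values are comparable cell-for-cell
with the published table. Only the 10 congeners with a published RfD
enter THQ/HI; the other 12 are reported as excluded, never silently
zeroed. Boundary classification follows the stated inequalities: THQ
exactly 0.1 is "low", HI exactly 1 is "potential".

The Monte Carlo mode (default 10,000 iterations) draws per iteration a
concentration per congener and IR/BW per group, then forms EDI, THQ
and the *iteration-wise* HI (the sum-of-median-THQs alternative is
reported alongside). Concentration strategies:

- `lognormal_mean_matched` (default): lognormal with the observed mean
  and geometric SD 2.2. The GSD default reflects that the published
  Monte Carlo medians sit at ≈0.73–0.79 of the deterministic point
  estimates, the median/mean ratio exp(−σ²/2) of a lognormal with
  σ ≈ 0.79 (GSD ≈ 2.2). The published medians are therefore
  approximated in distribution, not reproduced digit-for-digit — the
  survey does not state its input distributions.
- `bootstrap`: the congener means of a with-replacement resample of the
  samples (the sampling distribution of the mean).
- `fixed`: degenerate at the mean; with zero IR/BW CVs every percentile
  equals the deterministic risk table exactly (degenerate arrays are
  summarized by their common value to keep that equality exact in
  floating point).

IR and BW default to fixed point values; optional CVs (mean-matched
lognormal) support sensitivity analysis.

## Numerical and design choices

- Printed-precision comparisons against published table cells round the
  computed value to the cell's printed decimals; where a published
  ratio's numerator is itself rounded (EDIs printed at 2–3 decimals
  against THQs at 5), the comparison tolerance propagates half a unit
  of the numerator's last printed digit.
- Long-format CSV is the interchange format (wide export provided as a
  convenience but it cannot carry detect flags). Row order on write is
  sample_id then catalog order, so writes are byte-stable.
- Species and chemical classes are closed enumerations; region is free
  text (the survey names cities but gives no closed list).
- Wet-weight concentrations throughout; no dry-weight conversion.

## Problem sizes in the shipped tests

Generator-calibration checks use 10,000-sample cohorts (binomial SE of
a detection frequency ≈ 0.5 percentage points); the type-I-error
calibration of the null-month Kruskal–Wallis uses 500 replicate
cohorts of 5 months × 20 samples over a 3-congener catalog, sizes at
which the 95% binomial band around the nominal 0.05 rate is roughly
±0.02. The latent-factor Spearman check uses n = 533, the survey's
sample count.

## Limitations

- The package reproduces the survey's *reproducible surface*: the risk
  arithmetic, composition shares and the statistical machinery. The
  field results themselves (species and regional means) depend on raw
  samples that were never deposited and are used only as calibration
  targets.
- Carcinogenic risk (ILCR) and multi-pathway (inhalation, dermal)
  aggregation are out of scope, as in the source analysis.
- The EDI formula's unit convention (IR kept numerically in g/day)
  mirrors the published table's scale and keeps every cell directly
  comparable with it; a strict g→kg conversion would rescale all EDI,
  THQ and HI values by 1/1000. The package documents rather than
  silently "fixes" this, because the published RfD comparisons and risk
  classifications were made on the published scale.
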