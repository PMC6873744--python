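# Methods

## Model and scope

The package implements two-sample summary-data Mendelian randomization:
exposure (leukocyte telomere length, SD units) and outcome (Alzheimer's
disease, log odds) associations come from two non-overlapping GWAS
cohorts, and only per-SNP summary pairs (b_X, σ_X, b_Y, σ_Y) are used.
Identification rests on the usual instrumental-variable assumptions —
relevance (all packaged instruments reach p < 5×10⁻⁸ for the exposure),
independence, and exclusion (no horizontal pleiotropy) — with the robust
estimators and diagnostics probing exclusion violations. Individual-level
data, LD estimation from reference genotypes, and multivariable MR are out
of scope.

## Harmonization

Outcome records are aligned to the exposure's effect allele by exact
match, order swap (negating b_Y and complementing the allele frequency),
or strand complement, in that resolution order; allele sets that remain
irreconcilable are dropped with reason `incompatible`, never silently.
Palindromic (A/T, C/G) SNPs cannot be strand-resolved from alleles; they
are kept with strand inferred from allele frequency only when the exposure
minor-allele frequency is below 0.42 (configurable), else dropped as
`ambiguous`. After alignment every instrument is oriented so the effect
allele is the exposure-increasing allele (b_X > 0), which MR-Egger
requires. A cross-cohort effect-allele-frequency gap above 0.10 logs a
warning but does not drop the SNP — the packaged study retained one such
variant, and frequency differences of that size can reflect cohort
composition rather than allele mislabeling.

## Clumping

Greedy p-value-ordered clumping: visit SNPs from most to least significant
(ties broken lexicographically on rsID, making results independent of
input order) and keep a SNP unless an already-kept SNP on the same
chromosome within ±2 Mb has r² > 0.001 with it. Kept pairs therefore
satisfy r² ≤ 0.001; cross-chromosome pairs never clump. LD arrives as a
square r² matrix (TSV) or sparse pair list. For the packaged study no
pairwise r² values are published, only the kept/removed outcome, so the
pipeline builds a locus-block stand-in: r² = 0.8 between SNPs sharing a
gene label or lying within 200 kb on the same chromosome (transitive
closure), 0 elsewhere. Any r² above the 0.001 threshold would give the
same result; 0.8 is a typical within-locus value. The 200 kb proximity
rule is needed because two zinc-finger-gene SNPs 144 kb apart on
chromosome 19 carry different gene labels yet clump together in the
packaged table. This reproduces the packaged kept/removed column exactly
(10 of 16 kept).

## Estimators

All estimators work internally per SD increase of the exposure; when a
panel declares `per_sd_decrease` the pooled log odds ratio is negated at
report time (the reproduction study's reporting convention).

- **Wald ratio**: β̂ᵢ = b_Y/b_X, SE σ_Y/|b_X| (first-order delta method;
  a second-order variant adding the b_Y²σ_X²/b_X⁴ term is available).
- **IVW**: weighted mean of ratios with weights (b_X/σ_Y)². Default
  variance model is multiplicative random effects: fixed-effect SE times
  max(1, √(Q/(n−1))) — overdispersion widens the interval, underdispersion
  never narrows it. The point estimate is identical under both models.
  Normal-theory p-values. n = 1 reduces to the Wald ratio.
- **Maximum likelihood**: b_Xi ~ N(γᵢ, σ_Xi²), b_Yi ~ N(βγᵢ, σ_Yi²). The
  γᵢ profile out exactly, leaving the scalar objective
  ½Σ(b_Yi − βb_Xi)²/(σ_Yi² + β²σ_Xi²), minimized by bounded Brent search
  (deterministic; xatol 10⁻¹², bounds ±10·(|β₀| + max|β̂ᵢ|) around the IVW
  start β₀ — far wider than any plausible estimate, and scaling with the
  data so equivariance holds). SE from the observed information of the
  full (γ, β) vector via block inversion. As σ_X → 0 this reproduces
  fixed-effect IVW.
- **MR-Egger**: WLS of b_Y on b_X with free intercept, weights 1/σ_Y²
  (statsmodels WLS under the hood). Coefficient SEs use multiplicative
  residual scaling floored at 1, computed from the unscaled covariance so
  an exact fit stays finite; inference from t(n−2).
- **Weighted median**: ratios sorted, percentile positions
  pᵢ = (cum wᵢ − wᵢ/2)/Σw, linear interpolation at 0.5. SE by parametric
  bootstrap: resample b_X and b_Y from their sampling distributions with
  fixed SEs, recompute the full estimate, take the SD (default 1000
  draws, seed recorded).
- **Weighted mode**: argmax of the weighted Gaussian KDE of the ratios,
  bandwidth h = φ·0.9·min(sd, 1.4826·MAD)·n^(−1/5) floored at 10⁻⁸ (so an
  all-identical panel returns the common ratio), evaluated on a 512-point
  grid spanning the ratios ± 3h — grid resolution is far below reporting
  precision. Bootstrap SE as for the median.

Both median and mode accept `ratio_se = "first_order"` (weights
(b_X/σ_Y)², the default) or `"second_order"` (weights
1/(σ_Y²/b_X² + b_Y²σ_X²/b_X⁴), which admits exposure-side uncertainty and
down-weights weak instruments with large outcome effects).

### Weight-variant sensitivity on the packaged panel

On the 10 retained instruments the median is insensitive to this choice at
reporting precision only in direction, not value: first-order weights give
OR 1.029 per SD decrease, second-order 1.010; the mode gives 1.051 versus
1.007. The published estimates this fixture derives from (both printed as
1.01) are recovered under second-order weighting — the default of the
widely used R tooling — so the reproduction checks for the mode use
`second_order`, while the library default stays first-order for
consistency with the first-order Wald SEs used everywhere else. The
first-order median (1.029) still sits within 0.02 of the published value;
the first-order mode (1.051) does not, which is why the variant matters
and both are exposed.

## Diagnostics

- **Cochran Q** (IVW context): Q = Σwᵢ(β̂ᵢ − β̂_IVW)², wᵢ = (b_X/σ_Y)²,
  df n−1. **Rücker Q′** (Egger context): weighted RSS about the Egger fit,
  df n−2. Chi-square upper-tail p-values.
- **Leave-one-out**: re-estimate (IVW by default, any estimator callable)
  excluding each SNP; the full-panel IVW estimate always lies within the
  convex hull of the leave-one-out estimates (weighted-mean property,
  property-tested).
- **MR-PRESSO**: observed statistic RSS = Σ(b_Yi − β̂₋ᵢb_Xi)²/σ_Yi² with
  β̂₋ᵢ the leave-one-out fixed-effect IVW slope; null distribution from
  parametric simulations b_Xi* ~ N(b_Xi, σ_Xi), b_Yi* ~ N(β̂₋ᵢb_Xi, σ_Yi),
  re-deriving the leave-one-out slopes per simulation (vectorized).
  Monte-Carlo p-values are (1 + #{≥ observed})/(n_sim + 1), floored at
  1/(n_sim+1), never 0; defaults n_sim = 5000, minimum 100. Per-SNP
  outlier p-values compare each observed squared residual with its
  simulated counterparts (invariant to the per-SNP weighting) and are
  Bonferroni-adjusted; when outliers are flagged and at least two SNPs
  remain, a distortion p compares fixed-effect IVW with and without them
  via the two-estimate Cochran Q below. The inverse-variance weighting of
  the RSS follows the canonical formulation of the resampling test; the
  unweighted variant is anticonservative on heteroscedastic panels like
  this one (global p 0.44 vs 0.35 on the packaged panel). Null calibration
  is verified in the suite: 4% rejections at the 5% level over 200 null
  replicates (binomial band 1.9–8.1%).
- **Estimate comparison**: Q = (β̂ₐ − β̂_b)²/(SEₐ² + SE_b²), df 1, for
  comparing the MR estimate with an externally supplied estimate on the
  same scale and sign convention (conventions are checked).

## Synthetic-data generator

`simulate_panel` draws true exposure effects γᵢ ~ U(0.02, 0.15) (matching
the packaged instruments' magnitudes), observed b_X ~ N(γ, σ_X) with
σ_X = 0.012 and b_Y ~ N(β_true·γ + α, σ_Y) with σ_Y = 0.003 (the packaged
panel's typical SEs), so synthetic and fixture panels are numerically
comparable. A configured fraction of instruments is invalid with
pleiotropy α: `balanced` (mean zero), `directional` (non-zero mean, InSIDE
holds — the regime the Egger intercept estimates), or `inside_violated`
(α proportional to γ plus noise, scaled so the invalid-instrument mean
equals the configured value). Panels are oriented like harmonized data
(b_X > 0, jointly flipping b_Y — ratio-invariant). A single root seed
streams per-replicate seeds (`replicate_seeds`); identical configs are
bit-identical. `simulate_gwas_records` additionally emits full GWAS record
tables (chromosome 1, 3-Mb spacing, A/G alleles) and `simulate_ld_blocks`
builds block-LD matrices, so clumping and harmonization are testable
end-to-end.

What the generator does not emulate: LD between instruments used for
estimation (instruments are independent by construction), winner's-curse
selection of instruments, case-control sampling noise beyond the normal
approximation, and allele-frequency errors. Passing recovery tests
therefore shows estimator correctness under the stated generating model,
not robustness to those real-data features.

Verified study conditions (seeded, in the suite): IVW recovers
β_true = 0.05 over 200 replicates of 50 SNPs; the Egger intercept recovers
a directional pleiotropy mean of 0.01 (200 × 100 SNPs) while IVW is
biased; the weighted median beats IVW in absolute bias with 40% invalid
instruments; the weighted mode recovers β_true at 60% invalid instruments
when balanced pleiotropy smears the invalid ratios to both sides, leaving
the valid 40% as the largest weight cluster (plurality validity needs
strong instruments there: γ ~ U(0.1, 0.2), otherwise weak-instrument ratio
noise smears the valid cluster too).

## Pipeline and reporting

`run_pipeline` executes load → clump → harmonize → estimate → diagnose →
report. Estimates, the leave-one-out table, the clumping audit and the
scatter/forest plot data are TSV; diagnostics and provenance (package and
dependency versions, root and per-stage seeds, SHA-256 of the analytic
config) are JSON. Identical config and seed give byte-identical artifacts;
the output directory is excluded from the provenance hash for that reason.
Figure rendering is optional (`--plots`); the plot data files are always
written so figure-level checks need no graphics stack.

## Known reproduction caveats

Two published quantities from the study the fixture derives from do not
reproduce under any faithful computation and are asserted as-published
(hence failing) in the acceptance suite rather than forced:

- The published maximum-likelihood p-value (1.13×10⁻³) is inconsistent
  with the published confidence interval (1.01–1.05 implies z ≈ 2.56,
  p ≈ 1×10⁻²); this package computes p = 1.04×10⁻², in line with that CI
  and with the IVW p-value, as expected for two near-equivalent estimators
  on the same panel.
- The published MR-PRESSO global p (0.29) versus 0.35 computed here on the
  10 retained instruments (stable across seeds at n_sim = 5000). The same
  test on the full 16-SNP pre-clumping panel gives ≈ 0.26, consistent with
  the published value at the original tool's default 1000 simulations —
  the published number may predate clumping. The packaged pipeline tests
  pleiotropy on the post-clumping panel, which is the set the estimates
  actually use.

## Limitations

Wald-ratio weights ignore exposure-side uncertainty by default (the NOME
approximation); bootstrap SEs for median/mode assume normal sampling of
the summary statistics; the distortion test is a simplified two-estimate
comparison rather than the original resampling version; and the clumping
LD stand-in encodes locus membership, not real pairwise r², so it supports
reproduction and testing, not novel locus discovery.
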