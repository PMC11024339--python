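# Methods

`mrlink` implements bi-directional two-sample Mendelian randomization (MR)
on GWAS summary statistics, with a synthetic-data generator that makes every
stage of the analysis testable without external downloads. This note
documents the statistical model, the defaults and why they were chosen, the
numerical conventions, and what the synthetic experiments do and do not
demonstrate.

## The causal model and its assumptions

Two-sample MR treats genetic variants as instrumental variables for an
exposure. For SNP *j* the exposure GWAS reports an effect estimate
β̂<sub>Xj</sub> with standard error σ<sub>Xj</sub>, and the outcome GWAS
(from a different cohort) reports β̂<sub>Yj</sub>, σ<sub>Yj</sub>. If SNP
*j* is a valid instrument — associated with the exposure (relevance),
independent of confounders (independence), and affecting the outcome only
through the exposure (exclusion) — then β<sub>Yj</sub> = θ·β<sub>Xj</sub>
and the Wald ratio β̂<sub>Yj</sub>/β̂<sub>Xj</sub> estimates the causal
effect θ. All estimators here operate on these per-SNP summary pairs; no
individual-level data are modelled.

## Instrument selection

The screening cascade enforces the three IV assumptions with the analysis
constants used throughout:

1. **Relevance.** p < 5×10⁻⁸ and F = (β̂/σ)² > 10, both strict. The F
   statistic guards against weak-instrument bias; at these thresholds the
   p-filter already implies F ≈ 30, so F > 10 is a safety net for
   user-supplied thresholds.
2. **LD independence.** Greedy clumping at r² < 0.001 within ±1 Mb: SNPs are
   visited by ascending p-value (ties broken by chromosome then position for
   determinism); each index SNP discards same-chromosome SNPs within the
   window at r² ≥ 0.001. The window is read as ±1 Mb around the index,
   matching common clumping-tool semantics. Pairs absent from a precomputed
   r² table are kept with a warning rather than silently discarded — the
   conservative choice when the LD reference is incomplete.
3. **Independence from confounders.** A local annotation table (the shape of
   a PhenoScanner export) is screened for the confounders of the
   autoimmune-disease/sarcopenia relationship — smoking, body mass index,
   physical inactivity, malnutrition, extreme sleep duration — and any SNP
   associated with one at p < 5×10⁻⁸ is removed. The screening p-value
   threshold is this package's choice; trait matching is case-insensitive
   and exact.

Records lacking an effect-allele frequency are excluded up front because the
downstream MAF filter cannot be evaluated for them. Only biallelic A/C/G/T
SNPs are accepted anywhere; strand logic is undefined for indels.

## Harmonization

The exposure's allele coding is the fixed reference frame; only the outcome
record is modified. Palindromic SNPs (A/T, C/G) are removed unconditionally
— no frequency-based strand inference is attempted. Outcome alleles are
matched as-is, order-swapped (negating β and complementing the frequency),
strand-complemented, or complemented-and-swapped; anything else is
incompatible and dropped. After alignment, the MAF > 0.01 filter is applied
strictly on **both** sides (a missing frequency drops the SNP) — which side
the filter applies to is underdetermined in common practice, and both-sides
is the certifiable choice. Every input instrument is accounted for exactly
once across the harmonized pairs and the drop log.

## Estimators

All five estimators use first-order Wald-ratio weights w<sub>j</sub> =
β̂²<sub>Xj</sub>/σ²<sub>Yj</sub> (equivalently, ratio SE σ<sub>Yj</sub>/|β̂<sub>Xj</sub>|),
the convention under which the ratio meta-analysis and the weighted
through-origin regression of β̂<sub>Y</sub> on β̂<sub>X</sub> coincide.

- **IVW**: θ̂ = Σw<sub>j</sub>r<sub>j</sub>/Σw<sub>j</sub>; fixed-effect
  SE = (Σw<sub>j</sub>)^(−1/2). Cochran's Q = Σw<sub>j</sub>(r<sub>j</sub>−θ̂)²
  with k−1 df; when its p-value is < 0.05 the multiplicative random-effects
  SE (fixed SE × max(1, √(Q/(k−1)))) is used instead — the floor at 1 means
  under-dispersion never shrinks the SE.
- **MR-Egger**: SNPs are oriented to β̂<sub>X</sub> ≥ 0, then
  β̂<sub>Y</sub> = α + θβ̂<sub>X</sub> is fit by weighted least squares; the
  intercept α estimates directional pleiotropy. SEs are scaled by
  φ = max(1, √(RSS<sub>w</sub>/(k−2))) and inference uses t(k−2).
- **Weighted median**: the weighted 50% quantile of the ratios, linearly
  interpolated between cumulative weight midpoints; consistent while valid
  instruments carry ≥ 50% of the weight. Its SE comes from a parametric
  bootstrap (default 1000 draws, seeded): both β̂<sub>X</sub> and
  β̂<sub>Y</sub> are resampled from normals at their observed values and the
  whole estimator recomputed.
- **Penalized weighted median**: each SNP's weight is multiplied by
  min(1, 20·p<sub>j</sub>), p<sub>j</sub> being the χ²(1) upper tail of its
  Q contribution at the unpenalized estimate, then the weighted median is
  recomputed; gross outliers are effectively removed. The penalty constant
  20 makes the penalty inactive (20·p ≥ 1) for any SNP with p ≥ 0.05.
- **Maximum likelihood**: θ̂ minimizes
  L(θ) = Σ(β̂<sub>Yj</sub> − θβ̂<sub>Xj</sub>)²/(σ²<sub>Yj</sub> + θ²σ²<sub>Xj</sub>),
  the profile objective of the bivariate normal measurement model, which —
  unlike IVW — accounts for exposure-side sampling error. It is solved by
  bounded scalar minimization bracketed around the IVW estimate (half-width
  10× max(|θ̂<sub>IVW</sub>|, 5 SE), widened if the optimum pins a bound;
  tolerance 1e-10), with SE from the central-difference curvature of L/2.
  In the σ<sub>X</sub> → 0 limit it reduces to fixed-effect IVW.

Confidence intervals use z = 1.959964 on the β scale for all methods;
MR-Egger p-values use t(k−2). Binary outcomes are reported as odds ratios by
exponentiating β and the CI bounds (the SE stays on the log scale, and the
p-value is unchanged). Minimum instrument counts: 2 for IVW and maximum
likelihood, 3 for MR-Egger and both medians; a pair below a method's minimum
records that method as not estimable instead of failing the run.

## MR-PRESSO

The global test compares the observed leave-one-out weighted residual sum of
squares with its Monte-Carlo distribution: for each SNP *j* the
through-origin IVW slope θ̂₋ⱼ is fit without it, the observed residual is
w<sub>j</sub>(β̂<sub>Yj</sub> − θ̂₋ⱼβ̂<sub>Xj</sub>)², and each of n_sim
(default 1000) simulated datasets draws β̂*<sub>X</sub> ~ N(β̂<sub>X</sub>, σ<sub>X</sub>)
and β̂*<sub>Yj</sub> ~ N(θ̂₋ⱼβ̂<sub>Xj</sub>, σ<sub>Yj</sub>) and repeats
the whole leave-one-out computation. Monte-Carlo p-values carry the +1
correction (global p ≥ 1/(n_sim+1) always); per-SNP outlier p-values are
Bonferroni-multiplied by k and capped at 1, flagged at 0.05. Note the
Bonferroni product imposes a detectability floor of k/(n_sim+1): per-SNP
outlier detection needs n_sim ≳ 20k to be able to reach 0.05 at all, which
is why outlier experiments here use n_sim = 1000 while null-calibration
sweeps (which only consult the global p) can run at n_sim = 200. The
pipeline iterates test-and-remove until no outlier is flagged, fewer than 4
SNPs remain (≥ 3 are needed for stable leave-one-out slopes), or 10 rounds
have run. The distortion test is intentionally omitted; output metadata says
so.

## The bi-directional driver

The study design crosses the exposure set with the outcome set, then swaps
roles. The per-direction significance threshold is Bonferroni-corrected:
α/n where n is that direction's number of exposures (0.05/6 = 0.0083…,
printed 0.008; 0.05/8 = 0.00625, printed 0.006). Gating uses the exact
threshold; the report carries both exact and printed values, since the
rounding is presentational. The significance flag derives solely from the
IVW p-value — the other four methods are reported as concordance checks.
Pairs are processed in sorted (exposure, outcome) order and all randomness
expands deterministically from one master seed, so runs are bit-reproducible.

## The synthetic-data generator

The generator works directly on the summary-statistic scale: simulating
individual-level genotypes would add nothing, because two-sample MR consumes
only (β̂, σ) pairs. Per instrument, a true effect γ<sub>j</sub> ~ N(0, γ_sd)
is resampled until genome-wide significant at the SNP's sampled SE, and the
observed effect γ<sub>j</sub> + noise is redrawn (bounded retries) until the
observed p is also < 5×10⁻⁸ — so generated instruments pass the relevance
screen by construction. The outcome effect is
θγ<sub>j</sub> + α<sub>j</sub> + noise, with the direct (pleiotropic) path
α<sub>j</sub> set by the configured model. Directional and outlier effects
are applied on the exposure-increasing orientation (multiplied by
sign(γ<sub>j</sub>)): this is the convention under which a common direct
effect biases every Wald ratio the same way, i.e. genuinely *directional*
pleiotropy; without it, symmetric instrument signs would turn a constant
direct effect into sign-balanced ratio noise.

Defaults describe a well-powered biobank-scale pair: 200 SNPs with 30
instruments, per-SNP SEs uniform on [0.015, 0.025], γ_sd = 0.15 (instrument
z-scores ~6–10), MAF uniform on [0.05, 0.5], 200,000 samples recorded per
GWAS, and no pleiotropy, palindromes, strand flips, LD, or confounders
unless configured. The LD panel (500 samples) generates block-correlated
dosages from shared latent factors with loading √r, giving expected
within-block correlation r and ~0 across blocks; blocks are placed 2.5 Mb
apart so distinct loci never fall in one clump window. Confounder-labeled
SNPs receive an annotation to one of the five screened traits at
p ∈ [10⁻²⁰, 10⁻⁸·⁵]; some other SNPs get neutral-trait annotations above
threshold so the screen is exercised in both directions. The study-level
generator (`simulate_study`) places all traits on one shared SNP map with
disjoint per-trait instrument sets and a sparse causal-effect matrix, so any
trait's instruments can be looked up in any other trait's table.

**What the generator does not emulate:** winner's curse beyond the
observed-significance redraw (no truncation-corrected effect sizes),
sample overlap between cohorts, population stratification or relatedness,
LD between causal variants and instruments (the panel only drives clumping,
deliberately decoupled from effect simulation), allele-frequency-dependent
effect-size architecture, and indels/multi-allelic variation. Calibration
results on these data therefore certify the pipeline's statistical
correctness under its own assumptions, not robustness to those real-data
complications.

## Numerical conventions and degenerate inputs

- Clump ties at equal p-value resolve by (chromosome, position).
- SNPs with β̂<sub>X</sub> = 0 have no defined ratio and are dropped with a
  warning before ratio-based estimation.
- p-values are clamped into (0, 1] (two-sided normal tails can underflow).
- Weighted-median weight sums of zero and all-zero penalized weights raise
  explicit degenerate-input errors (penalty constant 0 is such a case).
- Monte-Carlo and bootstrap seeds are explicit parameters everywhere;
  the pipeline derives per-pair seeds from the master seed via
  `numpy.random.SeedSequence` spawn keys.
- Sumstats files serialize floats at 17 significant digits; round trips are
  exact to at least 12.

## Experiment sizes

The calibration experiments run at fixed sizes chosen to make their
Monte-Carlo error small relative to the quantities checked: type-I error and
CI coverage over 1000 replicates (binomial SE ≈ 0.007), estimator-robustness
comparison over 500, MR-PRESSO outlier detection over 100 with n_sim = 1000,
oracle agreement over 200 random instances, and the full 6×8 bi-directional
demonstration over a 200-SNP shared map with 12 instruments per trait,
n_sim = 200 and 200 bootstrap draws. The same sizes are used by
`scripts/acceptance.py`.

## Known limitations

- Only detection/removal of MR-PRESSO outliers is implemented; the
  distortion test is out of scope.
- No proxy-SNP substitution: instruments absent from the outcome GWAS are
  dropped, not rescued through LD proxies.
- No Steiger filtering, MR-RAPS, mode-based estimation, or multivariable MR.
- The IEU OpenGWAS/PhenoScanner network services are not queried; inputs are
  local files with documented schemas.
- Odds ratios are exp(β) of the log-odds causal estimate; no rescaling to
  per-SD exposure units is attempted.
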