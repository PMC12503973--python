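# Methods

`protmr` implements a proteome-wide two-sample Mendelian-randomization
(MR) pipeline for drug-target triangulation: circulating protein levels
are the exposures, a binary disease is the outcome, and genetic
variants near each protein-coding gene (cis-pQTLs) are the instruments.
Every stage operates on GWAS/pQTL summary statistics only; no
individual-level data are required.

## 1. Model

For protein $k$ with instruments $j = 1,\dots,J$, let
$\hat\beta_{X_j}$ (SE $\sigma_{X_j}$) be the per-allele effect of
variant $j$ on protein level (standardized units) and $\hat\beta_{Y_j}$
(SE $\sigma_{Y_j}$) its log-odds effect on disease. Under the
instrumental-variable assumptions (relevance, independence from
confounders, exclusion restriction), each variant provides a ratio
estimate of the causal effect $\gamma_k$:

$$\hat\gamma_j = \hat\beta_{Y_j} / \hat\beta_{X_j}.$$

The exposure and outcome samples are assumed non-overlapping, so the
two sets of sampling errors are independent (the NO-overlap part of the
standard two-sample design). Effects are reported as odds ratios per
standard-deviation increase in protein level, $\mathrm{OR} = e^{\gamma}$.

## 2. Instrument selection

1. **Cis window**: variants within 1 Mb of the gene body
   (`select_cis`, `window_bp = 1_000_000`). Cis instruments are
   preferred because their pathway to the outcome plausibly runs
   through the encoded protein.
2. **Significance**: pQTL $p < 5\times 10^{-8}$ (strict inequality).
3. **LD clumping** (`ld_clump`): greedy by ascending p-value (ties
   broken by position, then identifier); a retained index variant
   removes all variants with $r^2 \ge 0.1$ within 1000 kb. A stricter
   preset `CLUMP_STRICT` ($r^2 < 0.001$, 10 000 kb) is provided for
   sensitivity analyses.
4. **Strength**: per-variant $R^2 = 2f(1-f)\beta^2$ for effect-allele
   frequency $f$ and standardized $\beta$; the F-statistic is
   $F = R^2 (N - K - 1) / ((1 - R^2) K)$ with $K=1$ per variant
   (`formula_variant="standard"`). A variant of the formula with
   $(1+R^2)$ in the denominator is available as
   `formula_variant="as_printed"` for reproducing published tables
   that use that convention; for realistic $R^2 \ll 1$ the two differ
   negligibly. Instruments require $F > 10$ (strict).

## 3. Harmonization

Exposure and outcome records are joined on variant ID and aligned to
the exposure effect allele, flipping outcome signs (and EAF) when the
allele pairs are swapped. Palindromic (A/T, G/C) variants are dropped
unless the EAF is far from 0.5 (`palindromic_eaf_limit = 0.42`, i.e.
kept only if EAF < 0.42 or > 0.58, where strand can be inferred).
Allele mismatches are dropped with an explicit reason; nothing is
silently discarded.

## 4. Estimator suite

- **Wald ratio** ($J=1$): $\hat\gamma = \hat\beta_Y/\hat\beta_X$ with
  first-order delta SE
  $\sqrt{\sigma_Y^2/\hat\beta_X^2 + \hat\beta_Y^2\sigma_X^2/\hat\beta_X^4}$.
- **IVW**: inverse-variance weighted mean of ratios with weights
  $w_j = (\hat\beta_{X_j}/\sigma_{Y_j})^2$ (second-order terms
  ignored, the usual 2SLS-equivalent form). Fixed-effect SE
  $(\sum w_j)^{-1/2}$; the multiplicative-random-effects variant
  scales the SE by $\sqrt{\max(1, Q/(J-1))}$ — floored at 1 so random
  effects never yield a smaller SE than fixed.
- **Cochran's Q**: $Q=\sum_j w_j(\hat\gamma_j - \hat\gamma_{IVW})^2
  \sim \chi^2_{J-1}$ under homogeneity.
- **MR-Egger** ($J\ge 3$): WLS of $\hat\beta_Y$ on $\hat\beta_X$ with
  intercept, after orienting all instruments to $\hat\beta_X \ge 0$
  (InSIDE parameterization). Inference uses a $t$ reference with
  $J-2$ df and residual variance floored at 1 (multiplicative
  overdispersion only). The intercept estimates the mean directional
  pleiotropy; its test (p < 0.05) is the pleiotropy flag.
- **Weighted median** ($J\ge 3$): order the ratio estimates, walk the
  cumulative normalized weights $S_j = \sum_{i\le j} w'_i - w'_j/2$,
  and linearly interpolate to $S = 1/2$. The SE comes from a
  parametric bootstrap (default 1000 draws, seeded) that re-perturbs
  $\hat\beta_X$ and $\hat\beta_Y$ from their SEs.
- **Simple / weighted mode** ($J\ge 3$): mode of a Gaussian KDE over
  the ratio estimates on a 512-point grid, Silverman bandwidth times a
  tuning factor $\phi = 1$; the weighted variant weights the KDE by
  $w_j$. Bootstrap SE as above.
- **MR-PRESSO** ($J\ge 4$): the global observed statistic is the IVW
  residual sum of squares where each variant's prediction uses the
  leave-one-out (LOO) IVW slope. The null distribution is simulated
  (default 1000 draws) by regenerating *both* sides —
  $\beta_X^{sim} \sim N(\hat\beta_X, \sigma_X)$,
  $\beta_Y^{sim} \sim N(\hat\gamma_{LOO}\beta_X^{sim}, \sigma_Y)$ —
  and recomputing the per-simulation LOO slopes, so the null RSS
  carries the same exposure-side and LOO-estimation noise as the
  observed one (omitting either makes the test anticonservative).
  Empirical p-values use the $(1+x)/(1+n)$ correction. Per-variant
  outlier p-values are Bonferroni-adjusted by $J$; flagged outliers
  are removed and IVW re-run to give the outlier-corrected estimate.

## 5. Adjudication

Heterogeneity flag: Cochran's Q p < 0.05. Pleiotropy flag: Egger
intercept p < 0.05 or MR-PRESSO global p < 0.05. The primary estimate:

- $J = 1$ → Wald ratio;
- no flags → fixed-effect IVW;
- heterogeneity only → the more conservative (largest p) of
  weighted median and multiplicative-random-effects IVW;
- pleiotropy only → the more conservative of MR-Egger and the
  PRESSO outlier-corrected IVW;
- both → the most conservative of all four, ties resolved in the
  listed order.

Discovery significance is Bonferroni: $p < 0.05/m$ (strict), with $m$
the number of proteins carrying a valid primary estimate. Replication
requires the replication cohort to reach its own Bonferroni threshold
with a direction-consistent estimate.

## 6. Colocalization

Wakefield asymptotic Bayes factors per variant:
$\log \mathrm{ABF} = \tfrac12\log(1-r) + \tfrac12 r z^2$ with
$r = W/(W+V)$, $V$ the squared SE, and prior effect variance
$W = 0.15^2$ for quantitative traits, $0.2^2$ for case-control.
Hypotheses H0–H4 (no signal / trait-1 only / trait-2 only / two
distinct variants / one shared variant) are enumerated with priors
$p_1 = p_2 = 10^{-4}$, $p_{12} = 10^{-5}$, accumulated in log space by
log-sum-exp; H3 is the off-diagonal sum computed as "product of sums
minus diagonal" with a cancellation guard. A locus colocalizes when
PP(H4) > 0.80 (strict).

## 7. SMR and HEIDI

At the top cis variant, $T_{SMR} = z_X^2 z_Y^2/(z_X^2+z_Y^2) \sim
\chi^2_1$. HEIDI tests whether the SMR ratio is constant across the LD
block: eligible variants have $r^2$ with the top variant in
$[0.05, 0.9]$ and pQTL $z^2 > 10$, capped at the 20 highest-$r^2$
variants, minimum 3 (otherwise HEIDI is not applicable and the protein
cannot pass). The differences $d_i = \hat b_{SMR}(i) - \hat b_{SMR}(top)$
get a first-order delta-method covariance using the LD correlations;
$\sum z_{d_i}^2$ is a weighted sum of $\chi^2_1$ with weights the
eigenvalues of the correlation matrix of $z_d$. Its tail probability
is computed by Imhof's numerical inversion of the characteristic
function (adaptive quadrature, accepted only when the estimated error
is below $10^{-4}$), with a Satterthwaite-Welch two-moment chi-square
fallback. The two-moment approximation alone can err by more than 0.01
for skewed eigenspectra, which is why inversion is the default.
A protein passes triangulation when SMR $p < 0.05/m$ and HEIDI
$p > 0.05$.

## 8. Synthetic data generator

The generator works at the summary level (no genotypes): marginal
standardized effects are $R b$ for joint effects $b$ and LD matrix
$R$, observed effects are drawn from $N(Rb, R/n_{\text{eff}})$, and
per-allele effects divide by $\sqrt{2f(1-f)}$. For a binary outcome,
$n_{\text{eff}} = n \cdot cf (1-cf)$ with case fraction $cf$. LD is
AR(1): $R_{ij} = \rho^{|i-j|}$.

Defaults model the study conditions: exposure GWAS $N = 35{,}000$,
outcome GWAS $N = 350{,}000$, case fraction 0.03, per-variant F drawn
uniformly in (50, 500), causal effects $\gamma \in \{0.3, 0.5\}$,
exposure (pQTL) effect 0.15 (0.25 in "well-powered" scenarios).
Locus architectures H0–H4 mirror the colocalization hypotheses;
H3 places the two causal variants `linkage_separation` positions
apart. Directional pleiotropy is planted on the exposure-increasing
allele (mean/sd of the direct effect), and a configurable fraction of
instruments receive large outliers (`outlier_scale` outcome SEs).
Heterogeneity at large $\gamma$ arises naturally from the NOME
violation (finite instrument strength), not from an injected term.

What the generator does **not** emulate: sample overlap between
exposure and outcome, population stratification, winner's curse in
instrument selection, trans-pQTL effects, imputation quality, or
non-AR(1) LD.

All randomness flows from a single integer seed; sub-seeds are derived
with `rng.integers(0, 2**31 - 1)` so every component stays below
$2^{31}$.

## 9. Numerical choices

- Log-space accumulation (log-sum-exp) for all colocalization sums;
  the H3 cancellation guard returns PP3 = 0 rather than a negative
  probability when the diagonal dominates.
- Empirical p-values use $(1+x)/(1+n)$ so no simulated p is exactly 0.
- The MRE scale and the Egger residual variance are floored at 1.
- Bootstrap and simulation routines take explicit seeds; identical
  inputs and seeds reproduce byte-identical results.
- Imhof integration suppresses `IntegrationWarning`; correctness is
  guarded by the returned error estimate, not by convergence warnings.

## 10. Limitations

- Second-order terms in the IVW weights and the Wald delta SE are
  ignored; with weak instruments ($F \lesssim 10$) estimates are
  regression-diluted — hence the strict F filter.
- The adjudication tree is a fixed rule, not a model average; its
  "most conservative" choice can be underpowered when heterogeneity
  comes from NOME violation rather than pleiotropy.
- Colocalization assumes at most one causal variant per trait per
  locus and shared, well-estimated LD.
- HEIDI loses power (and is skipped) at loci with fewer than 3
  eligible LD partners.
- The generator's AR(1) LD and non-overlapping-sample assumption make
  calibration results optimistic relative to real cohorts.
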