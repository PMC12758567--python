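# Methods

This note documents the statistical machinery in `microdyad`: the models
and their assumptions, the defaults and why they were chosen, what the
synthetic-cohort generator does and does not emulate, and the numerical
choices that affect results.

## Study design being modelled

The package targets dyadic longitudinal cohorts: N mother–infant pairs,
each contributing stool samples and questionnaires at three waves
(approximately 1, 7 and 14 months postpartum). Four per-dyad channels are
analyzed jointly: infant gut diversity (IM), maternal gut diversity (MM),
one infant temperament scale (IT; negative emotionality NEG or regulation
REG, fitted as two parallel model variants), and maternal depressive
symptoms (MD, a 0–30 summed questionnaire score). Not every dyad
contributes every wave; missingness is handled inside the sampler.

## Alpha diversity

Chao1 is computed in its bias-corrected form
`Ŝ = S_obs + F₁(F₁−1)/(2(F₂+1))`, which stays defined when no doubletons
are present; the classic `F₁²/(2F₂)` variant is exposed via
`bias_corrected=False` and falls back to the corrected form at `F₂ = 0`.
Chao1 requires integer counts — singleton/doubleton statistics are
meaningless after total-sum scaling, so normalized tables are rejected.
Shannon entropy uses the natural log by default (`base` is exposed).
Identical code paths serve taxa tables and functional-term tables; for
functional terms only richness (Chao1) is of biological interest.

## Covariate PCA

Covariate tables mix units (ages, BMI, income brackets, binary exposure
flags), so PCA runs on the correlation matrix: categoricals are one-hot
encoded (first level dropped), missing cells mean-imputed, columns
z-scored, and the correlation matrix eigendecomposed. Constant columns are
dropped with a warning. The first four score columns (PC1–PC4) are the
fixed adjustment set everywhere downstream; four components is a design
constant of the targeted analysis, not chosen by scree. Component signs
follow the convention "the variable with the largest |loading| loads
positive", making scores — and hence every downstream coefficient —
reproducible.

## Trajectory mixed model

Diversity is modelled as
`value ~ wave + role + wave:role + PC1..PC4 + (1 | subject)` with
treatment coding (references: wave T1, role infant). Mothers and infants
are distinct subjects, so the random intercept is per person even within
a dyad. Estimation is REML with the restricted likelihood profiled down
to the single variance ratio λ = τ²/σ²; the group-block structure makes
each evaluation O(p²·groups), and λ is maximized by bounded scalar search
on the log scale with the λ = 0 boundary always checked (flat maternal
trajectories can put τ̂² on the boundary, in which case the fit equals
OLS and this is logged). Wald tests use the normal approximation — with
several hundred observations the difference from finite-df corrections is
negligible, and no df method is imposed.

Significant interactions are probed with nine pairwise contrasts on
estimated marginal means (covariates at their sample means): the three
wave pairs within each role and infant-vs-mother at each wave. These are
the comparisons of scientific interest; the remaining six cross cells
(e.g., infant T1 vs mother T3) are not tested. Bonferroni uses m = 9.

## Bayesian RI-CLPM

The panel model is, for dyad i, channel k, wave t:

```
t = 1 :  y = α[k,1] + γₖ'xᵢ + u[i,k] + ε[i,k,1]
t > 1 :  y = α[k,t] + Σⱼ B_t[k,j]·y[i,j,t−1] + γₖ'xᵢ + u[i,k] + ε[i,k,t]
```

with `u[i,k] ~ N(0, τₖ²)` independent across channels and residuals
independent across channels within a wave — the model is strictly
longitudinal and deliberately fits no within-wave covariance paths. Lag
matrices are wave-specific (T1→T2 and T2→T3 each get their own B), since
lagged effects over a 1→7-month interval need not equal those over
7→14 months. This is the lagged-observed-variable formulation with
additive random intercepts; the latent within/between decomposition is a
known alternative and is deliberately not implemented (see Limitations).

**Priors.** Regression coefficients (α, B, γ) carry flat uniform priors
on ±c_max with c_max = 100 on the standardized scale — effectively
uninformative; variances (τₖ², σ[k,t]²) carry InverseGamma(a = 2, b = 1).
All hyperparameters are configuration fields. A widening check (c_max ×10
leaves every draw unchanged when no draw hits the bounds) is part of the
test suite.

**Sampler.** Every full conditional is conjugate, so estimation is plain
Gibbs: per channel, the stacked heteroscedastic regression for
(α, B, γ) yields a Gaussian draw (rejection against the ±c_max box, which
in practice never binds); random intercepts and variances follow Gaussian
and inverse-gamma conditionals; missing cells are drawn from their
Gaussian full conditionals (data augmentation, valid under MAR) — a
missing cell at wave t < 3 receives information both from its own
equation and from every wave-t+1 outcome it predicts. Chains are
independent with seeds spawned from one seed sequence; defaults are
4 chains × 4000 iterations, 2000 burn-in, thin 2 (4000 retained draws),
which gives R-hat < 1.05 and ESS in the hundreds for the ~70-parameter
model at cohort sizes around 120–300 dyads. Split-chain R-hat and ESS are
computed via ArviZ.

**Decision rule.** A path is reported significant when its equal-tailed
95% credible interval excludes zero. The packaged
`coverage_experiment` measures what this rule delivers under repeated
sampling: with 20 replicates at 150 dyads the mean coverage of
nonzero-truth paths is ≈ 0.92 and the mean excludes-zero rate on
zero-truth paths ≈ 0.06 (see `scripts/acceptance.py`; the experiment
scales to any replicate count).

**Standardization.** Channels are z-scored internally by default
(means/SDs retained), since raw channel scales differ by orders of
magnitude (Chao1 in the hundreds vs 0–30 questionnaire sums) and a shared
coefficient prior is only meaningful on a common scale. Recovery and
calibration experiments instead fit the raw generator scale
(`standardize=False`) so posterior paths are directly comparable to the
generator's lag matrices.

## Per-feature association stage

Counts are total-sum scaled; features must reach 1% relative abundance in
at least ⌈10% · n⌉ samples (ceiling, so with 10 samples a single qualifying
sample suffices); surviving features are transformed as `log(x + δ_f)`
with δ_f = half the feature's minimum positive relative abundance.
Each feature is then fitted with the same REML engine as the trajectory
model: fixed effects NEG, REG, MD, age in months at assessment
(continuous), PC1–PC4; random intercept per subject; separate analyses
for infant-sample and mother-sample tables (temperament always attaches
to the dyad's infant and depression to the dyad's mother). BH adjustment
is applied jointly across the feature × {NEG, REG, MD} family within a
role; age and PC terms are adjustment covariates, not hypotheses, and
keep q = NaN. Significance is q < 0.05. The BH step-up is implemented
directly (NaN p-values are excluded from the family and propagate as NaN
q with a warning) and is tested for exact agreement with a brute-force
"min over the tail" oracle and with statsmodels.

## Synthetic cohort generator

Defaults encode the targeted study conditions: 121 dyads × 3 waves × 2
roles; a 4-channel Gaussian panel with dyad random intercepts
(τ = 0.5–0.7), residual SD 0.8, autoregressive paths 0.3–0.5 and three
modest cross-lags (temperament→infant diversity −0.25, infant
diversity→temperament −0.15, depression→maternal diversity −0.10); wave
intercepts that push infant diversity up across waves while maternal
diversity stays flat; four standard-normal latent covariates with small
(0.15) channel effects, observed only through a noisy 10-column covariate
table so that the PCA stage has real work to do; 29% of dyad-wave cells
missing completely at random, reproducing a cohort in which roughly 514
of 726 possible stool samples are observed.

Counts are realized per sample as follows. The number of present taxa S
scales the role/wave richness profile (infant 60→110→160, mother flat at
230) by `1 + 0.2·z`, where z is the standardized diversity-channel value —
the monotone link the recovery tests rely on. A dominant block of up to 12
taxa, drawn from role/wave-appropriate genus pools (Bifidobacterium /
Escherichia for infants at T1–T2, adult-type genera otherwise), receives a
fixed mass share (infant 0.85→0.75→0.60, mother 0.5) distributed by
stick-breaking Beta(1, θ) — the dominance knob. The remaining mass is
spread over the other S − 12 taxa by a heavy-tailed Dirichlet
(Gamma(0.5) variates), which keeps rare taxa, singletons and doubletons in
the table while leaving nearly all S taxa observable at the default
sequencing depth. A pure stick-breaking construction over all S taxa was
rejected: its geometric weight decay makes observed richness saturate
around 30 taxa regardless of S at realistic depth, which would destroy the
infant-rising/mother-flat richness structure the generator must emulate.
Depth is rounded log-normal with mean 50,000 reads (log-SD 0.3), counts
multinomial.

Behavior-linked "signal" taxa are always present in the relevant role's
samples at a 2% base relative abundance, multiplied by
`exp(effect · z_scale + biological noise)` where z_scale is the
standardized behavior score and the biological noise is log-normal with
SD 0.8 — without it the taxa would be implausibly deterministic and their
Wald SEs meaninglessly small. Mass is renormalized afterwards, so planted
log-abundance effects are attenuated by a few percent (compositional
closure plus the log pseudocount); recovery tests measure effects on the
transformed scale the models actually see.

Questionnaire scores are affine maps of the latent channels: NEG on a 1–7
scale (rounded to 2 decimals), MD on the integer 0–30 range; REG is a
companion scale anti-correlated with NEG (−0.4 on the latent scale) with
its own subject-stable component, so the REG model variant has realistic
within-person structure. Visit ages are jittered around 1, 7 and 14
months.

**What the generator does not emulate** — and what passing tests
therefore do not show about real data: taxa are exchangeable labels with
no phylogeny; missingness is MCAR (no informative dropout); panel
dynamics are linear-Gaussian with no within-wave residual covariance
(matching the fitted model — recovery tests cannot detect
misspecification the generator does not produce); questionnaire scores
have no item-level structure or floor/ceiling pile-ups beyond clipping;
sequencing depth is independent of biology.

## Numerical choices

- REML: λ searched on the log scale in [1e-10, 1e8] with the exact λ = 0
  boundary candidate; ties at the boundary resolve to OLS. Singular
  designs are rejected with the aliased columns named (QR pivoting).
- Gibbs: near-singular conditional precisions are jittered (1e-8 ridge)
  with a warning; coefficient draws are rejection-sampled against the
  prior box and clipped only after 1000 failures (never observed with
  default priors).
- Missing-cell initialization: observed channel-wave mean.
- Posterior summaries: equal-tailed percentiles pooled across chains;
  split R-hat/ESS from ArviZ; `summarize` refuses fewer than 100 retained
  draws per chain or fewer than 2 chains.
- The prevalence threshold uses the ceiling of the sample-count product;
  filtering operates on TSS-normalized values (a 1% abundance rule is
  only meaningful on the relative scale).
- All randomness flows through numpy `SeedSequence`; reruns with one seed
  are bit-identical, and the pipeline manifest hashes the
  analysis-relevant configuration (output location excluded).

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 100–150 random vectors
for the estimator oracles; a 6×4 balanced design for the REML closed
form; 200 dyads (plus a 1000-dyad Monte-Carlo reference for expected cell
means) for trajectory recovery; 200 observations / 4000 draws for the
conjugate-posterior check; 300 dyads with a planted standardized
cross-lag of 0.6 for RI-CLPM recovery; 20 replicates × 150 dyads for
interval calibration; a 121-dyad realization at 20% MCAR for the
augmentation check; 20 replicates × 150 dyads × 200 features (10 signal)
for FDR/sensitivity; and a 40-dyad cohort run twice for end-to-end
determinism. These sizes keep each experiment in the seconds-to-a-minute
range while leaving the measured rates well inside their target bands;
every experiment accepts larger sizes through its parameters.

## Known limitations

- The RI-CLPM random intercept is per channel and independent across
  channels; correlated intercepts (e.g., a shared dyad-level factor) are
  not implemented.
- The lagged-observed-variable formulation estimates different quantities
  than the latent within/between RI-CLPM decomposition when intercept
  variance is large; conclusions about "within-person" paths carry that
  caveat.
- Wald inference in the mixed models has no small-sample df correction;
  with fewer than ~20 subjects per role, p-values will be optimistic.
- Data augmentation assumes MAR; informative missingness biases paths.
- The association stage models log relative abundances with Gaussian
  errors; zero-inflated or count-level alternatives are out of scope.
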