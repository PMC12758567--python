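# microdyad

Dyadic longitudinal analysis of gut-microbiome diversity and behavior for
mother–infant cohorts observed over repeated postpartum waves (here T1, T2,
T3 ≈ 1, 7 and 14 months). The package is aimed at researchers who collect
stool-derived taxa (or functional-term) count tables alongside infant
temperament and maternal depression questionnaires and want to ask two
questions: *how do microbial communities change over the first year within
mothers and infants*, and *do microbiome and behavior predict each other
across time, within person and across the dyad?*

## What it computes

1. **Alpha diversity** per sample: bias-corrected Chao1 richness
   `Ŝ = S_obs + F₁(F₁−1) / (2(F₂+1))` and Shannon entropy `H = −Σ pₖ ln pₖ`.
2. **Covariate reduction**: correlation-matrix PCA of an arbitrary
   sociodemographic/health covariate table; the first four scores
   (PC1–PC4) are the adjustment set everywhere downstream.
3. **Group trajectories**: a REML random-intercept linear mixed model of
   diversity on time, role (infant/mother), their interaction and PC1–PC4,
   with nine Bonferroni-corrected post-hoc contrasts on estimated marginal
   means (within-role wave pairs and infant-vs-mother at each wave).
4. **Bayesian random-intercept cross-lagged panel model (RI-CLPM)** — the
   core inference. Four channels per dyad *i* (IM = infant diversity,
   MM = maternal diversity, IT = infant temperament, MD = maternal
   depression) evolve as

   ```
   y[i,k,t] = α[k,t] + Σⱼ B_t[k,j]·y[i,j,t−1] + γₖ'xᵢ + u[i,k] + ε[i,k,t]
   u[i,k] ~ N(0, τₖ²),   ε[i,k,t] ~ N(0, σ[k,t]²)
   ```

   with wave-specific lag matrices `B_t` (diagonal = autoregressive,
   off-diagonal = cross-lagged paths), dyad random intercepts, and no
   within-wave covariance paths. Estimation is by Gibbs sampling —
   uniform ±c_max priors on coefficients, inverse-gamma priors on
   variances, Gaussian data augmentation for missing cells — and a path
   is "significant" when its 95% equal-tailed credible interval excludes
   zero. Two model variants (temperament = negative emotionality or
   regulation) build from the same inputs.
5. **Per-feature associations**: TSS normalization, a 1%-abundance /
   10%-prevalence filter, log transform with a half-minimum pseudocount,
   then one random-intercept mixed model per feature with temperament,
   depression, age in months and PC1–PC4 as fixed effects, BH-adjusted
   at q < 0.05, separately for infant and mother samples.
6. **Synthetic cohorts**: a generator that emulates the targeted study
   design (121 dyads, rising infant richness under flat maternal richness,
   early Bifidobacterium/Escherichia dominance, behavior-linked taxa,
   ~29% missing cells) so every stage has ground truth to recover.

## Worked example

```python
from microdyad import (TrueParams, simulate_cohort, diversity_table,
                       reduce_covariates, fit_trajectory, build_panel,
                       DyadicRICLPM, RiclpmSpec, FeatureAssociation)

cohort = simulate_cohort(TrueParams(n_dyads=60, seed=5))
div = diversity_table(cohort.counts, "chao1", metadata=cohort.metadata)
print(div.groupby(["role", "wave"])["value"].mean().round(1))
```

```
role    wave
infant  T1       50.8
        T2      105.7
        T3      173.7
mother  T1      219.5
        T2      218.5
        T3      229.9
```

Infant richness triples across waves while maternal richness stays flat and
higher — the diverging-trajectories pattern the cohort design targets. The
mixed model quantifies the divergence as a time-by-role interaction:

```python
pcs = reduce_covariates(cohort.covariate_table, 4)
fit = fit_trajectory(div, pcs.scores)
# -> interaction role[mother]:wave[T3]: B=-107.48, SE=8.44, t=-12.73
```

i.e. mothers gain ~107 fewer Chao1 units than infants between T1 and T3.
The RI-CLPM then asks whether the channels forecast each other:

```python
panel = build_panel(div[["sample_id", "value", "subject_id", "dyad_id",
                         "role", "wave"]],
                    cohort.behavior, cohort.metadata, pcs.scores,
                    temperament="NEG")
model = DyadicRICLPM(RiclpmSpec(n_chains=2, n_iter=1500, n_burn=500,
                                thin=1, seed=5)).fit(panel)
print(model.significant_paths_)
# -> ['beta[MM<-IT:T1->T2]', 'beta[MD<-MD:T1->T2]', 'beta[MD<-MD:T2->T3]']
```

The depression autoregressive paths are genuine generator truth; at 60
dyads and short chains the path set is noisy (one spurious cross-lag here),
which is exactly what the packaged calibration experiment quantifies.
Finally, the association stage recovers the planted behavior-linked taxa:

```python
assoc = FeatureAssociation(role="infant").fit(
    cohort.counts, metadata=cohort.metadata,
    behavior=cohort.behavior, pcs=pcs.scores)
print(assoc.significant_[["feature", "predictor", "coefficient", "q"]])
```

```
            feature predictor  coefficient     q
        Dorea_sp063       REG        0.959 0.000
Lactobacillus_sp061       NEG       -0.817 0.000
Streptococcus_sp062       NEG        0.773 0.000
  Collinsella_sp064       REG       -0.906 0.000
  Escherichia_sp005       NEG       -2.153 0.012
```

The four planted taxa (indices 61–64) are found with correct signs; the
fifth row is a false discovery of the kind the FDR experiment bounds.

The same stages are available from the shell:

```bash
microdyad simulate --n-dyads 60 --seed 5 --out-dir cohort/
microdyad diversity --counts cohort/counts.tsv --metric chao1 --out div.tsv
microdyad run --config pipeline.yaml --seed 5
```

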