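# pleiomr

Two-sample Mendelian randomization (MR) that estimates the causal effect
of an exposure on an outcome from GWAS summary statistics while
*probabilistically identifying the instruments affected by correlated
horizontal pleiotropy* (CHP) — variants that act on a heritable
confounder of both traits. It handles correlated instruments through
LD-block modelling and overlapping GWAS samples through an error
correlation, and ships a full synthetic-study generator so every claim
is testable with zero downloads.

Intended users: statistical geneticists and epidemiologists running
summary-statistics MR who need an estimate that is robust to pleiotropic
instruments, plus a map of *which* genomic blocks carry the shared
confounding signal.

## Model

For instrument k with true marginal effects γₖ (exposure) and Γₖ
(outcome), the IV-to-outcome effect is a two-group mixture over LD
blocks l:

    Γ_lk | η_l = 0  ~  N(β₁ γ_lk, ξ²τ₁²)        no CHP
    Γ_lk | η_l = 1  ~  N(β₂ γ_lk, τ₂²)          CHP, β₂ = β₁ + δ

β₁ is the causal effect; δ = ρ_αγ σ_α0 / σ_γ is the shared confounding
slope; τ₂² > ξ²τ₁² because CHP adds instrument-specific variance.
Observed effects (γ̂, Γ̂) are linked to (γ, Γ) through the block LD
matrix R̂ (shrinkage λR̂_emp + (1−λ)I, λ = 0.85) and the sample-overlap
correlation R_e = [[1, ρ_e], [ρ_e, 1]]. A group spike-and-slab prior
η_l ~ Bernoulli(ω), ω ~ Beta(2, L) makes CHP sparse at the block level.
Inference is a blocked Gibbs sampler; β̂₁ comes from blocks currently
labelled clean, and each block gets a posterior probability
Pr(η_l = 1 | data) of carrying CHP. See `docs/methods.md` for the full
conditionals and design choices.

## Worked example

Simulate a study with a true causal effect β₁ = 0.1, 5% outcome
heritability each from uncorrelated and correlated pleiotropy (the CHP
support is 10 of 100 blocks), and fit:

```python
import pleiomr as pm

cfg = pm.SimConfig(n_x=20_000, n_y=20_000, p=1_000, L=100,
                   beta1=0.1, h2_theta=0.05, h2_alpha=0.05,
                   rho_alpha_gamma=0.2, seed=1)
study = pm.simulate_study(cfg)

est = pm.CorrelatedPleiotropyMR(n_iter=2_000, burn_in=1_000,
                                random_state=1).fit(study.pairs, ld=study.ld)
print(f"beta1_hat = {est.beta1_:.3f}  (posterior sd {est.beta1_sd_:.3f})")
print(f"95% CI    = ({est.beta1_ci_[0]:.3f}, {est.beta1_ci_[1]:.3f})")
print(f"p-value   = {est.p_value_:.2e}")
print(f"delta_hat = {est.delta_:.3f}")
print(f"CHP blocks (Pr > 0.8): {sorted(est.chp_blocks_.tolist())}")
```

Output:

```
beta1_hat = 0.143  (posterior sd 0.047)
95% CI    = (0.053, 0.235)
p-value   = 2.11e-03
delta_hat = 0.889
CHP blocks (Pr > 0.8): [1, 15, 19, 37, 41, 55, 92]
```

The causal effect is recovered within its credible interval (truth 0.1),
the confounding slope δ̂ ≈ 0.89 quantifies the bias a naive analysis
would mix in, and all seven flagged blocks are truly pleiotropic (the
generator planted CHP in blocks 1, 15, 16, 19, 37, 41, 44, 55, 92, 99).
Averaged over replicates the estimator is unbiased; a single replicate
scatters with the posterior sd. `pm.bayesian_fdr(est.pr_eta_, 0.1)`
turns the block probabilities into a discovery set with Bayesian FDR
control at 10%.

From the shell, the same workflow is:

```
pleiomr simulate --scenario standard --p 1000 --seed 1 --out-prefix out/study
pleiomr fit --exposure out/study.exposure.tsv --outcome out/study.outcome.tsv \
            --pairs out/study.pairs.tsv --blocks out/study.blocks.bed \
            --seed 1 --out-prefix out/fit
pleiomr evaluate --experiment fdr --reps 20 --seed 1 --out out/fdr.json
```

For real data, `pleiomr fit` reads two delimited summary tables
(configurable column names), harmonizes alleles to the exposure's effect
allele, selects instruments at p ≤ 5×10⁻⁴, assigns LDetect-style blocks,
and estimates ρ_e from null variants with `--rho-e auto`.

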