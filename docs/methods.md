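# Methods

## Problem and model

Two-sample Mendelian randomization (MR) estimates the causal effect
β₁ of an exposure X on an outcome Y from GWAS summary statistics: for
each instrument (IV) k one observes the marginal effect estimate and
standard error on the exposure, (γ̂ₖ, ŝ_γₖ), and on the outcome,
(Γ̂ₖ, ŝ_Γₖ). Horizontal pleiotropy breaks the instrument-validity
assumption in two ways. *Uncorrelated* pleiotropy (UHP, θₖ) perturbs the
outcome independently of instrument strength and can be absorbed by a
residual variance. *Correlated* pleiotropy (CHP, αₖ) arises when an
instrument acts on a heritable confounder of both traits, inducing
effects correlated with γₖ; unmodelled, it biases β̂₁ and can create
spurious reverse-causal findings.

`pleiomr` models the IV-to-outcome effect as a two-group mixture:

    Γₖ = β₁ γₖ + θₖ             (no CHP)
    Γₖ = β₁ γₖ + θₖ + αₖ        (CHP)

The CHP effect is decomposed through its regression on γ,
αₖ = δ·γₖ + α̃ₖ with δ = ρ_αγ·σ_α0/σ_γ (`decompose_chp`), so the CHP
group follows Γₖ = β₂γₖ + θₖ + α̃ₖ with β₂ = β₁ + δ, and detecting CHP
is equivalent to detecting non-zero instrument-specific residuals α̃ₖ.
A spike-and-slab prior with a latent label per unit gives

    Γ_lk | η_l = 0  ~  N(β₁ γ_lk, ξ²τ₁²)
    Γ_lk | η_l = 1  ~  N(β₂ γ_lk, τ₂²)

where the unit of the label η_l is an approximately independent LD
*block* l (nearby correlated instruments share their confounders, so CHP
is a block-level property), τ₁² = σ_θ² and τ₂² = σ_θ² + σ_α² > τ₁², and
ξ² is a parameter-expansion scale with improper prior ∝ 1/ξ² that
improves mixing at low signal-to-noise. Observed effects are linked to
latent true effects per block through the LD matrix R̂ (Eq. below) and,
when the two GWAS share participants, through the overlap correlation
ρ_e:

    (γ̂; Γ̂) ~ N( (Ŝ_γ R̂ Ŝ_γ⁻¹ γ ; Ŝ_Γ R̂ Ŝ_Γ⁻¹ Γ),
                 diag(Ŝ_γ, Ŝ_Γ) (R_e ⊗ R̂) diag(Ŝ_γ, Ŝ_Γ) ),

with R_e = [[1, ρ_e], [ρ_e, 1]]. Priors: γ_lk ~ N(0, σ_γ²),
η_l ~ Bernoulli(ω), ω ~ Beta(2, L) by default (sparse CHP; Beta(1, 1)
available), inverse-gamma IG(10⁻³, 10⁻³) on σ_γ², τ₁², τ₂², and weak
N(0, 100) priors on β₁ and β₂ (needed so their conditionals stay proper
when one label group is momentarily empty).

## Gibbs sampler: full conditionals

All conditionals are conjugate. Work in scaled coordinates
z_γ = Ŝ_γ⁻¹γ̂, z_Γ = Ŝ_Γ⁻¹Γ̂, u = Ŝ_γ⁻¹γ, v = Ŝ_Γ⁻¹Γ, so per block
z = (z_γ; z_Γ) ~ N(M w, R_e ⊗ R̂) with M = blockdiag(R̂, R̂) and
w = (u; v).

1. **(γ, Γ) per block, jointly.** The likelihood contributes precision
   M'(R_e⁻¹ ⊗ R̂⁻¹)M = (1−ρ_e²)⁻¹ [[R̂, −ρ_e R̂], [−ρ_e R̂, R̂]] and
   right-hand side (1−ρ_e²)⁻¹ (z_γ − ρ_e z_Γ; z_Γ − ρ_e z_γ), both
   precomputed once. The prior adds, with (b, t²) = (β₁, ξ²τ₁²) or
   (β₂, τ₂²) by η_l: diagonal ŝ_γ²(1/σ_γ² + b²/t²) on u, ŝ_Γ²/t² on v,
   and cross terms −b ŝ_γ ŝ_Γ/t². Sample w ~ N(P⁻¹ rhs, P⁻¹) by
   Cholesky; blocks of equal size are stacked and updated with batched
   linear algebra (the genome-wide R̂ is never materialized). A
   Cholesky failure triggers one 10⁻⁸·I jitter retry, then a hard error.
2. **η_l.** Bernoulli with log-odds log(ω/(1−ω)) +
   Σₖ [log N(Γ_lk; β₂γ_lk, τ₂²) − log N(Γ_lk; β₁γ_lk, ξ²τ₁²)].
3. **β₁, β₂.** Normal, from the η=0 (resp. η=1) instruments:
   precision Σγ²/t² + 1/100, mean (ΣγΓ/t²)/precision.
4. **τ₁² ~ IG(a + n₀/2, b + SSR₀/(2ξ²))**, **τ₂² ~ IG(a + n₁/2, b +
   SSR₁/2)**, **σ_γ² ~ IG(a + p/2, b + Σγ²/2)**, **ξ² ~ IG(n₀/2,
   SSR₀/(2τ₁²))** (from its improper prior; skipped when n₀ = 0), with
   SSR the group's residual sum of squares.
5. **ω ~ Beta(2 + Ση, L + L − Ση)** (default prior shown).
6. **Relabel.** The mixture is label-symmetric; identification imposes
   τ₂² > ξ²τ₁² (the CHP group has the larger outcome variance). If
   violated, swap β₁↔β₂, move ξ²τ₁² ↔ τ₂² with ξ² reset to 1,
   complement all η_l and map ω → 1−ω. On well-separated data the rule
   fires in < 5% of post-burn-in sweeps (tested).

The per-block update at ρ_e = 0 collapses to the two independent
multivariate-normal likelihoods, and with identity LD and singleton
blocks the sampler reduces exactly to the independent-instrument model;
both reductions are asserted bit-for-bit in the tests. The joint
posterior of (β₁, η) on small single-block instances is verified against
dense grid integration that marginalizes the latent effects analytically.

Point estimate and inference: β̂₁ = posterior mean, central 95%
percentile interval, and a two-sided normal p-value
2Φ(−|β̂₁|/sd(β₁)) from the posterior mean and standard deviation — the
construction is conventional for Gibbs-based MR and its frequentist
calibration is checked empirically (type-I test). δ̂ is reported as the
posterior mean of β₂ − β₁. Per-block Pr(η_l = 1 | data) feeds the
discovery rule; blocks with Pr > 0.8 are flagged, and the per-IV export
uses −log₁₀(1 − Pr) capped at 16.

Defaults: 5000 iterations, 2000 burn-in, thin 1, explicit seed required.
Effective sample size of the β₁ chain is reported
(initial-positive-sequence estimator). Variance draws are clamped to
[10⁻¹⁰, 10⁶]: a pure numerical guard — the vague IG prior otherwise
produces astronomically large draws when a label group is empty — that
never binds once both groups are populated.

## LD reference

Instruments are partitioned into approximately independent blocks from a
3-column BED-dialect interval file (0-based half-open; a boundary
position belongs to the right block; an instrument outside every
interval is assigned to the nearest one on its chromosome and logged).
Per block, the correlation matrix of reference-panel dosages is shrunk
towards the identity,

    R̂⁽ˡ⁾ = λ R̂_emp⁽ˡ⁾ + (1 − λ) I,   λ = 0.85 by default,

which bounds eigenvalues below by 1 − λ and certifies positive
definiteness by Cholesky before sampling. Reference genotypes are
accepted as a plain dosage matrix keyed by variant id; binary PLINK
parsing is out of scope (convert with `plink --recode A` or similar).

## Sample overlap

ρ_e is a plug-in constant estimated upstream (`estimate_overlap_rho`):
the Pearson correlation of the two traits' z-scores over shared variants
with |z| < 2 in both traits (≈95% null band; the choice is insensitive
in simulation), pruned to one variant per block when block information
is available. Fewer than 100 null variants triggers a ρ_e = 0 fallback
with a warning.

## Harmonization and instrument selection

Alleles are matched to the exposure's effect allele under the four
resolvable configurations (same / swapped / strand-complement /
complement-swapped); swapped cases flip the outcome effect sign;
palindromic variants (A/T, C/G) are dropped by default because strand
cannot be resolved without allele frequencies; unmatched variants are
dropped. Instrument selection keeps variants with exposure p-value
2Φ(−|γ̂/ŝ_γ|) ≤ 5×10⁻⁴ by default (normal approximation; GWAS sample
sizes are large). Duplicate variant ids keep the most significant
record.

## Synthetic-data generator

The generator emulates a polygenic two-cohort study:

* Genotypes: per-block latent AR(1) Gaussians (r = 0.4 or 0.8; blocks
  independent), thresholded at Φ⁻¹((1−f)²) and Φ⁻¹(1−f²) to dosages
  {0,1,2} with Hardy–Weinberg category probabilities; MAF f ~ U[0.05,
  0.5] shared across cohorts. Defaults: n_x = n_y = 50,000 individuals,
  n_r = 4,000 reference samples, p = 1000 instruments in L = 100 blocks
  of 10.
* Effects: (γₖ, αₖ) bivariate normal with correlation ρ_αγ on a sparse
  CHP support of whole blocks totalling 10% of instruments (the model's
  unit of CHP is the block); θ dense i.i.d. normal; q = 50 confounders
  with coefficient pairs (ψ_x, ψ_y) correlated at 0.8.
* Traits: x = Gγ + Uψ_x + ε, y = β₁x + Gα + Gθ + Uψ_y + ε. Scaling is
  *empirical*: each genetic component is rescaled on the simulated
  genotypes so its realized variance fraction hits its target
  (exposure instrument heritability 0.1; UHP and CHP fractions of
  outcome variance h²_θ, h²_α), and residuals top each trait's variance
  up to ~1. The confounder share of the non-genetic remainder is not
  specified by the design and defaults to 0.3 (open choice, exposed in
  the config). Because the components are rescaled individually,
  cross-covariances (e.g. between Gα and β₁x) land in the residual
  budget; realized fractions are within a few percent relative of their
  targets at n = 50,000.
* Summary statistics: closed-form per-variant simple linear regression
  in each cohort; the two cohorts are disjoint by default
  (`overlap_frac` reuses individuals and makes ρ_e > 0 testable).
* Reverse-causation design: y = β₁x + Gθ + ε with no confounders,
  exposure heritability 0.3, outcome heritability 0.25 of which 20% is
  causal (hence β₁ = √(0.05/0.3) ≈ 0.408), 5% of γ non-zero
  (block-aligned), p = 2000, r = 0.4. Both orientations of the summary
  statistics are returned with the truth flag.

What the generator does **not** emulate: real LD (AR(1) blocks only),
allele-frequency/effect-size coupling, binary outcomes, non-linear
confounding, population stratification, and winner's-curse selection —
so passing tests demonstrate correctness of the method under its own
modelling assumptions, not robustness to these real-data features.

## Evaluation

* Type-I / power: fraction of replicates with p < 0.05 per cell, with
  binomial confidence intervals; disjoint seed streams per cell.
* CHP discovery FDR: blocks sorted by descending Pr(η=1), included
  greedily while the running mean of 1 − Pr stays ≤ 0.1 (Bayesian
  local-FDR rule; the estimate never exceeds the level by construction)
  and validated against generator truth.
* Causal-direction ROC: per replicate the model is fitted in both
  orientations; the ROC sweeps a shared p-value threshold.
* Comparator: fixed-effect IVW, β̂ = Σ(γ̂Γ̂/ŝ_Γ²)/Σ(γ̂²/ŝ_Γ²).

## Problem sizes used by the test suite and acceptance script

Rates over replicates use reduced cohorts chosen so the per-instrument
strength (z-score sd ≈ √(n·h²/p)) matches the full-scale regime:
FDR control uses 50 replicates at n = 20,000, p = 1000 with 2000/1000
Gibbs iterations; type-I calibration uses 200 replicates at n = 8,000,
p = 200; effect recovery uses 12 replicates at n = 30,000, p = 1000;
the direction ROC uses 20 replicates at n = 10,000, p = 400. Generator
fidelity checks run at the full n = 50,000.

## Known limitations

* Sparse-CHP identification: when the CHP proportion is large the
  variance-ordering identification can break down (the mixture's roles
  blur), as reflected in the relabel-frequency diagnostic.
* Requires dozens of instruments; not suited to molecular exposures with
  few IVs.
* Single exposure, single outcome; no multivariable extension.
* ρ_e is plugged in, not sampled, so its estimation uncertainty is not
  propagated.
* p-values are a normal approximation to the posterior; heavy-tailed
  posteriors would mis-calibrate them (not observed in simulation).
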