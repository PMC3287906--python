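# Methods

## Model

For a quantitative trait measured on `n` unrelated subjects genotyped at
`p` SNPs, let `g_ij ∈ {0,1,2}` count copies of an (arbitrarily chosen)
reference allele, with missing calls allowed. The working response `y` is
the trait after two preprocessing steps: ordinary least-squares
residualization on the covariates (intercept, sex, age, smoking,
population-group indicators — a standard two-stage adjustment for
confounding and stratification), then use of those residuals directly. Each
genotype column is standardized over its *nonmissing* subjects to satisfy

```
Σᵢ x_ij = 0,   Σᵢ x_ij² = n_j,
```

with missing cells set to 0 afterwards so they drop out of every inner
product. Under this scaling the per-SNP marginal least-squares estimate is
`z_j = (x_j · y)/n_j` and the marginal loss has unit curvature in each
coordinate.

The SMCP estimate minimizes

```
L(β) = Σ_j (1/2n_j) Σ_i (y_i − x_ij β_j)²  +  Σ_j ρ₁(|β_j|; λ₁, γ)
       + (λ₂/2) Σ_j ς_j (|β_j| − |β_{j+1}|)² ,
```

where `ρ₁(t; λ₁, γ) = λ₁t − t²/(2γ)` for `t ≤ γλ₁` and `γλ₁²/2` beyond
(the MCP), and `ς_j` is the absolute Pearson correlation of genotype
columns `j` and `j+1` computed over subjects nonmissing at both, set to 0
across chromosome boundaries and for pairs with fewer than 3 shared
observations. The smoothing term acts on differences of *absolute*
coefficients: a fused-lasso penalty on raw differences would change with a
relabeling of either SNP's alleles, whereas this objective is exactly
invariant under any pattern of allele flips (the fitted `β_j` just changes
sign).

The marginal (per-SNP) loss, rather than the joint multiple-regression
residual, is used for two reasons: it makes missing genotypes trivial to
handle (each SNP's term uses its own `n_j` subjects), and it decouples the
coordinates except through the smoothing term, so coordinate descent needs
no residual updates.

Assumptions worth keeping in mind: subjects are unrelated (no kinship
adjustment), the trait is quantitative with roughly homoscedastic noise,
covariate effects are linear and removed once up front, and adjacency is
physical order within a chromosome.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `γ` (MCP concavity) | 3 | standard MCP choice; `γ→∞` is the lasso, `γ=1` the hard-threshold boundary mode (supported, handled exactly) |
| `η` (smoothing fraction) | 0.1 | fraction of the total penalty level given to LD smoothing via `λ₁=(1−η)τ`, `λ₂=ητ`; `η=0` is pure MCP |
| `τ` (overall level) | EBIC-tuned | decreasing log-spaced grid of 100 points from `τ_max = max_j|z_j|/(1−η)` (the smallest τ whose fit from zero is empty, by the entry condition `|z_j| ≤ λ₁`) down to `0.01·τ_max`, warm-started |
| EBIC `γ_E` | `1 − log n / (2 log p)`, clipped to [0,1] | the boundary value for EBIC model-selection consistency with `p` polynomial in `n`; liberal end of the admissible range |
| `tol` | 1e-6 | max absolute coefficient change per sweep |
| `max_sweeps` | 1000 | non-convergence returns a flagged result, never raises |
| FDR `q` | 0.05 | Benjamini–Hochberg level for the single-SNP baseline |

The exact algebraic split of `τ` into `(λ₁, λ₂)` is a convention of this
package: `λ₁ = (1−η)τ` and `λ₂ = ητ`, so `η` reads as "fraction of penalty
devoted to smoothing". Any reparameterization differing only by rescaling
relabels the τ axis without changing the fitted path. Similarly, the
factor `λ₂/2` in front of the smoothing sum is a convention; moving the ½
inside would only rescale `λ₂`.

## Coordinate descent

Because the loss is marginal, the 1-D problem in coordinate `j` (neighbors
fixed) is, writing `u = |β_j|` and choosing `sign(β_j) = sign(z_j)`,

```
f(u) = ½(1+w)u² − a·u + ρ₁(u),   w = λ₂(ς_{j−1}+ς_j),
a = |z_j| + λ₂(ς_{j−1}|β_{j−1}| + ς_j|β_{j+1}|).
```

The global minimizer is found exactly by evaluating `f` at four candidates:
0, the inner-regime stationary point `(a−λ₁)/(1+w−1/γ)` clamped to
`[0, γλ₁]`, the regime boundary `γλ₁`, and the flat-regime stationary point
`a/(1+w)` when it exceeds `γλ₁`. When the inner-regime curvature
`1+w−1/γ` is nonpositive (only possible at `γ = 1` with no smoothing) the
inner branch is linear or concave, so its minimum lies at an endpoint that
is already in the candidate set — the update stays exact without a
numerical fallback. Note the smoothing term *lowers* the effective entry
threshold of a SNP whose LD neighbors carry nonzero effects (through `a`);
this is the mechanism by which SMCP completes causal blocks that a plain
sparse penalty truncates.

Sweeps are cyclic in ascending SNP index (deterministic), implemented as a
numba kernel; convergence is declared when the largest coefficient change
in a sweep falls below `tol`. The objective is recorded per sweep and is
non-increasing by construction (each update is an exact 1-D minimization).
The MCP makes the problem nonconvex, so the result is a stationary point,
not a certified global optimum; warm starts along the decreasing τ grid
are the standard mitigation. Monomorphic SNPs are excluded from the fit
(coefficient 0, flagged) but retained in reports.

## Tuning and inference

**EBIC.** Each path point is scored by
`n·log(RSS/n) + k·log n + 2γ_E·log C(p,k)` with `k` the support size. RSS
is the *joint least-squares refit* on the selected columns: the criterion
compares candidate supports, not shrinkage levels. Scoring the penalized
coefficients directly was tried and rejected: under strong LD the marginal
MCP estimates of a causal block jointly over-predict (each member absorbs
the full block signal), which inflates the plug-in RSS precisely for the
models the smoothing penalty is designed to find, and systematically
drives SMCP to sparser selections than the lasso — inverting the method's
characteristic behavior. Ties in the EBIC argmin resolve to the larger τ
(sparser model). The path stops early once `k > n/2`: EBIC is meaningless
as `k → n` (the refit RSS collapses toward zero), and such models are
never competitive. The default `γ_E` sits at the consistency boundary and
is therefore liberal; on pure-noise panels of 500 SNPs at `n = 200` it
admits a single false SNP in roughly 10–20% of datasets. Raising `γ_E`
toward 1 suppresses those but also prunes genuine block members at
mini-exome scale; users wanting stricter null control should pass
`ebic_gamma` closer to 1.

**LOO p-values.** For each selected SNP `j`, the penalized model is refit
at the same `(λ₁, λ₂, γ)` with `β_j` constrained to zero (warm-started from
the full fit), and `D = n·log(RSS₋ⱼ/RSS)` — joint RSS of each model's
support, clipped at 0 — is referred to χ² with 1 degree of freedom. The
refit keeps the tuning fixed, so the p-value conditions on the selected τ
and is approximate, not selection-adjusted. Calibration is checked
empirically: for a null SNP held in the model by a weak penalty
(`τ = 0.02·max|z|`, `n = 500`, `p = 20`, independent SNPs), the p-values
are near-uniform (KS ≈ 0.1 over 200 replicates). The χ²₁ reference
deteriorates when `p/n` is not small or shrinkage is heavy.

**Baselines.** The lasso comparator runs the identical machinery with
`γ = 10¹²` (numerically exact soft thresholding) and `λ₂ = 0`. The
single-SNP baseline is a per-SNP simple linear regression Wald test with
step-up Benjamini–Hochberg correction (via statsmodels) at `q = 0.05`.

## Simulator

The generator emulates a GAW17-style mini-exome panel of unrelated
subjects. Two latent Gaussian haplotype processes per subject follow an
AR(1) along the SNP axis with lag-one correlation `ρ` (restarting at
chromosome boundaries); thresholding at the normal quantile of each SNP's
minor-allele frequency yields allele indicators, and their sum the 0/1/2
code. Thresholding attenuates correlation, especially for rare variants,
so the realized genotype-scale lag-one `|r|` is always reported. Traits
are linear in the causal genotypes plus covariate effects (binary sex and
smoking, Gaussian age, a 7-level population group expanded to indicators)
and Gaussian noise; missingness is an independent per-cell mask applied
after trait generation, so it thins information without biasing the
signal.

The `gaw17_like_preset` fixes the study conditions used throughout the
validation studies: `n = 697` subjects and `p = 2000` SNPs on two
chromosomes (a desk-scale stand-in for the full 24,487-SNP panel — scaling
up is a config change, not a code change), MAFs in (0.005, 0.10),
`ρ = 0.85` so that roughly half of adjacent pairs exceed realized
`|r| = 0.5` (the strong-LD regime the smoothing penalty presumes), one
block of three adjacent causal SNPs at MAF 0.02 with per-allele effects
(1.2, 0.9, 1.6) — rare variants with large per-allele effects, the regime
the method targets — and two isolated causal SNPs at MAF 0.05 with effect
0.45, deliberately near the detection boundary, as most causal variants
outside the main cluster are in practice. Noise SD is 1.

What the simulator does **not** capture: coalescent genealogy, variable
recombination, allele-frequency spectra by population, genotyping-error
structure, relatedness, and linkage beyond lag-one decay of the latent
AR(1). Passing the replicate studies therefore demonstrates correct
behavior under idealized strong-lag-one LD with clustered rare causal
variants, not performance on any particular real cohort.

## Validation studies and problem sizes

The acceptance script and the corresponding tests use: 100 random designs
(`n = 200`, `p = 50`) for the separable-MCP analytic oracle; 200 random
1-D instances against a `1e-4`-step grid search; 100 random fits
(`n = 100`, `p = 30`) for descent monotonicity; a 60-SNP design for the
soft-threshold limit; a 40-SNP design with 10 flipped columns for
allele-label invariance; 50 preset replicates for the method comparison;
50 null panels (`n = 200`, `p = 500`) for the empty-model rate; and 200
replicates (`n = 500`, `p = 20`) for LOO calibration.

## Known limitations

- Nonconvexity: only stationarity is guaranteed; different initializations
  can give different supports far from the warm-started path.
- LOO p-values condition on the selected tuning; no selective-inference
  correction is attempted.
- The EBIC default is liberal (see above); its combinatorial term assumes
  exchangeable candidate SNPs, which strong LD violates.
- Smoothing slightly handicaps isolated causal SNPs (their only neighbors
  are null), the price of favoring LD-coherent blocks.
- Only lag-one adjacency is smoothed; pairwise LD beyond lag one is
  deliberately out of scope for computational reasons.
- Quantitative traits only; no logistic or survival loss.
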