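# Methods

## Model and task

The package addresses leave-one-environment-out (LOEO) prediction in
multi-environment trials: every environment in turn is the entire test set,
and models trained on the remaining environments must predict all of its
phenotypes. Both model families share the reaction-norm decomposition
`y_ij = μ + L_i + g_j + gL_ij + ε_ij` with environment effects
`L ~ N(0, σ²_E H)`, line effects `g ~ N(0, σ²_g G)`, interaction
`gL ~ N(0, σ²_gL H ⊗ G)` and i.i.d. residuals. `G` is the genomic
relationship matrix over lines, `H` the environmental relationship matrix
over environments (identity when no covariates are available). With `H = I`
an unobserved environment's main effect is exchangeable with any other, so
its *predictive mean* carries no environment information — only `g` (and,
through G-relatedness, `gL`) moves the predictions. This is the structural
reason LOEO prediction is hard, and the setting in which the PLS
augmentation is interesting.

## Relationship matrices

`compute_G` / `compute_H` center each column and scale it to unit *sample*
variance (n−1 denominator), then form the cross-product divided by the
retained column count. This yields the exact identity `trace(G) = J − 1`
(and `trace(H) = I − 1`) used as a self-check throughout. Monomorphic
markers / constant covariates are dropped and the divisor adjusted;
imputation-produced real-valued dosages are accepted. A `vanraden1` option
scales the centered dosages by `2 Σ p_k(1−p_k)` instead; the standardized
recipe is the default so G and H are built by the same rule. Square roots
are symmetric eigen-roots (`L = U √Λ Uᵀ`, eigenvalues clipped to zero above
−1e-8 relative), so `L·L = K` and `X·L` is well defined regardless of
transposition convention.

## PLS on augmented designs

Incidence matrices `X_L (n×I)`, `X_g (n×J)`, `X_gL (n×IJ)` are built from
the observed (environment, line) index; under unbalanced data only rows are
dropped, all interaction columns are kept so the Kronecker multiplication
stays well formed. The package-wide interaction column order is
environment-major: column `i·J + j` is (environment i, line j), matching
`L_E ⊗ L_g`. The PLS input is `[X_L L_E | X_g L_g | X_gL (L_E⊗L_g)]`
(interaction block included only for the `E+G+GE` predictor). The
interaction block is assembled row-wise as `kron(L_E[i,:], L_g[j,:])`, which
avoids materializing the IJ×IJ Kronecker factor; a test checks it against
the literal product.

Latent variables are extracted NIPALS-style from the SVD of the deflated
cross-product `EᵀF`. For a univariate response the first left singular
vector is `w ∝ Eᵀf`; scores are normalized to **unit norm** (the common
convention; the printed division by the squared norm found in some
derivations yields identical coefficients, which the route-equivalence test
`X_new B = T_new b` verifies). The Y side is deflated as well, although for
a univariate response this is redundant. Signs are fixed so the
largest-magnitude entry of each weight vector is positive, making output
reproducible across linear-algebra backends. Coefficients are recovered
through `R = W(PᵀW)⁻¹`, `b = (TᵀT)⁻¹Tᵀy`, `B = R b`; extraction stops early
if the X residual norm falls below 1e-12 of its initial value.

Component count is chosen by k-fold cross-validated RMSEP with seeded
random folds (scikit-learn's `KFold`); because scores are orthogonal, the
per-fold predictions for all component counts come from one fit with the
maximum count. The smallest count attaining the minimum wins. The cap
`a_max = min(n_train−1, p, 30)` reflects that RMSEP curves on genomic
designs flatten early. The inner CV in the LOEO protocol defaults to k=5
(an 80/20 nested split); k=10 is the convention for stand-alone RMSEP
tuning and is what the generative-rank recovery test uses — both appear in
the method's literature and the choice is exposed as a parameter. Column
scaling is off by default: the augmented design's columns are already on
comparable scales through the relationship roots; a `scale` flag serves
raw-covariate use.

## Bayesian GBLUP

Each random term `u ~ N(0, σ²_t K)` is reparameterized through the
eigendecomposition of its **full** kernel, `u = U√D α`, `α ~ N(0, σ²_t I)`,
turning the model into Bayesian ridge blocks on fixed bases
`Φ = Z U √D` (for the interaction, `Φ` rows are `kron(ψ_H[i], ψ_G[j])`, so
the IJ×IJ kernel is never formed). Because the basis spans all levels —
including environments absent from training — the sampled coefficients
automatically carry the posterior of unobserved environments' effects
(prior conditional on the observed levels); averaging per-draw predictions
marginalizes them exactly as LOEO requires, with zero mean contribution
when `H = I`.

The Gibbs sweep updates μ (flat prior), each coefficient block jointly
(via the precomputed eigendecomposition of `ΦᵀΦ`, so a sweep costs a few
matrix-vector products per term), and the variance components from their
scaled-inverse-χ² full conditionals. Priors are df=5 with scales set so
each term's prior mode is an equal share of the observed phenotypic
variance — default-hyperparameter behavior in the BGLR style, since no
problem-specific tunables are assumed. Chain defaults are 12,000 iterations,
2,000 burn-in, thinning 5; the LOEO benchmark and test suite use shorter
explicit chains (1,500–8,000 iterations) because posterior predictive means
at the problem sizes shipped here (tens of lines, hundreds of observations)
stabilize well before the default length — chain settings are always
parameters, never baked in. Monte Carlo standard errors of predictive means
are computed from non-overlapping batch means. Variance components may be
fixed (`fix_varcomps`), which degenerates a zero-variance term's effects to
zero and is how the sampler is validated against the closed-form oracle.

`blup_oracle` is the exact conditional-Gaussian predictor with known
variance components: GLS mean plus cross-covariance times the inverse
training covariance. It exists purely as a testing oracle.

## Synthetic trials

`simulate` draws markers i.i.d. per locus as Binomial(2, p_k) with p_k
uniform in (0.05, 0.95) by default, covariates standard normal, and effects
from the stated multivariate normals using the symmetric roots of the
**realized** G and H — so parameter-recovery experiments are internally
consistent. Defaults (J=100 lines, I=5 environments, p=500 markers, r=0
covariates, variances 1/1/0.5/1, μ=10) describe a moderately heritable,
GE-containing trial of desk scale; μ is kept well away from zero because
NRMSE divides by the response mean. Unbalancedness removes cells uniformly
at random but never orphans a line or environment (resampled if violated).

What the generator does **not** emulate: linkage disequilibrium, population
structure, QTL architecture, spatial field trends, or trait networks.
Consequently the realized G is close to an identity plus noise of order
`1/√p`. Two consequences matter for interpreting results. First, with G
near identity, `σ²_gL (I ⊗ G)` is nearly indistinguishable from residual
variance — their sum is well identified, the split is not — so
posterior-mean variance components drift toward the middle of the weakly
identified region even though the sampler is exact (it recovers all
components within ~13% when G is strongly structured, and maximum
likelihood on the same data is unbiased on average). Second, data generated
from the reaction-norm model itself favor the correctly specified Bayesian
GBLUP; relative efficiencies near or below 1 on synthetic data say nothing
against PLS's documented advantage on real trials, whose structure departs
from the generative model. Passing tests here demonstrate correctness of
the machinery, not field performance.

`truth_nrmse_floor` reports the NRMSE between y and the true signal — the
best any predictor knowing the truth could do in expectation — and is used
as a lower-bound sanity check on every fitted method.

## Marker QC

Order of operations: (1) drop markers whose missing fraction exceeds
`max_missing` (default 0.15); (2) impute remaining gaps with the expected
dosage `2·p̂` under the observed allele frequency; (3) drop markers with
MAF < `maf_min` (default 0.05), MAF computed from pre-imputation calls.
Filtering on observed calls makes the pipeline idempotent and keeps the
MAF estimate independent of the imputation. Imputed dosages stay
real-valued; heterozygote recoding for assay-specific anomalies is out of
scope.

## Protocol and determinism

In the LOEO loop the PLS component count is tuned by inner CV on the
training environments only — the held-out environment's phenotypes are
never touched during tuning, which a permutation test asserts. "Global"
NRMSE pools all held-out predictions (one ratio, matching an
across-environments reading); the mean of per-environment NRMSEs is emitted
as "GlobalMean" since the alternative reading is equally defensible. Lines
observed only in the held-out environment are allowed; their effects are
reached purely through G. One master seed drives everything: per-fold seeds
are derived by hashing (environment, purpose) with the master seed, so
reports are bit-identical across reruns and folds are independent of
method order.

## Numerical choices and limitations

Eigenvalues below 1e-10 of the maximum are truncated from kernel bases;
PSD clipping tolerance is −1e-8 relative; `PᵀW` is well conditioned by
construction (near upper-triangular with unit diagonal) and inverted
directly. Problem sizes in the shipped tests and the acceptance script
(up to ~100 lines × 5 environments, 500 markers) are the package's chosen
desk scale; the algorithms are dense and scale as O(n·m) per Gibbs sweep
and O(n·p·a) per PLS fit, so trials with thousands of lines are feasible
but slower. Multi-trait models, dominance/epistasis kernels, nonlinear
(Gaussian) kernels, REML estimation and CV1/CV2 random cross-validation
schemes are out of scope.
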