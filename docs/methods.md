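# Methods

## Model

A mediating molecular trait is predicted from genotypes as T̃ = Σₖ Xₖ γ̃ₖ.
The target trait under the polygenic null is

    Y = Σₖ Xₖ δₖ + ε,      δₖ ~ N(0, σ²_δ),  ε ~ N(0, σ²_ε),

with no mediator effect (β = 0). The association statistic is the score form
Z = √n·r, r the sample correlation of T̃ and Y. Although δ is independent of
γ̃, both T̃ and the polygenic part of Y live in the column space of X, so
their sample correlation does not concentrate at zero as fast as the nominal
null assumes; the variance of Z grows as

    E[Z²] ≈ 1 + N · h²_δ · Φ,      Φ = (1/M) · (γ̃′Σ²γ̃)/(γ̃′Σγ̃),

with Σ the SNP correlation matrix and M the effective number of SNPs with
direct effects on Y. The correction divides each Z by √(1 + Φ·N·h²_δ).
Under an alternative with mediator effect β and prediction precision
τ² = var(T)/var(T̃),

    E[Z²] ≈ 1 + [N·h²_δ/(1 − τ²h²_gene)]·Φ + N·τ²h²_gene/(1 − τ²h²_gene),

where h²_gene = β²σ²_T/σ²_Y. Since τ² enters only through τ²h²_gene, noisy
prediction weights reduce power but never inflate the null — the
error-in-variables corollary that the test suite checks directly.

## Assumptions

- Additive, infinitesimal genetic architecture for the target trait; the
  fraction π of SNPs with nonzero δₖ mainly matters through M, and the slope
  estimate is empirically stable for π in [0.3, 1].
- Prediction error independent of the target-trait noise (weights trained in
  an external cohort).
- Continuous traits and a linear association; case-control designs on the
  liability scale are out of scope.
- Hardy-Weinberg equilibrium in simulated genotypes; no relatedness.

## Simulation conventions

**Genotypes.** Independent SNPs are Binomial(2, maf) draws; the minimal
example uses N = 1,000, M = 999, MAF = 0.4. LD-structured genotypes sum two
haplotypes obtained by thresholding correlated Gaussians (Gaussian copula);
the realized dosage correlation is attenuated relative to the latent
Gaussian correlation but monotone in it, which suffices for exercising the
analytic Φ beyond Σ = I.

**Standardization.** Columns are centered and divided by the population SD
(divisor n, not n−1), so (1/n)X′X is exactly a correlation matrix and
Z = √n·r is algebraically consistent with correlation-scale Σ. Subsampled
matrices are re-standardized within the subsample.

**Variance partition.** Each trait component is centered, made orthogonal
to the components before it (polygenic → genic → noise), and divided by its
realized sample SD before scaling to its target share. Orthogonalization is
what turns "exact in expectation" into "exact per replicate": the shares
h²_δ, h²_gene, 1 − h²_δ − h²_gene and var(Y) = 1 hold to 1e-10 in every
draw. The projection removes one degree of freedom per component, a
negligible O(1/n) perturbation. The rescaling by realized SD also means no
assumption about the SNP-effect distribution is needed for the partition;
a unit-variance Student-t option (`df`) provides the heavy-tail robustness
variant.

**Statistic.** Z = √n·r (score form) is the default; the regression t form
r√(n−2)/√(1−r²) is available via `statistic="t"`. At n ≥ 500 the two differ
negligibly. Two-sided p values come from the standard normal in both cases.

**Seeds.** One root seed per experiment is split into named child streams
(SHA-256 of operation keys fed to `SeedSequence`), and batch replicate r
uses the stream derived from (seed, "replicate", r). Batch runs therefore
reproduce the per-replicate loop: the only numerical difference is
matrix-product rounding (≤ 1e-12 in tests).

## Φ estimation

The inflation grid simulates `n_replicates` polygenic null traits at every
(N, h²_δ) combination, with individuals subsampled once per N (the
predicted mediator is computed once and carried along, as when a fixed
biobank subset is re-used across trait draws). Mean Z² per cell is
regressed on N·h²_δ by ordinary least squares with a free intercept — the
intercept is a diagnostic (values near 1 indicate a pure polygenic
background; real-data intercepts slightly above 1 reflect truly causal
mediators) and is reported, not forced. Cells are unweighted; per-cell
standard errors are retained for diagnostics. The estimate is made
conservative by one standard error, Φ = max(slope + SE, 0); negative fitted
slopes mean no detectable inflation and clip to zero.

The default desk-scale grid is N ∈ {500, 1000, 2000} × h²_δ ∈ {0, 0.5, 1}
with 500 replicates — a scaled-down version of a biobank protocol that
spans N up to 2×10⁴ with 1,000 replicates per cell. Grid regressions are
scale-free in x = N·h²_δ, so the smaller range changes only the standard
error, not the estimand.

`theoretical_phi` implements the analytic slope. It is a validation oracle,
not the production path: using it for real data would require the true LD
matrix and the effective number of causal SNPs M, neither of which is
estimable reliably. Two identities anchor the tests: (i) Σ = I gives
Φ = 1/M exactly; (ii) conditional on a realized genotype matrix, the
simulated mean Z² at heritability h² tracks 1 + h²·(n·Φ̂ − 1) with Φ̂
evaluated on the *sample* LD matrix X′X/n — averaging over genotype draws,
the −h² and the finite-sample excess of Φ̂ cancel, recovering 1 + n·h²/M.

## Correction and baseline

Variance control divides each Z by its own √(1 + Φ·N·h²_δ) and recomputes
two-sided normal p values; mediators without a Φ entry pass through flagged
(default) or raise (`missing_policy="error"`). Genomic control is the
comparison baseline: λ = median(Z²)/qχ²₁(0.5), applied only when λ > 1.
Because inflation is mediator-specific, a single λ must over-correct
low-Φ mediators and under-correct high-Φ ones; the test suite plants a
bimodal Φ distribution and verifies that variance control calibrates the
pooled p values where genomic control leaves a detectable KS departure.

## Evaluation conventions

QQ expected quantiles use rank/(n+1); the precision of a discovery set with
zero discoveries is reported as an explicit undefined flag, never 0 or 1;
multiple testing uses Bonferroni throughout. λ_GC computed from p values
(via the normal quantile) matches the Z-based genomic-control factor.

## Problem sizes and numerical choices

Simulation-backed tests use the minimal example (10³ × 999) with 300–1,000
replicates, and 2,000 × 999 for the correction-calibration checks, where the
expected uncorrected inflation factor is 2.0 — large enough that a KS test
at α = 0.01 on 1,000 p values rejects decisively while the corrected set
passes. Monte-Carlo assertions use 3–4 standard-error bands; collinearity
is declared at |r| ≥ 1 − 1e-12; standardization requires strictly positive
column variance and lists offending variants; grid regressions require at
least two distinct N·h²_δ values.

## What the synthetic data does not emulate

Real LD beyond the copula mechanism (no haplotype blocks, no MAF-LD
coupling), population structure and relatedness, imputation uncertainty,
strand ambiguity, binary traits, and horizontal pleiotropy. Passing tests
therefore demonstrate the internal consistency of the inflation law and the
correction under the stated generative model, not performance on any
particular cohort. Real-data use requires an externally estimated h²_δ and
a Φ table estimated with genotypes and prediction models matching the
study's ancestry and tissue.

## Known limitations

- Φ estimated at desk scale is of order 1/M for the simulated panel; tables
  for real use must be built at genome-wide M.
- Only effects well above the polygenic background remain significant after
  correction; co-regulation and LD contamination are not addressed.
- The one-SE adjustment is deliberately conservative; users wanting the
  point estimate can read `slope` from the Φ table.
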