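# twascal

Polygenicity-aware calibration of TWAS/xWAS association statistics.

## The problem

A transcriptome-wide association study (TWAS) — and its metabolite or
brain-imaging analogues (xWAS) — tests whether a *genetically predicted*
mediating trait T̃ = Σₖ Xₖ γ̃ₖ is associated with a target complex trait Y,
where X is the genotype dosage matrix and γ̃ the prediction weights. Because
T̃ is itself a linear combination of genotypes, any polygenic background in Y
(direct SNP effects δₖ with heritability h²_δ) leaks into the test even when
the mediator has no causal effect. The squared statistic inflates linearly:

    E[Z²] ≈ 1 + N · h²_δ · Φ,

with N the GWAS sample size and Φ a *mediator-specific* inflation slope.
Analytically, Φ = (1/M) · (γ̃′Σ²γ̃)/(γ̃′Σγ̃), where Σ is the SNP correlation
(LD) matrix and M the effective number of causal SNPs for the target trait;
for independent SNPs this reduces to 1/M. A single global rescaling (genomic
control) cannot be right for every mediator, so `twascal` estimates Φ per
mediator by simulation and applies the **variance-control** correction

    Z_corr = Z / √(1 + Φ · N · h²_δ),

which restores a standard-normal null. Users supply N and h²_δ (the latter
typically from LD score regression); Φ comes from the simulation workflow
below or from a published per-mediator table.

This matters in practice: with biobank-scale N ≥ 10⁵ and Φ on the order of
10⁻⁵ (genome-wide prediction models), uncorrected TWAS hits include many
polygenic-background artifacts.

## What the package provides

- `genotype_sim` — synthetic dosage matrices (independent Binomial(2, maf)
  SNPs, or LD-structured via a Gaussian copula), standardization, dosage TSV I/O.
- `weights_io` — prediction-weight containers, TSV and PredictDB-style SQLite
  dialects (the SQLite `extra` table carries Φ), mediator prediction with
  allele-orientation handling.
- `trait_sim` — polygenic null and alternative target traits with *exact*
  variance partitioning (polygenic / genic / noise shares hold per replicate).
- `association` — correlation-based Z = √n·r statistics, single and batched
  over replicates via one matrix product.
- `phi` — the (N, h²_δ) inflation grid, the slope regression with its
  conservative one-standard-error adjustment, the analytic Φ oracle, and the
  expected-Z² formulas under null and alternative.
- `correction` — variance control and a genomic-control baseline.
- `evaluation` — KS/QQ calibration reports, type-I error, λ_GC, Bonferroni
  precision/recall.
- `twascal` CLI — `simulate-genotypes`, `simulate-weights`, `simulate-traits`,
  `run-twas`, `estimate-phi`, `correct`, `evaluate`.

## Worked example

```python
import twascal as tc

# 1,000 individuals, 999 independent SNPs at MAF 0.4; dense normal weights
g = tc.standardize(tc.simulate_genotypes(1000, 999, maf=0.4, seed=1))
w = tc.simulate_true_weights(999, sparsity=1.0, seed=2, template=g)
t = tc.predict_mediator(g, w)

# mean Z^2 over 1,000 null traits, without and with a polygenic background
s0 = tc.batch_null_associations(g, t, tc.NullTraitSpec(h2_delta=0.0, seed=3), 1000)
s5 = tc.batch_null_associations(g, t, tc.NullTraitSpec(h2_delta=0.5, seed=3), 1000)

# estimate the inflation slope from a (N, h2) grid, then correct a Z score
grid = tc.run_inflation_grid(g, t, n_values=[500, 750, 1000],
                             h2_values=[0.0, 0.5, 1.0], n_replicates=500, seed=4)
est = tc.estimate_phi(grid)
```

prints (seeds as above):

```
mean Z^2, h2=0.0: 1.003 +/- 0.043
mean Z^2, h2=0.5: 1.506 +/- 0.068
predicted 1 + N*h2/M:       1.501
phi = 1.063e-03 (slope 9.973e-04 + SE 6.578e-05), intercept 1.008, R^2 0.970
analytic slope for independent SNPs, 1/M: 1.001e-03
```

With no polygenic background the test is calibrated (mean Z² ≈ 1). At
h²_δ = 0.5 the mean Z² matches the analytic 1 + N·h²_δ/M, and the grid
regression recovers Φ ≈ 1/M = 1.0×10⁻³. Note Φ scales as 1/M: desk-scale
simulations with M ≈ 10³ SNPs give Φ ≈ 10⁻³, while genome-wide panels with
M ≈ 10⁶ give the 10⁻⁵ magnitudes seen in real TWAS. Applying the correction
to an external association (`tc.variance_control`) divides Z by
√(1 + Φ·N·h²_δ) and recomputes the two-sided p value; at real-data scale
(N = 100,000, h²_δ = 0.5, Φ = 4.2×10⁻⁵) the factor is √3.1 ≈ 1.76, so
z = 3.0 becomes z_corr ≈ 1.70.

The same pipeline from the shell:

```sh
twascal simulate-genotypes --n 1000 --m 999 --maf 0.4 --seed 1 --out dos.tsv
twascal simulate-weights --genotypes dos.tsv --n-mediators 1 --seed 2 --out w.tsv
twascal estimate-phi --genotypes dos.tsv --weights w.tsv --out phi.tsv
twascal correct assoc.tsv --n 100000 --h2 0.5 --phi-table phi.tsv --out corrected.tsv
```

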