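# Methods

This note documents the statistical models implemented in `paradiv`,
the numerical choices behind them, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Occupancy under independent Poisson sampling

The parallelism null treats each population *j* as scattering its
`n_tot,j` mutations independently over genes with probabilities `p_i`;
conditional on the total, each gene's count is binomial, and
unconditionally the counts behave as independent Poisson variables.
The per-gene probability is estimated by **pooling across all M
populations**, `p̂_i = Σ_j n_i,j / Σ_j n_tot,j`. Read within a single
population the plug-in estimate would be self-referential (the
prediction would reuse the very observation it predicts); pooling makes
the occupancy formula

    o_i = 1 − (1/M) Σ_j (1 − p̂_i)^{n_tot,j}

a genuine zero-free-parameter prediction. A leave-one-out pooling would
change predictions only at O(1/M). The empty-product convention
`(1 − p̂_i)^0 = 1` means mutation-free populations contribute absence
deterministically.

The **geometric alternative** is the mean-matched geometric law on
{0, 1, 2, …}: matching the Poisson model's per-population mean
`μ_i,j = p̂_i·n_tot,j` fixes its absence probability at `1/(1 + μ_i,j)`
with no further freedom, preserving the zero-parameter character of the
comparison. Under it the tail is heavier, so for genes with
appreciable rates it over-predicts absence and loses to the Poisson
model on most genes — the behaviour the error summary quantifies via
`fraction_poisson_better` (ties in absolute error, common when both
models predict 0, are excluded from numerator and denominator and
reported as a count).

**Error summaries** default to genes with at least one pooled mutation:
never-hit genes are predicted perfectly at zero by both models and
would only dilute the MAE; `include_zero_genes=True` restores the full
average. Subsampling for the error-vs-replication curve is without
replacement, driven by an explicit `numpy` Generator seeded by the
caller; no global RNG state is touched anywhere in the package.

## Multiplicity and the eigenvalue covariance test

Gene length is a nuisance covariate for covariance detection, so counts
are rescaled to multiplicities `m_i,j = n_i,j·L̄/L_i` with `L̄` the mean
number of nonsynonymous sites over **all annotated genes** (the genome),
not just mutated ones. Genes with zero total mutations contribute no
variance and are dropped before decomposition (their number is recorded
in the result).

The statistic is the largest eigenvalue of the M×M population-level
Gram matrix of the gene-mean-centered multiplicity matrix, trace-
normalised (`e_1 = M·E_1/Σ E_m`, so the spectrum sums to M) and
standardised with the Tracy–Widom centering and scaling for sample
covariance spectra,

    μ(M, N) = (√(N−1) + √M)²/N,
    σ(M, N) = ((√(N−1) + √M)/N)·(1/√(N−1) + 1/√M)^{1/3}.

For large iid matrices `ẽ_1 = (e_1 − μ)/σ` approaches the Tracy–Widom
TW1 law (the test suite verifies the location empirically on Gaussian
matrices). We do **not** use the TW quantiles for inference: the counts
are small, sparse and integer, far from the asymptotic regime, so the
null distribution of `ẽ_1` is generated by randomization instead.

**Fixed-margin randomization.** Null tables preserve both the per-gene
totals and the per-population totals of the *integer counts* (the
multiplicity correction is re-applied after randomization — margins are
mutation totals, not real-valued multiplicities). Sampling is by
Patefield's conditional algorithm via `scipy.stats.random_table`, which
draws uniformly from the hypergeometric (conditional-independence)
distribution over tables with those margins; the test suite checks it
against an exact enumeration of all admissible tables on small margins.
Because the conditional distribution of an independently-sampled count
table given its margins is exactly this distribution regardless of the
underlying gene rates, the permutation test is exact: rate
heterogeneity between genes does not inflate its size.

The P value uses the add-one estimator
`(1 + #{null ≥ observed})/(1 + permutations)`, which is never zero and
valid at any permutation count.

**Centering.** Gene-mean centering removes the one trivial direction
(the all-ones population vector) and is applied identically to observed
and null matrices, so it cannot bias the test; it does shift the
*absolute* value of `ẽ_1` slightly relative to the raw-matrix TW
limit (one population degree of freedom is consumed), which is why the
Gaussian location check runs uncentered. Centering can be disabled with
a flag.

**Detection vs replication.** The `detection_vs_replication` curve
subsamples M′ populations and compares each subsample's observed
statistic to a single randomization draw. At M′ equal to the full M the
subsample is always the same matrix, so the "fraction above null"
degenerates to a fixed null quantile; meaningful curves use sizes below
the number of available populations.

## The Skellam divergence test

The difference of two independent Poisson counts follows the Skellam
distribution; folding onto |Δn| gives the null law of the per-gene
absolute count difference between treatments. The null rates are
**uniform across genes**, `λ_k = n_tot^(k)/N_genes` — deliberately
ignoring gene length and per-gene rate variation, so the test asks
whether a difference is too large for *any* exchangeable gene.
`N_genes` should be the genome-wide gene count (taken from the
annotation when supplied); it rescales λ and therefore every P value,
so it is recorded in each report header.

Numerics: the pmf is evaluated in log space with the exponentially
scaled Bessel function `ive`, using
`e^{−(λ1+λ2)} I_k(2√(λ1λ2)) = ive(k, 2√(λ1λ2)) e^{−(√λ1−√λ2)²}`, and
the two folded terms are combined with `logaddexp`; this is stable for
arbitrarily large or asymmetric rates. When one rate is zero the
`(λ1/λ2)^{k/2}` prefactor is degenerate and the law reduces to a pure
Poisson on |Δn|, handled as an explicit branch; when both are zero the
law is a point mass at 0. Upper-tail P values are computed by reverse
cumulative summation over a support truncated where a geometric-ratio
majorant bounds the remaining mass below 1e-15, so P values are
accurate to ~1e-14 and monotone in k by construction; P(0) is pinned to
exactly 1.

**Discrete FDR.** Because P_i depends on the data only through the
integer k, achievable significance levels form a finite set and the
expected number of null discoveries at level P collapses to a tail
evaluation: `N̄(P) = N_genes·S(max(k*(P), n_min))` with `k*(P)` the
smallest k whose P value is ≤ P. The critical level P* is the
**largest** achievable level with `N̄(P*)/N(P*) ≤ α`, maximising
discoveries at the stated FDR; if none qualifies the significant set is
empty. `n_min` (default 1: every gene with any difference is eligible)
exists to reduce the number of discrete tests and is surfaced as an
explicit option. Across more than two treatments, per-pair results are
combined by intersection — a gene is assigned to treatment t only if it
is significant with direction t in every pair involving t — with no
additional correction across pairs.

**Calibration caveat.** The uniform-rate null makes the test exact when
genes really are exchangeable; under strong per-gene rate heterogeneity
shared by both treatments, high-rate genes produce large |Δn| by
variance alone and the test becomes anticonservative. This is a
property of the method, not the implementation: the calibration
simulations therefore draw from the test's own null (uniform rates),
and users with strongly heterogeneous genomes should treat borderline
discoveries with caution (a length-weighted extension hook exists in
the null-rate construction but is off by default, matching the method).

## Synthetic data

`simulate_counts` draws, per population, a total `n_tot,j` (Poisson
with configurable mean, or fixed) and allocates it multinomially over
genes — exactly the sampling frame of the occupancy model, which makes
margin bookkeeping exact (column sums equal drawn totals always).
Treatment enrichment multiplies a gene's rate by a fold-change and
renormalises; covariance is injected by a per-population LogNormal(0,
σ²) multiplier shared by a gene set (multiplicative, hence
nonnegativity-preserving), also renormalised. Gene lengths are
log-normal (mean 1000 nonsynonymous sites, σ = 0.5 on the log scale),
independent of rates by default since the divergence null ignores
length.

What it does *not* emulate: linkage and clonal interference, selection
(rates are fixed, not fitness-derived), mutational spectra, within-gene
site structure, or sequencing error. Passing tests on this generator
show the statistics behave as designed under their own assumptions —
they do not certify robustness to those real-data features.

Default study conditions used across the test and acceptance suites
(chosen as typical of the experiments this framework targets, and kept
fixed): divergence calibration and power use 6 populations per
treatment; calibration uses 500 genes with ~50 mutations per population,
power uses 200 genes, ~100 mutations per population and a 10-fold
enrichment; occupancy error is traced at M = 25/100/500 with 100 genes
and ~20 mutations per population; covariance size uses 30 populations
and power 100 populations with a σ = 2 latent factor on a 10-gene set
(effect size fixed after pilot simulation). Permutation counts in the
simulation studies are 99 per test (P resolution 0.01), which keeps the
full validation suite at a few minutes on one core.

## Limitations

- The framework operates on a user-supplied gene universe; how
  intergenic mutations were assigned (or dropped) upstream is the
  user's responsibility and changes `N_genes`, hence λ.
- The covariance test detects a *global* signal only; per-pair gene
  covariances are deliberately not estimated (counts are too sparse).
- The divergence null's exchangeability assumption (above) makes it
  anticonservative under strong shared rate heterogeneity.
- Treatment pairs are tested marginally and combined by intersection;
  no multiplicity correction is applied across the pairs themselves.
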