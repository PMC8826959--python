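"""Global gene–gene covariance detection via the largest eigenvalue.

Counts are first length-corrected to multiplicities m_i,j = n_i,j·L̄/L_i
(L_i the number of nonsynonymous sites of gene i, L̄ the genome-wide
mean), so that long genes do not masquerade as covariance. The largest
eigenvalue E_1 of the population-level covariance spectrum of the
gene-centered multiplicity matrix is normalized as e_1 = M·E_1/Σ E_m
and centered/scaled with the Tracy–Widom constants

    μ(M, N) = (√(N−1) + √M)² / N
    σ(M, N) = ((√(N−1) + √M)/N) · (1/√(N−1) + 1/√M)^{1/3},

under which ẽ_1 = (e_1 − μ)/σ tends to the Tracy–Widom law for large
independent matrices. Significance is nevertheless assessed against a
randomization null: integer count tables with the observed row and
column margins, drawn uniformly under the conditional independence
model by Patefield's algorithm, each re-corrected for gene length and
re-decomposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneAnnotation, MutationCountMatrix, ValidationError


@dataclass
class MultiplicityMatrix:
    """Length-corrected mutation counts, same labels as the source matrix."""

    gene_ids: list[str]
    population_ids: list[str]
    values: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_populations(self) -> int:
        return len(self.population_ids)


def multiplicity_matrix(matrix: MutationCountMatrix, annotation: GeneAnnotation) -> MultiplicityMatrix:
    """m_i,j = n_i,j · L̄ / L_i with L̄ averaged over the whole annotation."""
    mean_L = annotation.mean_length
    lengths = np.array([annotation.length_of(g) for g in matrix.gene_ids])
    values = matrix.counts * (mean_L / lengths)[:, None]
    return MultiplicityMatrix(
        gene_ids=list(matrix.gene_ids),
        population_ids=list(matrix.population_ids),
        values=values,
    )


def tw_center(M: int, n_genes: int) -> float:
    """Tracy–Widom centering μ(M, N_genes)."""
    return (np.sqrt(n_genes - 1) + np.sqrt(M)) ** 2 / n_genes


def tw_scale(M: int, n_genes: int) -> float:
    """Tracy–Widom scaling σ(M, N_genes)."""
    return ((np.sqrt(n_genes - 1) + np.sqrt(M)) / n_genes) * (
        1.0 / np.sqrt(n_genes - 1) + 1.0 / np.sqrt(M)
    ) ** (1.0 / 3.0)


def normalized_eigenvalues(values: np.ndarray, center: bool = True) -> np.ndarray:
    """Eigenvalues e_m of the population-level spectrum, scaled to sum to M.

    ``values`` is genes x populations. Rows (genes) are mean-centered by
    default; the M x M Gram matrix of population profiles is then
    decomposed. Eigenvalues are returned in decreasing order.
    """
    X = np.asarray(values, dtype=float)
    n_genes, M = X.shape
    if M < 2 or n_genes < 2:
        raise ValidationError("eigen-analysis needs >= 2 populations and >= 2 genes")
    if center:
        X = X - X.mean(axis=1, keepdims=True)
    gram = X.T @ X
    evals = np.linalg.eigvalsh(gram)[::-1]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    if total <= 0:
        raise ValidationError("multiplicity matrix has zero variance (rank 0 after centering)")
    return M * evals / total


def normalized_largest_eigenvalue(mult: MultiplicityMatrix | np.ndarray, center: bool = True) -> float:
    """ẽ_1 = (e_1 − μ)/σ for the gene-centered multiplicity matrix."""
    values = mult.values if isinstance(mult, MultiplicityMatrix) else np.asarray(mult)
    n_genes, M = values.shape
    e = normalized_eigenvalues(values, center=center)
    return float((e[0] - tw_center(M, n_genes)) / tw_scale(M, n_genes))


def fixed_margin_randomize(matrix: MutationCountMatrix, rng: np.random.Generator) -> MutationCountMatrix:
    """Random count table with exactly the input's row and column sums.

    Drawn by Patefield's conditional algorithm (uniform over tables under
    the independence/hypergeometric model). The input is not modified.
    """
    row = matrix.gene_totals
    col = matrix.population_totals
    if row.sum() == 0:
        raise ValidationError("cannot randomize an all-zero matrix")
    table = stats.random_table(row, col, seed=rng).rvs(method="patefield")
    table = np.asarray(table, dtype=np.int64)
    return MutationCountMatrix(
        gene_ids=list(matrix.gene_ids),
        population_ids=list(matrix.population_ids),
        counts=table,
        treatment_of=dict(matrix.treatment_of),
    )


@dataclass
class CovarianceTestResult:
    """Observed ẽ_1, its randomization null sample, and the P value."""

    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    permutations: int
    seed: int
    M: int
    n_genes: int
    n_genes_dropped: int
    centered: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observed_stat": [self.observed_stat],
                "p_value": [self.p_value],
                "permutations": [self.permutations],
                "seed": [self.seed],
                "M": [self.M],
                "n_genes": [self.n_genes],
                "n_genes_dropped": [self.n_genes_dropped],
            }
        )


def _drop_zero_genes(matrix: MutationCountMatrix) -> tuple[MutationCountMatrix, int]:
    keep = matrix.gene_totals > 0
    dropped = int((~keep).sum())
    if dropped == 0:
        return matrix, 0
    kept = MutationCountMatrix(
        gene_ids=[g for g, k in zip(matrix.gene_ids, keep) if k],
        population_ids=list(matrix.population_ids),
        counts=matrix.counts[keep],
        treatment_of=dict(matrix.treatment_of),
    )
    return kept, dropped


def covariance_test(
    matrix: MutationCountMatrix,
    annotation: GeneAnnotation,
    permutations: int = 10_000,
    seed: int = 0,
    center: bool = True,
) -> CovarianceTestResult:
    """Randomization test for a global covariance signal.

    The observed ẽ_1 comes from the multiplicity correction of the real
    counts; each null draw randomizes the integer counts under fixed
    margins first and applies the same correction. The one-sided
    upper-tail P value uses the add-one estimator
    (1 + #{null ≥ observed}) / (1 + permutations), so it is never zero.
    """
    if permutations < 1:
        raise ValidationError("permutations must be >= 1")
    work, dropped = _drop_zero_genes(matrix)
    observed = normalized_largest_eigenvalue(multiplicity_matrix(work, annotation), center=center)
    rng = np.random.default_rng(seed)
    null_stats = np.empty(permutations)
    for b in range(permutations):
        rand = fixed_margin_randomize(work, rng)
        null_stats[b] = normalized_largest_eigenvalue(
            multiplicity_matrix(rand, annotation), center=center
        )
    p = (1 + int((null_stats >= observed).sum())) / (1 + permutations)
    return CovarianceTestResult(
        observed_stat=observed,
        null_stats=null_stats,
        p_value=p,
        permutations=permutations,
        seed=seed,
        M=work.n_populations,
        n_genes=work.n_genes,
        n_genes_dropped=dropped,
        centered=center,
    )


def detection_vs_replication(
    matrix: MutationCountMatrix,
    annotation: GeneAnnotation,
    sizes,
    reps: int,
    seed: int = 0,
    center: bool = True,
) -> pd.DataFrame:
    """Fraction of observed ẽ_1 exceeding a single null draw, per M'.

    For each subsample size, populations are drawn without replacement,
    the observed statistic is computed on the subsample, and one
    margin-preserving randomization provides its null counterpart. The
    returned fraction estimates the detectability of covariance at that
    replication level.
    """
    M = matrix.n_populations
    sizes = [int(s) for s in sizes]
    for s in sizes:
        if not (2 <= s <= M):
            raise ValidationError(f"subsample size {s} outside [2, {M}]")
    rng = np.random.default_rng(seed)
    rows = []
    for s in sizes:
        wins = 0
        for _ in range(reps):
            idx = sorted(rng.choice(M, size=s, replace=False))
            sub = matrix.subset_populations([matrix.population_ids[i] for i in idx])
            sub, _ = _drop_zero_genes(sub)
            obs = normalized_largest_eigenvalue(multiplicity_matrix(sub, annotation), center=center)
            rand = fixed_margin_randomize(sub, rng)
            null = normalized_largest_eigenvalue(multiplicity_matrix(rand, annotation), center=center)
            wins += obs > null
        rows.append((s, wins / reps))
    return pd.DataFrame(rows, columns=["n_populations", "fraction_above_null"])
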