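"""Zero-free-parameter prediction of gene occupancy across replicates.

Under the null model, each population j acquires its n_tot,j mutations
independently, each landing in gene i with probability p_i. Pooling
counts over all M replicate populations gives the plug-in estimate

    p̂_i = Σ_j n_i,j / Σ_j n_tot,j,

and the predicted occupancy (fraction of populations with at least one
hit in gene i) follows with no further free parameters:

    o_i = 1 − (1/M) Σ_j (1 − p̂_i)^{n_tot,j}.

A mean-matched geometric count law serves as the alternative model: a
geometric distribution on {0, 1, 2, …} with mean μ has absence
probability 1/(1+μ), so o_i^G = 1 − (1/M) Σ_j 1/(1 + p̂_i · n_tot,j).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MutationCountMatrix, ValidationError


def pooled_gene_probabilities(matrix: MutationCountMatrix) -> np.ndarray:
    """Per-gene hit probabilities p̂_i pooled across all populations.

    Sums to 1; raises if the matrix contains no mutations at all.
    """
    gene_totals = matrix.gene_totals
    total = gene_totals.sum()
    if total == 0:
        raise ValidationError("no mutations to estimate rates")
    return gene_totals / total


def observed_occupancy(matrix: MutationCountMatrix) -> np.ndarray:
    """Fraction of populations carrying >=1 mutation in each gene."""
    return (matrix.counts >= 1).mean(axis=1)


def predicted_occupancy_poisson(matrix: MutationCountMatrix, p_hat=None) -> np.ndarray:
    """Predicted occupancy under independent multinomial/Poisson sampling."""
    if p_hat is None:
        p_hat = pooled_gene_probabilities(matrix)
    n_tot = matrix.population_totals  # (M,)
    # absence prob per gene x population: (1 - p_i)^{n_tot,j}; 0^0 == 1
    absent = (1.0 - p_hat)[:, None] ** n_tot[None, :]
    return 1.0 - absent.mean(axis=1)


def predicted_occupancy_geometric(matrix: MutationCountMatrix, p_hat=None) -> np.ndarray:
    """Predicted occupancy under the mean-matched geometric alternative."""
    if p_hat is None:
        p_hat = pooled_gene_probabilities(matrix)
    n_tot = matrix.population_totals
    absent = 1.0 / (1.0 + p_hat[:, None] * n_tot[None, :])
    return 1.0 - absent.mean(axis=1)


@dataclass
class OccupancyReport:
    """Observed and predicted occupancy per gene, with error summaries.

    ``mae_poisson``/``mae_geometric`` are mean absolute errors over the
    genes selected by ``include_zero_genes``; ``fraction_poisson_better``
    is the share of compared genes (ties excluded) where the Poisson
    prediction is strictly closer to the observation.
    """

    gene_ids: list[str]
    observed: np.ndarray
    predicted_poisson: np.ndarray
    predicted_geometric: np.ndarray
    pooled_probability: np.ndarray
    mae_poisson: float
    mae_geometric: float
    fraction_poisson_better: float
    n_ties: int
    n_compared: int
    include_zero_genes: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "observed": self.observed,
                "predicted_poisson": self.predicted_poisson,
                "predicted_geometric": self.predicted_geometric,
                "abs_err_poisson": np.abs(self.predicted_poisson - self.observed),
                "abs_err_geometric": np.abs(self.predicted_geometric - self.observed),
            }
        )


def occupancy_error(observed, predicted_poisson, predicted_geometric, mask=None):
    """MAE of each model and the fraction of genes where Poisson wins.

    Ties in absolute error (common when both models predict 0 for an
    unmutated gene) are excluded from both numerator and denominator of
    ``fraction_poisson_better``; the tie count is returned.
    """
    observed = np.asarray(observed, dtype=float)
    predicted_poisson = np.asarray(predicted_poisson, dtype=float)
    predicted_geometric = np.asarray(predicted_geometric, dtype=float)
    if not (observed.shape == predicted_poisson.shape == predicted_geometric.shape):
        raise ValidationError("occupancy vectors must cover the same gene set")
    if mask is None:
        mask = np.ones_like(observed, dtype=bool)
    err_p = np.abs(predicted_poisson - observed)[mask]
    err_g = np.abs(predicted_geometric - observed)[mask]
    mae_p = float(err_p.mean()) if err_p.size else 0.0
    mae_g = float(err_g.mean()) if err_g.size else 0.0
    ties = err_p == err_g
    n_ties = int(ties.sum())
    n_compared = int((~ties).sum())
    frac = float((err_p < err_g)[~ties].mean()) if n_compared else float("nan")
    return mae_p, mae_g, frac, n_ties, n_compared


def occupancy_report(matrix: MutationCountMatrix, include_zero_genes: bool = False) -> OccupancyReport:
    """Full per-gene occupancy comparison for one environment.

    By default the error summaries average only over genes with at least
    one pooled mutation (genes never hit are predicted perfectly at 0 by
    both models and would dilute the MAE); set ``include_zero_genes`` to
    average over every row.
    """
    p_hat = pooled_gene_probabilities(matrix)
    obs = observed_occupancy(matrix)
    pred_p = predicted_occupancy_poisson(matrix, p_hat)
    pred_g = predicted_occupancy_geometric(matrix, p_hat)
    mask = None if include_zero_genes else (matrix.gene_totals > 0)
    mae_p, mae_g, frac, n_ties, n_compared = occupancy_error(obs, pred_p, pred_g, mask)
    return OccupancyReport(
        gene_ids=list(matrix.gene_ids),
        observed=obs,
        predicted_poisson=pred_p,
        predicted_geometric=pred_g,
        pooled_probability=p_hat,
        mae_poisson=mae_p,
        mae_geometric=mae_g,
        fraction_poisson_better=frac,
        n_ties=n_ties,
        n_compared=n_compared,
        include_zero_genes=include_zero_genes,
    )


def subsample_error_curve(
    matrix: MutationCountMatrix,
    sizes,
    reps: int,
    seed: int,
    include_zero_genes: bool = False,
) -> pd.DataFrame:
    """Prediction error as a function of the number of replicates.

    For each subsample size M' the populations are resampled without
    replacement ``reps`` times; p̂, predictions, observed occupancy and
    the Poisson MAE are recomputed within each subset. Returns a table
    with columns (n_populations, mean_mae, sd_mae). Deterministic for a
    given ``seed``.
    """
    M = matrix.n_populations
    sizes = [int(s) for s in sizes]
    for s in sizes:
        if s < 2:
            raise ValidationError(f"subsample size {s} < 2")
        if s > M:
            raise ValidationError(f"subsample size {s} exceeds the {M} populations available")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for s in sizes:
        maes = np.empty(reps)
        for r in range(reps):
            idx = rng.choice(M, size=s, replace=False)
            sub = matrix.subset_populations([matrix.population_ids[i] for i in sorted(idx)])
            rep = occupancy_report(sub, include_zero_genes=include_zero_genes)
            maes[r] = rep.mae_poisson
        rows.append((s, float(maes.mean()), float(maes.std(ddof=1)) if reps > 1 else 0.0))
    return pd.DataFrame(rows, columns=["n_populations", "mean_mae", "sd_mae"])
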