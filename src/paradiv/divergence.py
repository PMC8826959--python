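"""Skellam test for divergent evolution between two environments.

If gene-level mutation counts within each environment are independent
Poisson variables, the difference of a gene's counts between two
environments follows the Skellam distribution, and its absolute value
|Δn_i| = |n_i^(1) − n_i^(2)| folds that law onto the nonnegative
integers:

    Pr[|Δn| = k] = e^{−(λ1+λ2)} [ (λ1/λ2)^{k/2} I_k(2√(λ1λ2))
                                 + (λ2/λ1)^{k/2} I_k(2√(λ1λ2)) ],  k > 0
    Pr[|Δn| = 0] = e^{−(λ1+λ2)} I_0(2√(λ1λ2)),

with I_k the modified Bessel function of the first kind and null rates
λ_k = n_tot^(k)/N_genes (the same rate for every gene: the null carries
no per-gene information, by construction). The per-gene P value is the
upper tail P_i = Σ_{k ≥ |Δn_i|} Pr[|Δn| = k].

Because the statistic is discrete, P values take only the achievable
levels {P(k)}; the false-discovery threshold P* is the largest level at
which the expected number of null discoveries,
N̄(P) = N_genes · Σ_{k ≥ n_min} θ(P − P(k))·Pr[|Δn| = k], stays within
a fraction α of the observed discovery count N(P).

All Bessel evaluations use the exponentially scaled `ive` in log space,
so the pmf is stable for arbitrarily large or asymmetric rates; when one
rate is zero the law degenerates to a pure Poisson and is evaluated by
that branch directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import TreatmentPair, ValidationError

_TAIL_EPS = 1e-15


@dataclass(frozen=True)
class SkellamNull:
    """Shared-rate null for |Δn|: λ_k = n_tot^(k) / N_genes."""

    lambda_1: float
    lambda_2: float
    n_genes: int

    def __post_init__(self) -> None:
        if self.lambda_1 < 0 or self.lambda_2 < 0:
            raise ValidationError("null rates must be nonnegative")
        if self.n_genes < 1:
            raise ValidationError("N_genes must be positive")

    @classmethod
    def from_totals(cls, n_tot_1: int, n_tot_2: int, n_genes: int) -> "SkellamNull":
        return cls(n_tot_1 / n_genes, n_tot_2 / n_genes, n_genes)


def _log_abs_pmf(k: np.ndarray, lam1: float, lam2: float) -> np.ndarray:
    """log Pr[|Δn| = k] for strictly positive rates, vectorized over k."""
    k = np.asarray(k)
    x = 2.0 * np.sqrt(lam1 * lam2)
    # e^{-(λ1+λ2)} I_k(x) = ive(k, x) · e^{x - (λ1+λ2)} = ive(k, x) · e^{-(√λ1-√λ2)²}
    with np.errstate(divide="ignore"):  # ive underflow far in the tail -> pmf 0
        base = np.log(special.ive(k, x)) - (np.sqrt(lam1) - np.sqrt(lam2)) ** 2
    half_ratio = 0.5 * k * (np.log(lam1) - np.log(lam2))
    # k>0 folds two Skellam terms: (λ1/λ2)^{k/2} + (λ2/λ1)^{k/2}
    fold = np.logaddexp(half_ratio, -half_ratio)
    return np.where(k == 0, base, base + fold)


def skellam_abs_pmf(k, null: SkellamNull):
    """Pr[|Δn| = k] under the folded Skellam null. Vectorized over k.

    Symmetric in (λ1, λ2). Degenerates to a Poisson law on k when one
    rate is zero, and to a point mass at zero when both are.
    """
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or not np.issubdtype(k_arr.dtype, np.integer):
        k_float = np.asarray(k, dtype=float)
        if np.any(k_float < 0) or np.any(k_float != np.floor(k_float)):
            raise ValidationError("k must be a nonnegative integer")
        k_arr = k_float.astype(np.int64)
    lam1, lam2 = null.lambda_1, null.lambda_2
    if lam1 == 0.0 and lam2 == 0.0:
        out = np.where(k_arr == 0, 1.0, 0.0)
    elif lam1 == 0.0 or lam2 == 0.0:
        out = stats.poisson.pmf(k_arr, lam1 + lam2)
    else:
        out = np.exp(_log_abs_pmf(k_arr, lam1, lam2))
    return float(out) if np.isscalar(k) else out


def _support_pmf(null: SkellamNull, k_min_len: int = 0) -> np.ndarray:
    """pmf over 0..K where the truncated tail beyond K is < 1e-15.

    K starts at mean + 10·sd + 20 of the unfolded difference and grows
    until the ratio-test majorant bounds the remaining mass below the
    tolerance (terms eventually decay faster than geometrically).
    """
    lam = null.lambda_1 + null.lambda_2
    K = int(np.ceil(lam + 10.0 * np.sqrt(lam) + 20.0))
    K = max(K, k_min_len)
    while True:
        k = np.arange(K + 1)
        pmf = skellam_abs_pmf(k, null)
        if pmf[-1] == 0.0:
            return pmf
        ratio = pmf[-1] / pmf[-2] if pmf[-2] > 0 else 0.0
        if ratio < 1.0 and pmf[-1] * ratio / (1.0 - ratio) < _TAIL_EPS:
            return pmf
        K *= 2


def _survival(null: SkellamNull, k_min_len: int = 0) -> np.ndarray:
    """S[k] = Pr[|Δn| >= k] for k = 0..K, with S[0] = 1 exactly.

    Computed by reverse cumulative summation of the truncated pmf, so
    small tail values are accurate and S is monotone by construction.
    """
    pmf = _support_pmf(null, k_min_len)
    s = np.cumsum(pmf[::-1])[::-1]
    s[0] = 1.0
    return s


def divergence_p_value(k_obs, null: SkellamNull):
    """Upper-tail P value P = Σ_{k ≥ k_obs} Pr[|Δn| = k]. Vectorized.

    P(0) = 1 exactly; beyond the truncated support the tail is below
    1e-15 and the P value is reported as 0.0 there only when the null
    assigns literally no mass (both rates zero); otherwise it is the
    computed tail.
    """
    scalar = np.isscalar(k_obs)
    k_arr = np.atleast_1d(np.asarray(k_obs, dtype=np.int64))
    if np.any(k_arr < 0):
        raise ValidationError("k_obs must be nonnegative")
    s = _survival(null, k_min_len=int(k_arr.max()) + 1)
    out = s[np.minimum(k_arr, len(s) - 1)].astype(float)
    out[k_arr > len(s) - 1] = 0.0
    return float(out[0]) if scalar else out


def expected_significant(P: float, null: SkellamNull, n_min: int = 1) -> float:
    """N̄(P): expected genes with |Δn| ≥ n_min and P_i ≤ P under the null.

    Because P_i depends on the counts only through k, the Heaviside sum
    collapses to a tail: N̄(P) = N_genes · S(max(k*(P), n_min)) with
    k*(P) the smallest k whose P value is ≤ P.
    """
    if not (0.0 < P <= 1.0):
        raise ValidationError("P must be in (0, 1]")
    if n_min < 0:
        raise ValidationError("n_min must be >= 0")
    s = _survival(null, k_min_len=n_min + 1)
    # tolerance absorbs last-ulp differences between survival arrays of
    # different truncation lengths when P is itself an achievable level
    qualifying = np.nonzero(s <= P * (1.0 + 1e-12) + 1e-15)[0]
    if qualifying.size == 0:
        return 0.0  # P below every achievable level in the support
    k_star = int(qualifying[0])
    k_eff = max(k_star, n_min)
    tail = s[k_eff] if k_eff < len(s) else 0.0
    return null.n_genes * float(tail)


def critical_p_value(observed_k, null: SkellamNull, alpha: float, n_min: int = 1):
    """Discrete-FDR threshold P* and the significant-gene mask.

    Candidate thresholds are the achievable P values {P(k)} of the
    observed counts with k ≥ n_min. P* is the largest candidate with
    N̄(P*) / N(P*) ≤ α, maximizing discoveries at the stated FDR;
    returns (None, all-False mask, table) when no candidate qualifies.
    The table lists every candidate with its N̄, N and ratio.
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must be in (0, 1)")
    observed_k = np.asarray(observed_k, dtype=np.int64)
    if observed_k.size == 0:
        raise ValidationError("no observed counts supplied")
    p_obs = divergence_p_value(observed_k, null)
    tested = observed_k >= max(n_min, 1)
    candidates = np.unique(p_obs[tested])
    rows = []
    p_star = None
    for P in candidates:
        if P <= 0.0:
            # beyond the support: the null puts no measurable mass here
            n_bar = 0.0
        else:
            n_bar = expected_significant(float(P), null, n_min=n_min)
        n_obs = int(((p_obs <= P) & tested).sum())
        ratio = n_bar / n_obs if n_obs else np.inf
        rows.append((float(P), n_bar, n_obs, ratio))
        if ratio <= alpha and (p_star is None or P > p_star):
            p_star = float(P)
    table = pd.DataFrame(rows, columns=["p_level", "expected_significant", "observed_significant", "ratio"])
    if p_star is None:
        return None, np.zeros_like(tested), table
    significant = tested & (p_obs <= p_star)
    return p_star, significant, table


@dataclass
class DivergenceReport:
    """Per-gene divergence test for one pair of treatments."""

    label_1: str
    label_2: str
    gene_ids: list[str]
    n_1: np.ndarray
    n_2: np.ndarray
    abs_delta: np.ndarray
    direction: np.ndarray  # enriched treatment label, or "none" when Δn = 0
    p_values: np.ndarray
    significant: np.ndarray
    p_star: float | None
    alpha: float
    n_min: int
    n_genes_null: int
    null: SkellamNull
    n_tested: int
    expected_table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "n_1": self.n_1,
                "n_2": self.n_2,
                "abs_delta_n": self.abs_delta,
                "direction": self.direction,
                "p_value": self.p_values,
                "significant": self.significant,
            }
        )

    @property
    def significant_genes(self) -> list[str]:
        return [g for g, s in zip(self.gene_ids, self.significant) if s]


def divergence_test(
    pair: TreatmentPair,
    n_genes: int | None = None,
    alpha: float = 0.05,
    n_min: int = 1,
) -> DivergenceReport:
    """Run the full Skellam divergence test on one treatment pair.

    ``n_genes`` sets the size of the gene universe defining the null
    rates λ_k = n_tot^(k)/N_genes; it defaults to the number of genes in
    the pair (use the genome-wide annotation count when available, since
    λ depends on it). Deterministic: no randomness anywhere.
    """
    if n_genes is None:
        n_genes = len(pair.gene_ids)
    if pair.n_tot_1 == 0 and pair.n_tot_2 == 0:
        raise ValidationError("no mutations in either treatment")
    if n_min < 1:
        raise ValidationError("n_min must be >= 1")
    null = SkellamNull.from_totals(pair.n_tot_1, pair.n_tot_2, n_genes)
    k = pair.abs_delta
    p_vals = divergence_p_value(k, null)
    p_star, significant, table = critical_p_value(k, null, alpha=alpha, n_min=n_min)
    delta = pair.n_1 - pair.n_2
    direction = np.where(delta > 0, pair.label_1, np.where(delta < 0, pair.label_2, "none"))
    return DivergenceReport(
        label_1=pair.label_1,
        label_2=pair.label_2,
        gene_ids=list(pair.gene_ids),
        n_1=pair.n_1,
        n_2=pair.n_2,
        abs_delta=k,
        direction=direction,
        p_values=p_vals,
        significant=significant,
        p_star=p_star,
        alpha=alpha,
        n_min=n_min,
        n_genes_null=n_genes,
        null=null,
        n_tested=int((k >= n_min).sum()),
        expected_table=table,
    )


def consistent_enrichment(reports: dict[tuple[str, str], DivergenceReport]) -> dict[str, list[str]]:
    """Genes significantly enriched toward one treatment in every pair.

    Gene g is assigned to treatment t iff in EVERY pairwise comparison
    involving t, g is significant with direction t. A gene can satisfy
    this for at most one treatment (directions conflict otherwise).
    """
    treatments = sorted({t for pair in reports for t in pair})
    import itertools

    expected = set(itertools.combinations(treatments, 2))
    present = {tuple(sorted(p)) for p in reports}
    missing = expected - present
    if missing:
        raise ValidationError(f"missing pairwise comparisons: {sorted(missing)}")
    assigned: dict[str, list[str]] = {t: [] for t in treatments}
    for t in treatments:
        relevant = [r for pair, r in reports.items() if t in pair]
        gene_ids = relevant[0].gene_ids
        ok = np.ones(len(gene_ids), dtype=bool)
        for r in relevant:
            ok &= r.significant & (r.direction == t)
        assigned[t] = [g for g, v in zip(gene_ids, ok) if v]
    return assigned
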