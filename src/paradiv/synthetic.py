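"""Synthetic count matrices with the structure the framework assumes.

The generator mirrors the sampling frame of the null model exactly:
each population draws its total mutation count n_tot,j (fixed or
Poisson), then allocates the hits multinomially over genes according to
its treatment's rate vector. Treatment-specific enrichment multiplies
and renormalizes rates; gene–gene covariance is injected by a shared
log-normal latent multiplier per population acting on a designated gene
set. Ground truth (true rates, enriched and covarying genes) is
returned for recovery tests. Every output is a pure function of the
config, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import GeneAnnotation, MutationCountMatrix, TreatmentPair, ValidationError


@dataclass
class EnrichmentSpec:
    """Multiply one gene's rate by ``fold`` within one treatment."""

    gene_index: int
    treatment: str
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValidationError("enrichment fold-change must be > 0")


@dataclass
class CovarianceSpec:
    """Shared log-normal latent factor over a gene set.

    Per population, all genes in ``gene_indices`` have their rates
    multiplied by a common LogNormal(0, sigma²) draw (then renormalized),
    which induces positive covariance within the set.
    """

    gene_indices: list[int]
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("latent-factor sigma must be >= 0")


@dataclass
class SimulationConfig:
    """All knobs of the generator.

    Defaults emulate a modest evolve-and-resequence experiment: a few
    hundred genes, a handful of replicate populations per treatment,
    Poisson-distributed per-population totals of a few tens of
    mutations, and moderately heterogeneous per-gene rates (symmetric
    Dirichlet). Gene lengths are log-normal around 1000 nonsynonymous
    sites, independent of rates.
    """

    n_genes: int = 500
    populations_per_treatment: int = 6
    treatments: list[str] = field(default_factory=lambda: ["default"])
    rate_concentration: float | None = 1.0  # symmetric Dirichlet; None = uniform rates
    mean_total: float = 50.0
    fixed_total: int | None = None  # overrides the Poisson total law when set
    enrichment: list[EnrichmentSpec] = field(default_factory=list)
    covariance: list[CovarianceSpec] = field(default_factory=list)
    length_sigma: float = 0.5  # log-normal spread of gene lengths
    mean_length: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.populations_per_treatment < 1:
            raise ValidationError("populations_per_treatment must be >= 1")
        if not self.treatments:
            raise ValidationError("at least one treatment label required")
        if len(set(self.treatments)) != len(self.treatments):
            raise ValidationError("treatment labels must be unique")
        if self.mean_total <= 0 and self.fixed_total is None:
            raise ValidationError("mean_total must be > 0")
        for e in self.enrichment:
            if not (0 <= e.gene_index < self.n_genes):
                raise ValidationError(f"enrichment gene index {e.gene_index} out of range")
            if e.treatment not in self.treatments:
                raise ValidationError(f"enrichment treatment {e.treatment!r} unknown")
        for c in self.covariance:
            for g in c.gene_indices:
                if not (0 <= g < self.n_genes):
                    raise ValidationError(f"covariance gene index {g} out of range")


@dataclass
class GroundTruth:
    """What the generator actually used — for recovery tests."""

    base_rates: np.ndarray
    treatment_rates: dict[str, np.ndarray]
    enriched: list[EnrichmentSpec]
    covarying: list[CovarianceSpec]
    drawn_totals: np.ndarray
    config: SimulationConfig


def _base_rates(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.rate_concentration is None:
        return np.full(config.n_genes, 1.0 / config.n_genes)
    r = rng.dirichlet(np.full(config.n_genes, config.rate_concentration))
    return r


def simulate_counts(config: SimulationConfig):
    """Draw (MutationCountMatrix, GeneAnnotation, GroundTruth).

    Column sums equal the drawn per-population totals exactly
    (multinomial conservation). Identical config => identical output.
    """
    rng = np.random.default_rng(config.seed)
    base = _base_rates(config, rng)

    treatment_rates: dict[str, np.ndarray] = {}
    for t in config.treatments:
        r = base.copy()
        for e in config.enrichment:
            if e.treatment == t:
                r[e.gene_index] *= e.fold
        treatment_rates[t] = r / r.sum()

    gene_ids = [f"gene_{i:04d}" for i in range(config.n_genes)]
    population_ids = []
    treatment_of = {}
    cols = []
    drawn_totals = []
    for t in config.treatments:
        for j in range(config.populations_per_treatment):
            pid = f"{t}_pop_{j:03d}"
            population_ids.append(pid)
            treatment_of[pid] = t
            rates = treatment_rates[t]
            if config.covariance:
                rates = rates.copy()
                for c in config.covariance:
                    if c.sigma > 0:
                        factor = rng.lognormal(mean=0.0, sigma=c.sigma)
                        rates[c.gene_indices] *= factor
                rates = rates / rates.sum()
            if config.fixed_total is not None:
                n_tot = int(config.fixed_total)
            else:
                n_tot = int(rng.poisson(config.mean_total))
            drawn_totals.append(n_tot)
            cols.append(rng.multinomial(n_tot, rates))

    counts = np.array(cols, dtype=np.int64).T  # genes x populations
    matrix = MutationCountMatrix(gene_ids, population_ids, counts, treatment_of)

    lengths = config.mean_length * rng.lognormal(
        mean=-0.5 * config.length_sigma**2, sigma=config.length_sigma, size=config.n_genes
    )
    annotation = GeneAnnotation(lengths=dict(zip(gene_ids, lengths)))

    truth = GroundTruth(
        base_rates=base,
        treatment_rates=treatment_rates,
        enriched=list(config.enrichment),
        covarying=list(config.covariance),
        drawn_totals=np.array(drawn_totals),
        config=config,
    )
    return matrix, annotation, truth


def simulate_null_pair(config: SimulationConfig) -> TreatmentPair:
    """Two treatments drawn from one identical rate vector (no divergence).

    Used to calibrate the false-discovery behaviour of the divergence
    test: any gene it flags on such a pair is a false discovery.
    """
    if config.enrichment:
        raise ValidationError("null pair must have no enrichment (null must be null)")
    cfg = config
    if len(cfg.treatments) != 2:
        cfg = replace(config, treatments=["t1", "t2"])
    matrix, _, _ = simulate_counts(cfg)
    from .io import collapse_by_treatment

    pairs = collapse_by_treatment(matrix)
    return next(iter(pairs.values()))
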