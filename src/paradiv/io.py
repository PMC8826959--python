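"""Core data containers and tabular IO.

Everything downstream operates on a gene-by-population matrix of
nonsynonymous mutation counts, an annotation table of per-gene
nonsynonymous site counts, and an optional population-to-treatment map.
All files are plain TSV (UTF-8, genes as rows, populations as columns);
lines starting with ``#`` are metadata comments and are skipped on read.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_TREATMENT = "default"


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class MutationCountMatrix:
    """Integer mutation counts per gene (rows) per population (columns).

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row of ``counts``.
    population_ids : list of str
        Unique population identifiers, one per column of ``counts``.
    counts : ndarray of shape (n_genes, n_populations)
        Nonnegative integer mutation counts.
    treatment_of : dict, optional
        Maps population id to its treatment label. Populations missing
        from the map get the label ``"default"``.
    """

    gene_ids: list[str]
    population_ids: list[str]
    counts: np.ndarray
    treatment_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if len(self.gene_ids) == 0:
            raise ValidationError("no genes: count matrix has zero rows")
        if len(self.population_ids) == 0:
            raise ValidationError("no populations: count matrix has zero columns")
        if self.counts.shape != (len(self.gene_ids), len(self.population_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.population_ids)} populations"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.population_ids)) != len(self.population_ids):
            raise ValidationError("duplicate population ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts)
            rounded = np.rint(as_int).astype(np.int64)
            if not np.array_equal(rounded, as_int):
                raise ValidationError("counts must be integral")
            self.counts = rounded
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[i]!r}, "
                f"population {self.population_ids[j]!r}"
            )
        self.treatment_of = {
            p: self.treatment_of.get(p, DEFAULT_TREATMENT) for p in self.population_ids
        }

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_populations(self) -> int:
        """M, the number of replicate populations."""
        return len(self.population_ids)

    @property
    def population_totals(self) -> np.ndarray:
        """n_tot,j — total mutations acquired by each population."""
        return self.counts.sum(axis=0)

    @property
    def gene_totals(self) -> np.ndarray:
        """Pooled per-gene mutation counts across all populations."""
        return self.counts.sum(axis=1)

    @property
    def treatments(self) -> list[str]:
        """Distinct treatment labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.population_ids:
            seen.setdefault(self.treatment_of[p], None)
        return list(seen)

    def subset_populations(self, population_ids: list[str]) -> "MutationCountMatrix":
        """Return a new matrix restricted to the given populations."""
        idx = [self.population_ids.index(p) for p in population_ids]
        return MutationCountMatrix(
            gene_ids=list(self.gene_ids),
            population_ids=list(population_ids),
            counts=self.counts[:, idx].copy(),
            treatment_of={p: self.treatment_of[p] for p in population_ids},
        )

    def restrict_to_treatment(self, label: str) -> "MutationCountMatrix":
        pops = [p for p in self.population_ids if self.treatment_of[p] == label]
        if not pops:
            raise ValidationError(f"no populations with treatment {label!r}")
        return self.subset_populations(pops)


@dataclass
class GeneAnnotation:
    """Per-gene nonsynonymous site counts L_i.

    ``mean_length`` is L̄, the mean over *all* annotated genes in the
    genome — the normalizer of the multiplicity correction.
    """

    lengths: dict[str, float]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValidationError("annotation is empty")
        for g, L in self.lengths.items():
            if not (L > 0):
                raise ValidationError(f"gene {g!r} has nonpositive length L_i={L}")

    @property
    def n_genes(self) -> int:
        return len(self.lengths)

    @property
    def mean_length(self) -> float:
        return float(np.mean(list(self.lengths.values())))

    def length_of(self, gene_id: str) -> float:
        try:
            return self.lengths[gene_id]
        except KeyError:
            raise KeyError(
                f"gene {gene_id!r} is present in the count matrix but missing "
                "from the annotation"
            ) from None


@dataclass
class TreatmentPair:
    """Per-gene counts summed within each of two treatments."""

    label_1: str
    label_2: str
    gene_ids: list[str]
    n_1: np.ndarray
    n_2: np.ndarray

    def __post_init__(self) -> None:
        self.n_1 = np.asarray(self.n_1, dtype=np.int64)
        self.n_2 = np.asarray(self.n_2, dtype=np.int64)
        if self.n_1.shape != self.n_2.shape or len(self.n_1) != len(self.gene_ids):
            raise ValidationError("per-treatment count vectors must match the gene list")
        if (self.n_1 < 0).any() or (self.n_2 < 0).any():
            raise ValidationError("negative per-treatment counts")

    @property
    def n_tot_1(self) -> int:
        return int(self.n_1.sum())

    @property
    def n_tot_2(self) -> int:
        return int(self.n_2.sum())

    @property
    def abs_delta(self) -> np.ndarray:
        """|Δn_i| — absolute difference in mutation counts per gene."""
        return np.abs(self.n_1 - self.n_2)


# ---------------------------------------------------------------------------
# readers / writers


def read_treatment_map(path) -> dict[str, str]:
    """Read a two-column TSV mapping population_id to treatment label."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("treatment map needs two columns (population_id, treatment)")
    pops, labels = df.iloc[:, 0], df.iloc[:, 1]
    if pops.duplicated().any():
        dup = pops[pops.duplicated()].iloc[0]
        raise ValidationError(f"duplicate population id {dup!r} in treatment map")
    return dict(zip(pops, labels))


def read_count_matrix(path, treatment_map_path=None) -> MutationCountMatrix:
    """Read a gene-by-population count matrix from TSV.

    The header row gives population ids; the first column (``gene_id``)
    gives gene ids. Cells must be nonnegative integers.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[0] == 0:
        raise ValidationError("no genes: count matrix has zero rows")
    if df.shape[1] < 2:
        raise ValidationError("no populations: count matrix has zero count columns")
    gene_ids = df.iloc[:, 0].tolist()
    population_ids = [str(c) for c in df.columns[1:]]
    cells = df.iloc[:, 1:]
    counts = np.empty((len(gene_ids), len(population_ids)), dtype=np.int64)
    for j, col in enumerate(cells.columns):
        for i, raw in enumerate(cells[col]):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"malformed count {raw!r} at gene {gene_ids[i]!r}, "
                    f"population {population_ids[j]!r}"
                ) from None
            if v < 0:
                raise ValidationError(
                    f"negative count {v} at gene {gene_ids[i]!r}, "
                    f"population {population_ids[j]!r}"
                )
            counts[i, j] = v
    treatment_of = read_treatment_map(treatment_map_path) if treatment_map_path else {}
    return MutationCountMatrix(gene_ids, population_ids, counts, treatment_of)


def write_count_matrix(matrix: MutationCountMatrix, path, header_comments=()) -> None:
    """Write a count matrix as TSV, preserving integer counts exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("gene_id\t" + "\t".join(matrix.population_ids) + "\n")
        for i, g in enumerate(matrix.gene_ids):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in matrix.counts[i]) + "\n")


def read_gene_annotation(path) -> GeneAnnotation:
    """Read a gene annotation TSV with columns gene_id, L_i[, description]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    cols = {c.lower(): c for c in df.columns}
    if "gene_id" not in cols or "l_i" not in cols:
        raise ValidationError("annotation must have columns gene_id and L_i")
    genes = df[cols["gene_id"]].astype(str)
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ValidationError(f"duplicate gene id {dup!r} in annotation")
    lengths = {}
    for g, L in zip(genes, df[cols["l_i"]]):
        L = float(L)
        if not (L > 0):
            raise ValidationError(f"gene {g!r} has nonpositive length L_i={L}")
        lengths[g] = L
    descriptions = {}
    if "description" in cols:
        descriptions = dict(zip(genes, df[cols["description"]].astype(str)))
    return GeneAnnotation(lengths=lengths, descriptions=descriptions)


def write_gene_annotation(annotation: GeneAnnotation, path, header_comments=()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("gene_id\tL_i\n")
        for g, L in annotation.lengths.items():
            fh.write(f"{g}\t{L:g}\n")


def collapse_by_treatment(matrix: MutationCountMatrix) -> dict[tuple[str, str], TreatmentPair]:
    """Sum counts within treatments and form one pair per unordered pair.

    Returns a dict keyed by (label_1, label_2) in treatment-appearance
    order; per-gene counts are sums over that treatment's populations.
    """
    labels = matrix.treatments
    if len(labels) < 2:
        raise ValidationError(
            "count matrix has a single treatment; between-treatment divergence "
            "needs >= 2 treatments (use the parallelism module for one-environment data)"
        )
    sums = {}
    for t in labels:
        cols = [j for j, p in enumerate(matrix.population_ids) if matrix.treatment_of[p] == t]
        sums[t] = matrix.counts[:, cols].sum(axis=1)
    pairs = {}
    for a, b in itertools.combinations(labels, 2):
        pairs[(a, b)] = TreatmentPair(
            label_1=a, label_2=b, gene_ids=list(matrix.gene_ids), n_1=sums[a], n_2=sums[b]
        )
    return pairs
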