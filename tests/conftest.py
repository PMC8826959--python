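import numpy as np
import pytest

from paradiv import GeneAnnotation, MutationCountMatrix


@pytest.fixture
def small_matrix():
    """2 genes x 3 populations, two treatments."""
    return MutationCountMatrix(
        gene_ids=["gA", "gB"],
        population_ids=["p1", "p2", "p3"],
        counts=np.array([[2, 0, 1], [0, 3, 0]]),
        treatment_of={"p1": "hot", "p2": "hot", "p3": "cold"},
    )


@pytest.fixture
def small_annotation():
    return GeneAnnotation(lengths={"gA": 100.0, "gB": 300.0})


@pytest.fixture
def counts_tsv(tmp_path):
    p = tmp_path / "counts.tsv"
    p.write_text("gene_id\tp1\tp2\ngA\t1\t0\ngB\t0\t2\n")
    return p


@pytest.fixture
def treatments_tsv(tmp_path):
    p = tmp_path / "treatments.tsv"
    p.write_text("population_id\ttreatment\np1\thot\np2\tcold\n")
    return p


@pytest.fixture
def annotation_tsv(tmp_path):
    p = tmp_path / "annotation.tsv"
    p.write_text("gene_id\tL_i\ngA\t100\ngB\t300\n")
    return p
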