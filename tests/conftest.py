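import numpy as np
import pytest

from dnmjoint import AnnotationDesign, CohortInfo, GeneTable, MixtureParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def toy_table(rng):
    """Ten genes, two traits, counts drawn once from a fixed seed."""
    m = 10
    mu = 10 ** rng.uniform(-6, -4.5, size=m)
    y1 = rng.poisson(2 * 5000 * mu * np.where(rng.random(m) < 0.3, 20.0, 1.0))
    y2 = rng.poisson(2 * 4000 * mu * np.where(rng.random(m) < 0.3, 15.0, 1.0))
    return GeneTable(
        gene_id=np.array([f"G{i}" for i in range(m)], dtype=object),
        mu=mu,
        y1=y1,
        y2=y2,
    )


@pytest.fixture
def toy_cohorts():
    return CohortInfo(n1=5000, n2=4000)


@pytest.fixture
def toy_designs(toy_table):
    m = toy_table.n_genes
    return [
        AnnotationDesign.intercept_only(m, 1),
        AnnotationDesign.intercept_only(m, 2),
    ]


@pytest.fixture
def toy_params():
    return MixtureParams(
        pi=np.array([0.9, 0.04, 0.04, 0.02]),
        beta1=np.array([3.0]),
        beta2=np.array([2.7]),
    )
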