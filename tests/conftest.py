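import numpy as np
import pandas as pd
import pytest

from elisl.data_io import GenePair, OmicsBundle
from elisl.pipeline import featurize_world
from elisl.synthetic import SyntheticWorldConfig, generate_world

SMALL_WORLD_CONFIG = SyntheticWorldConfig(
    n_genes=60,
    n_cell_lines=150,
    n_patients=200,
    n_normals=50,
    n_healthy=50,
    n_sl_pairs=20,
    n_nonsl_pairs=20,
    seed=7,
)


@pytest.fixture(scope="session")
def small_world():
    """A reduced synthetic world shared by the unit tests."""
    return generate_world(SMALL_WORLD_CONFIG)


@pytest.fixture(scope="session")
def small_blocks(small_world):
    """The five feature blocks for the small world's labelled pairs."""
    return featurize_world(small_world)


@pytest.fixture()
def toy_bundle():
    """Hand-built 4-sample x 3-gene cell-line bundle with known alterations."""
    samples = ["S1", "S2", "S3", "S4"]
    genes = ["A", "B", "C"]
    dependency = pd.DataFrame(
        [[-1.0, 0.5, 0.0], [-0.2, 0.1, 0.0], [-0.8, -0.4, 0.0], [0.0, 0.2, 0.0]],
        index=samples,
        columns=genes,
    )
    expr_z = pd.DataFrame(
        [[2.0, 0.0, 0.0], [1.96, 0.0, 0.0], [-2.5, 0.0, 0.0], [0.0, 0.0, 0.0]],
        index=samples,
        columns=genes,
    )
    mutations = pd.DataFrame(
        {
            "sample": ["S2", "S4", "S1"],
            "gene": ["B", "B", "C"],
            "variant_class": ["missense", "nonsense", "silent"],
        }
    )
    cna = pd.DataFrame(
        [[0, 2, 0], [0, 0, 0], [0, -2, 1], [0, 0, 0]], index=samples, columns=genes
    )
    return OmicsBundle(
        samples=samples,
        genes=genes,
        dependency=dependency,
        expr_z=expr_z,
        mutations=mutations,
        cna=cna,
        sample_context=pd.Series(
            ["BRCA", "BRCA", "LUAD", "BRCA"], index=samples
        ),
    )


def make_tissue_bundle(rng, n_samples=40, genes=("A", "B", "C", "D")):
    """Random small tissue bundle for unit tests (no planted structure)."""
    genes = list(genes)
    samples = [f"P{i}" for i in range(n_samples)]
    level = pd.DataFrame(
        rng.lognormal(3.0, 1.0, size=(n_samples, len(genes))), index=samples, columns=genes
    )
    expr_z = pd.DataFrame(
        rng.standard_normal((n_samples, len(genes))), index=samples, columns=genes
    )
    cna = pd.DataFrame(
        rng.choice([-2, -1, 0, 1, 2], size=(n_samples, len(genes)), p=[0.05, 0.1, 0.7, 0.1, 0.05]),
        index=samples,
        columns=genes,
    )
    mut_mask = rng.random((n_samples, len(genes))) < 0.2
    si, gi = np.nonzero(mut_mask)
    mutations = pd.DataFrame(
        {
            "sample": [samples[i] for i in si],
            "gene": [genes[i] for i in gi],
            "variant_class": "missense",
        }
    )
    clinical = pd.DataFrame(
        {
            "sample": samples,
            "time_months": rng.exponential(60.0, size=n_samples),
            "event": rng.integers(0, 2, size=n_samples),
            "age": rng.normal(60, 8, size=n_samples),
            "sex": rng.choice(["F", "M"], size=n_samples),
            "cancer": "BRCA",
        }
    )
    return OmicsBundle(
        samples=samples,
        genes=genes,
        expr_z=expr_z,
        expr_level=level,
        mutations=mutations,
        cna=cna,
        clinical=clinical,
        sample_context=pd.Series("BRCA", index=samples),
        expr_level_normal=pd.DataFrame(
            rng.lognormal(3.0, 1.0, size=(12, len(genes))),
            index=[f"N{i}" for i in range(12)],
            columns=genes,
        ),
        expr_level_healthy=pd.DataFrame(
            rng.lognormal(3.0, 1.0, size=(12, len(genes))),
            index=[f"H{i}" for i in range(12)],
            columns=genes,
        ),
    )


@pytest.fixture()
def tissue_bundle():
    return make_tissue_bundle(np.random.default_rng(11))
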