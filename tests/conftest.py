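import anndata as ad
import numpy as np
import pandas as pd
import pytest

from lrtme import synthetic
from lrtme.phenotyping import assign_phenotypes, gate_cells


@pytest.fixture(scope="session")
def zero_noise_spec():
    """Spatial spec with sigma=0 intensities and zero ring jitter."""
    model = {m: (3.0, 0.0, 0.0, 0.0) for m in synthetic.DEFAULT_INTENSITY_MODEL}
    return synthetic.default_spatial_spec(
        n_samples=3,
        seed=11,
        intensity_model=model,
        ring_jitter_um=0.0,
    )


@pytest.fixture(scope="session")
def zero_noise_cohort(zero_noise_spec):
    return synthetic.generate_spatial(zero_noise_spec)


@pytest.fixture(scope="session")
def gated_cohort():
    """Default-noise synthetic cohort, gated and phenotype-assigned."""
    cells, truth = synthetic.generate_spatial(
        synthetic.default_spatial_spec(n_samples=4, seed=5)
    )
    gated = gate_cells(cells)
    gated = assign_phenotypes(gated, synthetic.default_phenotype_defs())
    return gated, truth


@pytest.fixture(scope="session")
def small_adata():
    """Tiny expression dataset with two subtypes."""
    return synthetic.generate_expression(
        synthetic.default_expression_spec(
            n_samples_per_subtype=3, n_cells_per_sample=150, seed=7
        )
    )


def make_adata(X, clusters=None, samples=None, subtypes=None, genes=None):
    """Hand-built AnnData with the annotation columns the package expects."""
    X = np.asarray(X, float)
    n, g = X.shape
    obs = pd.DataFrame(
        {
            "sample_id": samples if samples is not None else ["s0"] * n,
            "subtype": subtypes if subtypes is not None else ["LR"] * n,
            "cluster": clusters if clusters is not None else ["c0"] * n,
        },
        index=[f"cell{i}" for i in range(n)],
    )
    var = pd.DataFrame(
        index=genes if genes is not None else [f"g{j}" for j in range(g)]
    )
    return ad.AnnData(X=X, obs=obs, var=var)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
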