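import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nicherx.io import ObsMatrix
from nicherx.simulate import SimConfig


def make_matrix(
    values,
    gene_ids=None,
    obs_ids=None,
    layer="raw_counts",
    log_base="e",
    sample_id="S0",
    tissue="spatial",
    sample_ids=None,
):
    """Build an ObsMatrix from a plain array with minimal metadata."""
    values = np.asarray(values)
    n_genes, n_obs = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    obs_ids = obs_ids or [f"o{i}" for i in range(n_obs)]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids if sample_ids is not None else sample_id,
            "tissue": tissue,
        },
        index=pd.Index(obs_ids, name="obs_id"),
    )
    extra = {"log_base": log_base, "target_sum": 1e4} if layer == "log_transformed" else {}
    return ObsMatrix(
        values=sp.csr_matrix(values) if layer == "raw_counts" else values.astype(float),
        gene_ids=list(gene_ids),
        obs_ids=list(obs_ids),
        obs_meta=meta,
        layer=layer,
        meta=extra,
    )


@pytest.fixture
def small_config():
    """Reduced-scale study conditions for fast recovery/property tests."""
    return SimConfig(
        n_samples_case=2,
        n_samples_control=2,
        spots_per_sample=200,
        n_genes=800,
        n_cells={"kidney": 800, "blood": 800},
        n_decoy_drugs=6,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
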