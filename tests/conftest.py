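import numpy as np
import pandas as pd
import pytest

from amyglia import bulk_de, synthetic


@pytest.fixture(scope="session")
def bulk_default():
    """One default two-strain bulk experiment with ground truth."""
    cfg = synthetic.BulkConfig(seed=11)
    exp, truth = synthetic.generate_bulk_counts(cfg)
    return cfg, exp, truth


@pytest.fixture(scope="session")
def app_norm(bulk_default):
    """Filtered, normalized, residualized amyloid-strain matrix + samples."""
    _, exp, _ = bulk_default
    sub = exp.subset_strain("APP")
    filt = bulk_de.filter_low_counts(sub, min_mean=5.0, min_samples=5)
    norm = bulk_de.normalize_log_cpm(filt)
    norm = bulk_de.residualize_covariates(
        norm, filt.samples[["batch", "concentration"]], filt.samples
    )
    return norm, filt.samples


@pytest.fixture(scope="session")
def sc_default():
    cfg = synthetic.SingleCellConfig(seed=11)
    adata, truth = synthetic.generate_single_cell_counts(cfg)
    return cfg, adata, truth


def make_normalized(values: np.ndarray, genes=None, samples=None):
    """Wrap a raw value array as a NormalizedMatrix for unit fixtures."""
    from amyglia.containers import NormalizedMatrix

    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    return NormalizedMatrix(
        values=df, library_sizes=pd.Series(1.0, index=df.columns)
    )
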