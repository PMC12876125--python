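import numpy as np
import pandas as pd
import pytest

from crosstalk.containers import ExpressionMatrix
from crosstalk.synthetic import SyntheticConfig, generate_two_tissue_study


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A reduced-universe study that keeps every stratum populated."""
    return SyntheticConfig(
        n_genes=300,
        n_ligands=40,
        n_receptors=40,
        n_pairs=80,
        frac_de_ligands=0.2,
        frac_de_receptors=0.2,
        frac_de_background=0.1,
        effect_log2=2.0,
        sigma=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_two_tissue_study(small_config)


def make_matrix(values, tissue="BL", groups=None, genes=None, samples=None) -> ExpressionMatrix:
    """Hand-built ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"G{i}" for i in range(n_genes)]
    samples = samples or [f"S{i}" for i in range(n_samples)]
    groups = groups or ["HC"] * (n_samples // 2) + ["OA"] * (n_samples - n_samples // 2)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        sample_group=pd.Series(groups, index=samples, name="group"),
        tissue=tissue,
    )
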