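import numpy as np
import pandas as pd
import pytest

from pnstrat import CountMatrix, ExpressionMatrix, SimConfig, simulate_cohort


def make_expr(values, scale="linear", genes=None, samples=None, purity=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    if scale == "counts":
        return CountMatrix(df.astype(int))
    kwargs = {}
    if scale == "residual":
        kwargs["purity_used"] = purity
    return ExpressionMatrix(df, scale=scale, **kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with planted structure shared across tests."""
    cfg = SimConfig(
        n_samples_per_group=40,
        n_genes=600,
        pn_set_size=150,
        n_de_in_pn=50,
        n_de_outside_pn=50,
        de_fold_change=1.6,
        nb_dispersion=0.2,
        stroma_shift=1.0,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def two_groups():
    samples = [f"s{j}" for j in range(10)]
    return pd.Series(["A"] * 5 + ["B"] * 5, index=samples)
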