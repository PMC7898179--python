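import numpy as np
import pandas as pd
import pytest

from dmvstates import preprocessing, simulate


@pytest.fixture(scope="session")
def synth():
    """Default synthetic study (180 samples x 170 genes) with truth labels."""
    spec = simulate.SynthSpec(seed=11)
    ct, truth = simulate.generate_qpcr(spec)
    return spec, ct, truth


@pytest.fixture(scope="session")
def expr(synth):
    _, ct, _ = synth
    return preprocessing.to_expression(ct)


def make_expr(values: np.ndarray, genes=None, samples=None, lod_ct=28.0,
              meta=None) -> preprocessing.ExprMatrix:
    """Small helper: wrap a plain array of LOD-relative values (0 = censored)."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    return preprocessing.ExprMatrix(
        values=df, detected=df > 0, lod_ct=lod_ct, sample_meta=meta
    )
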