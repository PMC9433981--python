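import numpy as np
import pandas as pd
import pytest

from seedcoex import (ExpressionMatrix, SampleMeta, SimulationParams,
                      generate_experiment)


def make_matrix(values, metas, log2=False):
    df = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(np.shape(values)[0])],
        columns=[m.sample_id for m in metas],
    )
    return ExpressionMatrix(df, metas, log2=log2)


def design(varieties=(("SD1", "SD"), ("SL1", "SL")), stages=("S1", "S2", "S3", "S4"),
           replicates=3):
    metas = []
    for vname, vclass in varieties:
        for stage in stages:
            for rep in range(1, replicates + 1):
                metas.append(
                    SampleMeta(f"{vname}_{stage}_r{rep}", vname, vclass,
                               stage, rep)
                )
    return metas


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(
        n_genes=300, n_targets=15, n_deg_extra=30,
        n_aux_datasets=2, aux_n_samples=24, promoter_length=400, seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_params):
    return generate_experiment(small_params)
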