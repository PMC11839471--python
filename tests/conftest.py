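import numpy as np
import pandas as pd
import pytest

from oncopath import PipelineParams, SimConfig, generate_study, run_study
from oncopath.containers import ExpressionMatrix

#: Fixed seed for the reference synthetic study used across the suite.
STUDY_SEED = 7


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study: 4 cancer types x 15 cell lines, 2000
    transcripts, 50 planted markers/type at +2 log2 over sd 0.5."""
    return generate_study(SimConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def study_result(bundle):
    """Full pipeline run on the reference bundle."""
    return run_study(
        bundle.transcript_matrix,
        bundle.protein_matrix,
        bundle.labels,
        bundle.pathways,
        bundle.drug_targets,
        bundle.approved_pairs,
        bundle.mnauc,
        PipelineParams(seed=STUDY_SEED),
    )


def make_matrix(values, scale="log2", symbols=None, biotypes=None, prefix="f"):
    """Small ExpressionMatrix helper for hand-built examples."""
    values = np.asarray(values, dtype=float)
    idx = pd.Index([f"{prefix}{i}" for i in range(values.shape[0])], name="feature_id")
    cols = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=idx, columns=cols),
        scale=scale,
        gene_symbols=None if symbols is None else pd.Series(symbols, index=idx),
        biotypes=None if biotypes is None else pd.Series(biotypes, index=idx),
    )
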