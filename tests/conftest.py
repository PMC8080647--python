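import numpy as np
import pandas as pd
import pytest

from senquad import ExpressionCohort, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def two_study_cohort():
    """Tiny deterministic cohort: 2 studies × (2+2) samples, 6 genes."""
    rng = np.random.default_rng(42)
    genes = ["THOC1", "THOC2", "NXF1", "CDKN1A", "BG1", "BG2"]
    samples = [f"s{i}" for i in range(8)]
    values = pd.DataFrame(
        rng.normal(8, 1, size=(len(genes), len(samples))),
        index=genes, columns=samples,
    )
    metadata = pd.DataFrame(
        {
            "study_id": ["A"] * 4 + ["B"] * 4,
            "group": ["senescent", "senescent", "nonsenescent", "nonsenescent"] * 2,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionCohort(values, metadata)
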