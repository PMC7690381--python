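import numpy as np
import pandas as pd
import pytest

from mirnorm import CtMatrix, SampleTable, default_screening_spec, generate_cohort


def make_ct(values, assay_ids=None, sample_ids=None, detected=None) -> CtMatrix:
    values = np.asarray(values, dtype=float)
    n_a, n_s = values.shape
    if assay_ids is None:
        assay_ids = [f"g{i}" for i in range(n_a)]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(n_s)]
    if detected is None:
        detected = np.isfinite(values)
    return CtMatrix(assay_ids, sample_ids, values, detected)


def make_samples(groups, cohort="screening", plates=None) -> SampleTable:
    """groups: list of (sample_id, group) or dict group -> count."""
    if isinstance(groups, dict):
        rows = []
        for g, n in groups.items():
            rows += [(f"{g}_{i}", g) for i in range(n)]
        groups = rows
    df = pd.DataFrame(groups, columns=["sample_id", "group"])
    df["cohort"] = cohort
    if plates is not None:
        df["plate_id"] = plates
    return SampleTable(df)


@pytest.fixture(scope="session")
def screening_cohort():
    """One deterministic draw of the default screening-stage cohort."""
    return generate_cohort(default_screening_spec(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
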