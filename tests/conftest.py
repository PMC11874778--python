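import numpy as np
import pandas as pd
import pytest

from lupine.io import CountMatrix, TimeSeriesStudy


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_counts(rng):
    """12 samples x 6 taxa Poisson counts with no planted structure."""
    counts = rng.poisson(30, size=(12, 6)).astype(float)
    counts[counts.sum(axis=0) == 0] = 1
    return CountMatrix(
        values=counts,
        sample_ids=[f"s{i}" for i in range(12)],
        taxon_ids=[f"t{j}" for j in range(6)],
    )


@pytest.fixture
def three_time_study(rng):
    """10 subjects x 8 taxa x 3 time points, unstructured counts."""
    tables = []
    subjects = [f"m{i}" for i in range(10)]
    for t in range(3):
        counts = rng.poisson(25, size=(10, 8)).astype(float) + 1
        tables.append(
            CountMatrix(
                values=counts,
                sample_ids=[f"{s}_t{t}" for s in subjects],
                taxon_ids=[f"t{j}" for j in range(8)],
            )
        )
    return TimeSeriesStudy(
        tables=tables,
        time_labels=["0", "1", "2"],
        group_label="g",
        subject_ids=subjects,
    )


@pytest.fixture
def metadata_frame():
    """Complete 2-group, 3-time, 5-subject metadata."""
    rows = []
    for g in ("a", "b"):
        for s in range(5):
            for t in range(3):
                rows.append(
                    {
                        "sample_id": f"{g}{s}_t{t}",
                        "subject_id": f"{g}{s}",
                        "time": str(t),
                        "group": g,
                    }
                )
    return pd.DataFrame(rows)
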