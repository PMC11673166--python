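import numpy as np
import pytest

import statsynth as ss


@pytest.fixture(scope="session")
def tiny_schema() -> ss.TableSchema:
    """Three-column schema (two features + outcome) for fast tests."""
    c = ss.ColumnSpec
    return ss.TableSchema((
        c("A", "continuous", 0, 100, 60, "above"),
        c("B", "count", 0, 20, 10, "above"),
        c("Y", "binary", 0, 1, is_outcome=True),
    ), n_rows_default=50)


@pytest.fixture(scope="session")
def tiny_table(tiny_schema) -> ss.Table:
    rng = np.random.default_rng(0)
    n = 50
    vals = np.column_stack([
        rng.uniform(0, 100, n),
        np.round(rng.uniform(0, 20, n)),
        (rng.uniform(size=n) < 0.3).astype(float),
    ])
    vals[0, 2] = 1.0
    vals[1, 2] = 0.0
    return ss.Table(vals, tiny_schema)


@pytest.fixture(scope="session")
def tiny_stats(tiny_table) -> ss.StatisticsVector:
    return ss.extract_statistics(tiny_table)


@pytest.fixture(scope="session")
def reference_table() -> ss.Table:
    return ss.make_reference_table(seed=1)
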