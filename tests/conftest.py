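import numpy as np
import pandas as pd
import pytest

from stressnet.io import ExpressionSeries


@pytest.fixture
def small_series() -> ExpressionSeries:
    """A tiny deterministic 6-gene, 4-time × 2-replicate series."""
    rng = np.random.default_rng(42)
    times = np.repeat([0.0, 2.0, 4.0, 24.0], 2)
    reps = np.tile([1, 2], 4)
    genes = [f"g{i}" for i in range(6)]
    values = pd.DataFrame(
        rng.normal(7.0, 1.0, size=(6, 8)),
        index=genes,
        columns=[f"t{int(t)}_rep{r}" for t, r in zip(times, reps)],
    )
    return ExpressionSeries(values, times, reps)


@pytest.fixture
def toy_two_point_series() -> ExpressionSeries:
    """One gene, two times, two replicates: (1.0, 1.2) then (2.0, 2.2)."""
    values = pd.DataFrame(
        [[1.0, 1.2, 2.0, 2.2]],
        index=["g0"],
        columns=["t0_rep1", "t0_rep2", "t2_rep1", "t2_rep2"],
    )
    return ExpressionSeries(values, np.array([0.0, 0.0, 2.0, 2.0]), np.array([1, 2, 1, 2]))
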