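import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sialoquant.quant import IntensityMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_matrix(values, runs, conditions, channels=None, index=None):
    """Build a small IntensityMatrix by hand for unit tests."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    channels = channels or [str(100 + i) for i in range(n)]
    samples = [f"{runs[j]}:{channels[j]}" for j in range(n)]
    design = pd.DataFrame(
        {"run": runs, "condition": conditions, "channel": channels}, index=samples
    )
    index = index if index is not None else [f"f{i}" for i in range(values.shape[0])]
    return IntensityMatrix(pd.DataFrame(values, index=index, columns=samples), design)


@pytest.fixture
def two_group_matrix():
    """3 runs x 4 channels, 2 mock + 2 ST3GAL4 per run."""

    def build(values, index=None):
        runs = sum([[f"run{r}"] * 4 for r in (1, 2, 3)], [])
        conditions = ["mock", "mock", "ST3GAL4", "ST3GAL4"] * 3
        channels = ["114", "115", "116", "117"] * 3
        return make_matrix(values, runs, conditions, channels, index)

    return build
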