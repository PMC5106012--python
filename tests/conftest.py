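import numpy as np
import pytest

from upmclock import MethylationDataset


@pytest.fixture
def toy_dataset() -> MethylationDataset:
    """3 sites x 4 individuals, exact linear trends (no noise)."""
    ages = np.array([20.0, 40.0, 60.0, 80.0])
    rates = np.array([0.02, -0.01, 0.005])
    starts = np.array([0.1, 0.9, 0.5])
    values = starts[:, None] + np.outer(rates, ages)
    return MethylationDataset(
        site_ids=["s1", "s2", "s3"],
        individual_ids=["a", "b", "c", "d"],
        values=values,
        ages=ages,
    )
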