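import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from akw_mrpk import LabeledDataset, SyntheticConfig, generate_synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_dataset() -> LabeledDataset:
    """Six patients, three attributes, 4:2 class split."""
    return LabeledDataset(
        attribute_names=("glucose", "bmi", "pregnancies"),
        attribute_kinds=("continuous", "continuous", "discrete"),
        values=np.array(
            [
                [120.0, 30.0, 1.0],
                [90.0, 24.0, 0.0],
                [150.0, 35.0, 3.0],
                [100.0, 26.0, 2.0],
                [160.0, 38.0, 5.0],
                [95.0, 22.0, 1.0],
            ]
        ),
        labels=np.array([1, 0, 1, 0, 1, 0]),
    )


@pytest.fixture
def pima_like() -> LabeledDataset:
    """Medium synthetic PIMA-shaped dataset with a clear two-attribute signal."""
    return generate_synthetic(
        SyntheticConfig(n_samples=300, effect_size=2.0, seed=11)
    )
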