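import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from maaspenn import GeneratorConfig, default_kernel_schema, simulate_dataset
from maaspenn.features import FeatureTable
from maaspenn.metadata import ScanMetadata

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_scan(scan_id="s1", **overrides) -> ScanMetadata:
    """A fully specified scan; override any parameter per test."""
    base = dict(
        vendor="GE",
        model="LightSpeed16",
        tube_current=200.0,
        exposure=160.0,
        exposure_time=750.0,
        slice_thickness=2.5,
        pixel_spacing=0.68,
        kernel="STANDARD",
    )
    base.update(overrides)
    return ScanMetadata(scan_id=scan_id, **base)


def make_table(scan_id, values, arm="original", feature_names=None) -> FeatureTable:
    values = np.asarray(values, dtype=float)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(values.shape[1])]
    frame = pd.DataFrame(
        values,
        index=[f"voi{v:03d}" for v in range(values.shape[0])],
        columns=feature_names,
    )
    return FeatureTable(scan_id=scan_id, arm=arm, frame=frame)


@pytest.fixture(scope="session")
def schema():
    return default_kernel_schema()


@pytest.fixture(scope="session")
def small_dataset():
    """A 12-scan synthetic cohort shared by read-only tests."""
    return simulate_dataset(GeneratorConfig(n_scans=12, seed=11))
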