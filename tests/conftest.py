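import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from pdmotion import (
    AccelerometerRecording,
    TestMetadata,
    TestType,
)

GRAVITY = 9.80665


def make_recording(
    z_signal: np.ndarray,
    fs: float = 100.0,
    test_type: TestType = TestType.HAND_TREMOR,
    angular: np.ndarray | None = None,
    user_id: str = "test",
) -> AccelerometerRecording:
    """Recording whose vertical axis carries gravity plus the given signal."""
    n = z_signal.size
    trans = np.zeros((n, 3))
    trans[:, 2] = GRAVITY + z_signal
    return AccelerometerRecording(
        metadata=TestMetadata(
            sampling_rate=fs,
            duration=n / fs,
            date="2015-01-01T00:00:00",
            test_type=test_type,
            user_id=user_id,
        ),
        trans_acc=trans,
        angular_rate=angular,
    )


@pytest.fixture(scope="session")
def pipeline_report():
    """One full pipeline run on the default 40-subject cohort, shared."""
    from pdmotion import PipelineConfig, run_pipeline

    return run_pipeline(PipelineConfig(seed=42))
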