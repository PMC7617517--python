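import numpy as np
import pandas as pd
import pytest

from luxtrace import LightSeries


def make_series(
    values,
    epoch: float = 60.0,
    start: str = "2024-01-01 00:00",
    tz: str = "UTC",
    channel: str = "LIGHT",
    sid: str = "test",
) -> LightSeries:
    idx = pd.date_range(
        pd.Timestamp(start, tz=tz), periods=len(values), freq=pd.Timedelta(seconds=epoch)
    )
    frame = pd.DataFrame({channel: np.asarray(values, dtype=float)}, index=idx)
    return LightSeries(sid, frame, epoch=epoch)


@pytest.fixture
def series_factory():
    return make_series
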