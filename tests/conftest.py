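"""Shared fixtures: synthetic recordings and MF series built at test time."""

import numpy as np
import pytest

from emgfatigue import (
    CHANNEL_ORDER,
    EMGGenSpec,
    EpochSpec,
    MFSeries,
    bandpass_filter,
    detect_artifacts,
    generate_emg,
    mf_series,
)


@pytest.fixture(scope="session")
def six_channel_recording():
    """A 30 s six-channel fatiguing recording (IMF 100 Hz, −0.3 Hz/s)."""
    return generate_emg(EMGGenSpec(seed=11))


@pytest.fixture(scope="session")
def six_channel_series(six_channel_recording):
    filt = bandpass_filter(six_channel_recording)
    return mf_series(filt, mask=detect_artifacts(filt))


@pytest.fixture(scope="session")
def single_channel_series():
    rec = generate_emg(EMGGenSpec(imf0=95.0, slope=-0.25, seed=3, channels=("L5_left",)))
    filt = bandpass_filter(rec)
    return mf_series(filt, mask=detect_artifacts(filt))


def make_series(values_by_channel, t_start=3.0, step=0.5, n=54, band=(20.0, 450.0)):
    """Construct an MFSeries directly from per-channel value arrays/callables."""
    spec = EpochSpec(epoch_length=step, overlap=0.0, t_start=t_start,
                     t_end=t_start + step * n)
    times = t_start + step / 2.0 + step * np.arange(n)
    values, excluded = {}, {}
    for ch, v in values_by_channel.items():
        arr = v(times) if callable(v) else np.broadcast_to(np.asarray(v, float), times.shape).copy()
        values[ch] = np.asarray(arr, dtype=float)
        excluded[ch] = ~np.isfinite(values[ch])
    return MFSeries(times=times, values=values, excluded=excluded, band=band, spec=spec)


@pytest.fixture
def line_series():
    """Noiseless series mf(t) = 100 − 0.3 (t − 3) on all six channels."""
    f = lambda t: 100.0 - 0.3 * (t - 3.0)
    return make_series({ch: f for ch in CHANNEL_ORDER})
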