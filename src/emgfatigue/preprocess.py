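"""Band-pass filtering and artefact screening ahead of spectral analysis.

The analysis band-pass is a 4th-order Butterworth applied forward and
backward (zero-phase), so epoch timing is preserved and the effective
roll-off is 8th order. Artefact screening is amplitude/saturation based:
samples beyond an absolute amplitude limit are masked, as are plateaus of
identical samples near the channel's own extreme (AD-converter clipping).
Masked samples never enter a spectrum; epochs containing too many masked
samples are excluded from the MF series instead of being repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .exceptions import ParameterError
from .io import EMGRecording


def bandpass_filter(
    rec: EMGRecording,
    low: float = 20.0,
    high: float = 500.0,
    order: int = 4,
    notch_50hz: bool = False,
) -> EMGRecording:
    """Zero-phase Butterworth band-pass of every channel.

    Parameters are the band edges in Hz; ``high`` must stay below the
    Nyquist frequency. An optional 50 Hz notch is available for mains
    interference but is off by default.
    """
    nyq = rec.sampling_rate / 2.0
    if not 0 < low < high:
        raise ParameterError(f"band edges must satisfy 0 < low < high (got {low}, {high})")
    if high >= nyq:
        raise ParameterError(f"high edge {high} Hz must be below Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.sampling_rate, output="sos")
    out: dict[str, np.ndarray] = {}
    for name, x in rec.samples.items():
        y = signal.sosfiltfilt(sos, x)
        if notch_50hz:
            b, a = signal.iirnotch(50.0, Q=30.0, fs=rec.sampling_rate)
            y = signal.filtfilt(b, a, y)
        out[name] = y
    return rec.copy_with(
        out,
        filter={"type": "butterworth", "order": order, "low_hz": low, "high_hz": high,
                "zero_phase": True, "notch_50hz": notch_50hz},
    )


@dataclass
class ArtifactMask:
    """Per-channel boolean masks (True = artefactual sample)."""

    masks: dict[str, np.ndarray]
    amplitude_limit: float
    clip_fraction: float
    min_run: int

    @property
    def n_masked(self) -> dict[str, int]:
        return {k: int(v.sum()) for k, v in self.masks.items()}

    def fraction_masked(self, channel: str) -> float:
        m = self.masks[channel]
        return float(m.mean()) if len(m) else 0.0

    def summary(self) -> dict:
        return {
            "amplitude_limit_uv": self.amplitude_limit,
            "clip_fraction": self.clip_fraction,
            "min_run": self.min_run,
            "n_masked": self.n_masked,
        }


def _clipping_runs(x: np.ndarray, threshold: float, min_run: int) -> np.ndarray:
    """Mask runs of >= min_run identical samples with |value| >= threshold."""
    mask = np.zeros(len(x), dtype=bool)
    if len(x) < min_run or threshold <= 0:
        return mask
    same = np.concatenate([[False], np.diff(x) == 0])
    # run ids increment whenever the value changes
    run_id = np.cumsum(~same)
    extreme = np.abs(x) >= threshold
    counts = np.bincount(run_id[extreme], minlength=run_id[-1] + 1)
    bad_runs = np.flatnonzero(counts >= min_run)
    if len(bad_runs):
        mask = np.isin(run_id, bad_runs) & extreme
    return mask


def detect_artifacts(
    rec: EMGRecording,
    amplitude_limit: float = 3000.0,
    clip_fraction: float = 0.95,
    min_run: int = 5,
) -> ArtifactMask:
    """Screen each channel for amplitude and clipping artefacts.

    A sample is masked when |amplitude| exceeds ``amplitude_limit`` (µV),
    or when it sits in a run of at least ``min_run`` identical values at
    ``clip_fraction`` of the channel's own maximum absolute amplitude or
    above (saturated AD converter). Deterministic; invariant to a sign
    flip of the signal.
    """
    if amplitude_limit <= 0 or not 0 < clip_fraction <= 1 or min_run < 2:
        raise ParameterError("artifact thresholds must be positive (clip_fraction in (0, 1])")
    masks: dict[str, np.ndarray] = {}
    for name, x in rec.samples.items():
        mask = np.abs(x) > amplitude_limit
        peak = float(np.max(np.abs(x))) if len(x) else 0.0
        if peak > 0:
            mask |= _clipping_runs(x, clip_fraction * peak, min_run)
        masks[name] = mask
    return ArtifactMask(masks, amplitude_limit, clip_fraction, min_run)
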