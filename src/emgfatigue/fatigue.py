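"""Linear fatigue regression on MF series and the study outcome set.

Per channel, an ordinary least-squares line MF(t) = a + b·t is fitted
over the non-excluded epochs of the analysis window. The fatigue
descriptors are:

* IMF (initial median frequency, Hz) — the fitted line evaluated at the
  analysis-window onset (3 s by default), i.e. the regression onset;
* slope (Hz/s) — the rate of MF decline b;
* normalized slope (%/s) — 100 · b / IMF, the decline per second as a
  percentage of the initial MF.

Channel fits aggregate into per-level bilateral means (L1, L2, L5), the
all-electrode mean, and the "most-negative electrode" (the channel with
the steepest decline, re-selected per recording).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AnalysisError, FitError, NormalizationError, ValidationError
from .io import CHANNEL_ORDER, LEVELS, ChannelLabel
from .spectral import MFSeries

#: Outcome keys used in long-format tables.
OUTCOMES = ("imf", "slope_hzs", "slope_norm")

#: Scope keys: per-level bilateral means plus the two derived scores.
SCOPES = ("L1", "L2", "L5", "all", "most_negative")

MIN_FIT_POINTS = 10


@dataclass(frozen=True)
class ChannelFatigue:
    """OLS fatigue descriptors for one electrode channel."""

    channel: str
    imf: float
    slope: float
    slope_norm: float
    intercept_t0: float
    r_squared: float
    n_points: int

    def outcome(self, name: str) -> float:
        return {"imf": self.imf, "slope_hzs": self.slope, "slope_norm": self.slope_norm}[name]


def fit_channel(
    series: MFSeries,
    channel: str,
    min_points: int = MIN_FIT_POINTS,
    imf_at_zero: bool = False,
) -> ChannelFatigue:
    """Fit the fatigue line of one channel of an MF series.

    The IMF is the fitted value at the analysis-window onset
    (``series.spec.t_start``); set ``imf_at_zero`` to extrapolate to
    t = 0 instead. Raises :class:`FitError` below ``min_points`` usable
    epochs or when the channel was flagged unusable, and
    :class:`NormalizationError` when the fitted IMF is non-positive.
    """
    if channel in series.unusable:
        raise FitError(f"channel {channel} flagged unusable (too many excluded epochs)")
    t, y = series.channel_points(channel)
    if len(t) < min_points:
        raise FitError(f"channel {channel}: {len(t)} usable epochs < minimum {min_points}")
    res = stats.linregress(t, y)
    t_ref = 0.0 if imf_at_zero else series.spec.t_start
    imf = res.intercept + res.slope * t_ref
    if imf <= 0:
        raise NormalizationError(f"channel {channel}: fitted IMF {imf:.3f} Hz is non-positive")
    return ChannelFatigue(
        channel=channel,
        imf=float(imf),
        slope=float(res.slope),
        slope_norm=float(100.0 * res.slope / imf),
        intercept_t0=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(t),
    )


@dataclass
class FatigueResult:
    """Fatigue descriptors of one recording: 6 channels + aggregates."""

    channels: dict[str, ChannelFatigue]
    per_level: dict[str, dict[str, float]]
    overall: dict[str, float]
    most_negative: ChannelFatigue
    metadata: dict = field(default_factory=dict)

    def value(self, outcome: str, scope: str) -> float:
        if scope in LEVELS:
            return self.per_level[scope][outcome]
        if scope == "all":
            return self.overall[outcome]
        if scope == "most_negative":
            return self.most_negative.outcome(outcome)
        raise KeyError(scope)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (scope/channel, outcome)."""
        subject = self.metadata.get("subject")
        day = self.metadata.get("day")
        rows = []
        for name in CHANNEL_ORDER:
            cf = self.channels[name]
            lab = ChannelLabel.parse(name)
            for out in OUTCOMES:
                rows.append(
                    {"subject": subject, "day": day, "side": lab.side, "scope": lab.level,
                     "outcome": out, "value": cf.outcome(out)}
                )
        for level in LEVELS:
            for out in OUTCOMES:
                rows.append({"subject": subject, "day": day, "side": "both", "scope": level,
                             "outcome": out, "value": self.per_level[level][out]})
        for out in OUTCOMES:
            rows.append({"subject": subject, "day": day, "side": "both", "scope": "all",
                         "outcome": out, "value": self.overall[out]})
            rows.append({"subject": subject, "day": day, "side": "both", "scope": "most_negative",
                         "outcome": out, "value": self.most_negative.outcome(out)})
        return pd.DataFrame(rows)


def aggregate(channels: "dict[str, ChannelFatigue] | list[ChannelFatigue]",
              metadata: "dict | None" = None) -> FatigueResult:
    """Combine six channel fits into the recording-level outcome set.

    Per-level values are the arithmetic mean of the left and right fits;
    the all-electrode value is the mean over the six channels; the
    most-negative electrode is the channel with the minimum slope in
    Hz/s, ties broken toward the later channel in the fixed order
    L1_left … L5_right (caudal/right wins).
    """
    if isinstance(channels, list):
        channels = {cf.channel: cf for cf in channels}
    missing = [name for name in CHANNEL_ORDER if name not in channels]
    if missing:
        raise AnalysisError(f"aggregate requires all six channels; missing {missing}")
    per_level: dict[str, dict[str, float]] = {}
    for level in LEVELS:
        pair = [channels[f"{level}_left"], channels[f"{level}_right"]]
        per_level[level] = {out: float(np.mean([c.outcome(out) for c in pair])) for out in OUTCOMES}
    overall = {
        out: float(np.mean([channels[name].outcome(out) for name in CHANNEL_ORDER]))
        for out in OUTCOMES
    }
    most_neg = None
    for name in CHANNEL_ORDER:  # later channels win ties
        cf = channels[name]
        if most_neg is None or cf.slope <= most_neg.slope:
            most_neg = cf
    return FatigueResult(
        channels=dict(channels),
        per_level=per_level,
        overall=overall,
        most_negative=most_neg,
        metadata=dict(metadata or {}),
    )


def fit_recording(series: MFSeries, metadata: "dict | None" = None,
                  min_points: int = MIN_FIT_POINTS) -> FatigueResult:
    """Fit all six channels of an MF series and aggregate them."""
    fits = {ch: fit_channel(series, ch, min_points=min_points) for ch in series.channels}
    md = dict(series.metadata)
    md.update(metadata or {})
    return aggregate(fits, metadata=md)


def batch_fatigue(results: "list[FatigueResult]") -> pd.DataFrame:
    """Stack per-recording results into one long table.

    Rows are keyed (subject, day, side, scope, outcome); duplicate
    (subject, day) pairs are an input error. An empty input yields an
    empty table with the standard columns.
    """
    cols = ["subject", "day", "side", "scope", "outcome", "value"]
    if not results:
        return pd.DataFrame(columns=cols)
    keys = [(r.metadata.get("subject"), r.metadata.get("day")) for r in results]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicate (subject, day) recordings: {dupes}")
    return pd.concat([r.to_frame() for r in results], ignore_index=True)[cols]
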