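"""Bilateral MF imbalance: segmental ratios and global scores.

For each lumbar level the epoch-by-epoch ratio r = MF_right / MF_left is
mapped through an antisymmetric transform R with R(1) = 0 and
R(r) = −R(1/r), so that equal-sized right- and left-dominant imbalances
get equal-magnitude, opposite-sign scores. The default transform is the
piecewise reciprocal

    R(r) = r − 1        for r ≥ 1
    R(r) = 1 − 1/r      for r < 1

which reads directly as a fractional difference of the dominant side
(r = 1.10 → +0.10); a log-ratio alternative R(r) = ln r is selectable.
The segmental score of a level is 100 × the mean transformed ratio over
the retained epochs (a signed percent, right > left positive). The
"uncompensated" global score is the mean across the three levels of the
absolute segmental values (total imbalance regardless of direction); the
"compensated" score is the plain mean (direction-aware, cancellation
allowed), so uncompensated ≥ |compensated| always.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AnalysisError, ParameterError
from .io import LEVELS
from .spectral import MFSeries

TRANSFORMS = ("reciprocal", "log")

MIN_PAIRED_EPOCHS = 10


def ratio_series(mf_right: np.ndarray, mf_left: np.ndarray) -> np.ndarray:
    """Epoch-by-epoch right/left MF ratio, pairwise-dropping NaN epochs."""
    r = np.asarray(mf_right, dtype=float)
    l = np.asarray(mf_left, dtype=float)
    if r.shape != l.shape:
        raise AnalysisError(f"ratio series need equal lengths (got {r.shape} vs {l.shape})")
    keep = np.isfinite(r) & np.isfinite(l)
    r, l = r[keep], l[keep]
    if np.any(r <= 0) or np.any(l <= 0):
        raise AnalysisError("MF values must be positive to form ratios")
    return r / l


def symmetric_transform(r, transform: str = "reciprocal"):
    """Antisymmetric recentering of a ratio: R(1)=0, R(r) = −R(1/r)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise AnalysisError("ratio must be positive")
    if transform == "reciprocal":
        out = np.where(r >= 1.0, r - 1.0, 1.0 - 1.0 / r)
    elif transform == "log":
        out = np.log(r)
    else:
        raise ParameterError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")
    return out if out.ndim else float(out)


@dataclass
class ImbalanceResult:
    """Per-level and global MF imbalance scores of one recording."""

    segmental: dict[str, float]          # level -> signed percent
    uncompensated: float                 # percent, >= 0
    compensated: float                   # percent, signed
    n_ratio_samples: dict[str, int]
    transform: str
    metadata: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        md = self.metadata or {}
        rows = [
            {"subject": md.get("subject"), "day": md.get("day"), "level": lvl,
             "value_percent": self.segmental[lvl], "n_ratio_samples": self.n_ratio_samples[lvl],
             "transform": self.transform}
            for lvl in LEVELS
        ]
        for name, val in (("uncompensated", self.uncompensated), ("compensated", self.compensated)):
            rows.append({"subject": md.get("subject"), "day": md.get("day"), "level": name,
                         "value_percent": val, "n_ratio_samples": None, "transform": self.transform})
        return pd.DataFrame(rows)


def segmental_imbalance(
    series: MFSeries, level: str, transform: str = "reciprocal",
    min_pairs: int = MIN_PAIRED_EPOCHS,
) -> tuple[float, int]:
    """Signed percent imbalance of one lumbar level.

    Returns ``(percent, n_pairs)`` where percent = 100 × mean transformed
    right/left ratio over epochs where both sides are non-excluded.
    """
    right, left = f"{level}_right", f"{level}_left"
    for name in (right, left):
        if name not in series.values:
            raise AnalysisError(f"level {level}: channel {name} missing from MF series")
    ratios = ratio_series(series.values[right], series.values[left])
    if len(ratios) < min_pairs:
        raise AnalysisError(f"level {level}: only {len(ratios)} paired epochs < minimum {min_pairs}")
    return float(100.0 * np.mean(symmetric_transform(ratios, transform))), len(ratios)


def global_imbalance(segmental: dict[str, float],
                     n_ratio_samples: "dict[str, int] | None" = None,
                     transform: str = "reciprocal",
                     metadata: "dict | None" = None) -> ImbalanceResult:
    """Combine the three segmental scores into the global imbalance pair."""
    missing = [lvl for lvl in LEVELS if lvl not in segmental]
    if missing:
        raise AnalysisError(f"global imbalance requires all levels; missing {missing}")
    vals = np.array([segmental[lvl] for lvl in LEVELS], dtype=float)
    return ImbalanceResult(
        segmental={lvl: float(segmental[lvl]) for lvl in LEVELS},
        uncompensated=float(np.mean(np.abs(vals))),
        compensated=float(np.mean(vals)),
        n_ratio_samples=dict(n_ratio_samples or {lvl: 0 for lvl in LEVELS}),
        transform=transform,
        metadata=dict(metadata or {}),
    )


def compute_imbalance(series: MFSeries, transform: str = "reciprocal") -> ImbalanceResult:
    """Full imbalance analysis of a six-channel MF series."""
    segmental: dict[str, float] = {}
    n_samples: dict[str, int] = {}
    for lvl in LEVELS:
        segmental[lvl], n_samples[lvl] = segmental_imbalance(series, lvl, transform)
    return global_imbalance(segmental, n_samples, transform, metadata=series.metadata)
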