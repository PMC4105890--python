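"""End-to-end orchestration: filter → MF series → regression → reports.

The pipeline functions are thin, deterministic drivers over the library
modules: they read a manifest of recordings, run the per-recording
analysis (band-pass, artefact screen, MF series, fatigue regression,
imbalance), stack the long outcome table, and hand it to the reliability
and cohort statistics. Per-recording failures are tabulated and the
batch continues. Every written artifact embeds the package version and
a hash of the effective configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import fatigue as _fatigue
from . import gtheory as _gtheory
from . import imbalance as _imbalance
from .cohort import bootstrap_mean_diff, two_way_anova
from .exceptions import DesignError, ParameterError
from .io import EMGRecording, read_emg
from .preprocess import bandpass_filter, detect_artifacts
from .spectral import EpochSpec, MFSeries, mf_series

log = logging.getLogger("emgfatigue")


def _from_dict(cls, d: dict):
    if d is None:
        return cls()
    valid = {f.name for f in fields(cls)}
    unknown = set(d) - valid
    if unknown:
        raise ParameterError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass(frozen=True)
class FilterConfig:
    low_hz: float = 20.0
    high_hz: float = 500.0
    order: int = 4
    notch_50hz: bool = False


@dataclass(frozen=True)
class ArtifactConfig:
    amplitude_uv: float = 3000.0
    clip_fraction: float = 0.95
    min_run: int = 5
    max_bad_fraction: float = 0.10


@dataclass(frozen=True)
class EpochConfig:
    length_s: float = 0.5
    overlap: float = 0.0
    t_start_s: float = 3.0
    t_end_s: float = 30.0
    window: str = "blackman"


@dataclass(frozen=True)
class MFConfig:
    band_low_hz: float = 20.0
    band_high_hz: float = 450.0


@dataclass(frozen=True)
class ImbalanceConfig:
    transform: str = "reciprocal"


@dataclass(frozen=True)
class ReliabilityConfig:
    estimator: str = "reml"
    n_days_decision: int = 1
    n_sides_decision: int = 2


@dataclass(frozen=True)
class CohortConfig:
    n_boot: int = 2000
    seed: int = 0
    ss_type: int = 2


@dataclass(frozen=True)
class PipelineConfig:
    """Effective configuration of a pipeline run; unknown keys rejected."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    epoch: EpochConfig = field(default_factory=EpochConfig)
    mf: MFConfig = field(default_factory=MFConfig)
    imbalance: ImbalanceConfig = field(default_factory=ImbalanceConfig)
    reliability: ReliabilityConfig = field(default_factory=ReliabilityConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    @classmethod
    def from_dict(cls, d: "dict | None") -> "PipelineConfig":
        d = dict(d or {})
        sections = {f.name: f.default_factory for f in fields(cls)}
        unknown = set(d) - set(sections)
        if unknown:
            raise ParameterError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {
            name: _from_dict(factory().__class__, d.get(name))
            for name, factory in sections.items()
        }
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def epoch_spec(self) -> EpochSpec:
        return EpochSpec(
            epoch_length=self.epoch.length_s,
            overlap=self.epoch.overlap,
            t_start=self.epoch.t_start_s,
            t_end=self.epoch.t_end_s,
            window=self.epoch.window,
        )


def analyze_recording(
    rec: EMGRecording,
    config: "PipelineConfig | None" = None,
    metadata: "dict | None" = None,
):
    """Full single-recording analysis.

    Returns ``(FatigueResult, MFSeries, ImbalanceResult | None)``; the
    imbalance result is None when the recording lacks a complete
    bilateral channel set.
    """
    config = config or PipelineConfig()
    filtered = bandpass_filter(
        rec, config.filter.low_hz, config.filter.high_hz,
        config.filter.order, config.filter.notch_50hz,
    )
    mask = detect_artifacts(
        filtered, config.artifact.amplitude_uv,
        config.artifact.clip_fraction, config.artifact.min_run,
    )
    series = mf_series(
        filtered, config.epoch_spec(), mask,
        band=(config.mf.band_low_hz, config.mf.band_high_hz),
        max_bad_fraction=config.artifact.max_bad_fraction,
    )
    result = _fatigue.fit_recording(series, metadata=metadata)
    imb = None
    if len(series.values) == 6:
        imb = _imbalance.compute_imbalance(series, config.imbalance.transform)
        if metadata:
            imb.metadata.update(metadata)
    return result, series, imb


@dataclass
class FatigueRun:
    """Outputs of a batch fatigue run."""

    table: pd.DataFrame            # long outcome table
    imbalance_table: pd.DataFrame  # per-recording imbalance scores
    mf_series: list[MFSeries]
    plot_data: pd.DataFrame        # per-epoch MF + fitted-line endpoints
    failures: pd.DataFrame
    config: PipelineConfig

    @property
    def n_ok(self) -> int:
        return len(self.mf_series)


def _plot_rows(result: "_fatigue.FatigueResult", series: MFSeries) -> list[dict]:
    md = result.metadata
    rows = []
    for ch in series.channels:
        cf = result.channels[ch]
        for t, v, ex in zip(series.times, series.values[ch], series.excluded[ch]):
            rows.append({"subject": md.get("subject"), "day": md.get("day"), "channel": ch,
                         "kind": "mf_point", "time_s": t, "mf_hz": v, "excluded": bool(ex)})
        for t in (series.times[0], series.times[-1]):
            rows.append({"subject": md.get("subject"), "day": md.get("day"), "channel": ch,
                         "kind": "fit_line", "time_s": t,
                         "mf_hz": cf.intercept_t0 + cf.slope * t, "excluded": False})
    return rows


def run_fatigue(manifest, config: "PipelineConfig | None" = None) -> FatigueRun:
    """Run the fatigue pipeline over a manifest of recordings.

    ``manifest`` is an iterable of dicts (or a DataFrame) with at least
    ``path`` (or a ready ``recording``) plus subject/day metadata; extra
    keys (age, gender, ...) are carried into the outcome table. Failing
    recordings are tabulated in ``failures`` and the batch continues.
    """
    config = config or PipelineConfig()
    if isinstance(manifest, pd.DataFrame):
        manifest = manifest.to_dict("records")
    results, imb_frames, all_series, plot_rows, failures = [], [], [], [], []
    extra_cols: dict[tuple, dict] = {}
    for entry in manifest:
        entry = dict(entry)
        rec = entry.pop("recording", None)
        path = entry.pop("path", None)
        label = str(path) if path is not None else f"recording[{len(results)}]"
        try:
            if rec is None:
                rec = read_emg(path)
            res, series, imb = analyze_recording(rec, config, metadata=entry)
            results.append(res)
            all_series.append(series)
            plot_rows.extend(_plot_rows(res, series))
            if imb is not None:
                imb_frames.append(imb.to_frame())
            extra_cols[(entry.get("subject"), entry.get("day"))] = {
                k: v for k, v in entry.items() if k not in ("subject", "day")
            }
            log.info("analyzed %s: %d epochs/channel", label, len(series.times))
        except Exception as err:  # tabulate and continue: one bad file must not kill a batch
            failures.append({"recording": label, "subject": entry.get("subject"),
                             "day": entry.get("day"), "error": f"{type(err).__name__}: {err}"})
            log.warning("failed %s: %s", label, err)
    table = _fatigue.batch_fatigue(results)
    for key, extras in extra_cols.items():
        sel = (table["subject"] == key[0]) & (table["day"] == key[1])
        for k, v in extras.items():
            if k not in table.columns:
                table[k] = None
            table.loc[sel, k] = v
    return FatigueRun(
        table=table,
        imbalance_table=(pd.concat(imb_frames, ignore_index=True)
                         if imb_frames else pd.DataFrame()),
        mf_series=all_series,
        plot_data=pd.DataFrame(plot_rows),
        failures=pd.DataFrame(failures, columns=["recording", "subject", "day", "error"]),
        config=config,
    )


def run_reliability(table: pd.DataFrame, config: "PipelineConfig | None" = None) -> pd.DataFrame:
    """Reliability report (D, absolute SEM, error variance) from a fatigue table."""
    config = config or PipelineConfig()
    days_per_subject = table.groupby("subject")["day"].nunique()
    if (days_per_subject < 2).all():
        raise DesignError("reliability needs at least 2 test days per subject")
    group_col = "age_group" if "age_group" in table.columns else None
    return _gtheory.reliability_report(
        table,
        group_col=group_col,
        method=config.reliability.estimator,
        n_days_decision=config.reliability.n_days_decision,
        n_sides_decision=config.reliability.n_sides_decision,
    )


def run_cohort(table: pd.DataFrame, config: "PipelineConfig | None" = None,
               day: "int | None" = None) -> pd.DataFrame:
    """Cohort comparison report from a fatigue table with group columns.

    Outcomes are averaged over days per subject (the primary analysis;
    pass ``day`` to restrict to a single test day), then each outcome ×
    scope is compared across age and gender with the two-way ANOVA and
    stratified bootstrap mean differences.
    """
    config = config or PipelineConfig()
    for col in ("age_group", "gender"):
        if col not in table.columns:
            raise DesignError(f"cohort analysis needs a {col!r} column in the fatigue table")
    data = table[table["side"] == "both"]
    if day is not None:
        data = data[data["day"] == day]
    per_subject = (
        data.groupby(["subject", "age_group", "gender", "scope", "outcome"], observed=True)["value"]
        .mean()
        .reset_index()
    )
    rows = []
    for (outcome, scope), grp in per_subject.groupby(["outcome", "scope"], observed=True):
        anova = two_way_anova(grp, ss_type=config.cohort.ss_type)
        boot_age = bootstrap_mean_diff(grp, factor="age_group",
                                       n_boot=config.cohort.n_boot, seed=config.cohort.seed)
        boot_gender = bootstrap_mean_diff(grp, factor="gender",
                                          n_boot=config.cohort.n_boot, seed=config.cohort.seed + 1)
        means = grp.groupby("age_group", observed=True)["value"].agg(["mean", "sem"])
        row = {"outcome": outcome, "scope": scope}
        for g in ("young", "old"):
            if g in means.index:
                row[f"mean_{g}"] = means.loc[g, "mean"]
                row[f"se_{g}"] = means.loc[g, "sem"]
        for _, eff in anova.iterrows():
            key = eff["effect"].replace(":", "_x_")
            row[f"F_{key}"] = eff["F"]
            row[f"p_{key}"] = eff["p"]
        row.update({
            "diff_age": boot_age.difference, "diff_age_ci_low": boot_age.ci_low,
            "diff_age_ci_high": boot_age.ci_high,
            "diff_gender": boot_gender.difference, "diff_gender_ci_low": boot_gender.ci_low,
            "diff_gender_ci_high": boot_gender.ci_high,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path: "str | Path",
                config: "PipelineConfig | None" = None) -> Path:
    """Write a result table with a provenance header comment."""
    from . import __version__

    path = Path(path)
    with open(path, "w") as fh:
        cfg_hash = (config or PipelineConfig()).hash
        fh.write(f"# emgfatigue {__version__} config={cfg_hash}\n")
        df.to_csv(fh, index=False)
    return path
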