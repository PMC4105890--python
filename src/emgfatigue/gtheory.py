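"""Generalizability-theory reliability for the subject × day × side design.

Observed fatigue outcomes y_ijk (subject i, test day j, body side k) are
modeled as a crossed random-effects design

    y_ijk = μ + s_i + d_j + l_k + (sd)_ij + (sl)_ik + e_ijk

with independent zero-mean components. The error sources follow the
measurement design of the study this package supports: subject, day,
side, subject×day, subject×side, plus a residual that confounds the
day×side and three-way terms with pure error. Side-aggregated outcomes
(all-electrode mean, most-negative electrode) have one value per
(subject, day), so their G-study is the one-facet subject × day design
in which subject×day is confounded with the residual.

Two estimators are provided:

* ``anova_ems`` — the closed-form expected-mean-squares solution of the
  balanced crossed ANOVA (exact on balanced data; the G-study classic);
* ``reml`` — restricted maximum likelihood on the same model, fitted by
  direct optimization of the profiled restricted likelihood; it accepts
  unbalanced data (dropouts) and is the package default.

A decision study then turns the components into the absolute error
variance for a measurement protocol averaging over n'_d days and n'_s
sides,

    σ²_abs = σ²_d/n'_d + σ²_l/n'_s + σ²_sd/n'_d + σ²_sl/n'_s + σ²_e/(n'_d n'_s),

the dependability coefficient D = σ²_s / (σ²_s + σ²_abs) — the ICC-type
index for absolute (criterion-referenced) decisions — and the absolute
SEM = sqrt(σ²_abs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .exceptions import DesignError, MethodError, ParameterError

TWO_FACET_COMPONENTS = ("subject", "day", "side", "subject:day", "subject:side", "residual")
ONE_FACET_COMPONENTS = ("subject", "day", "residual")


@dataclass
class FacetedDataset:
    """Long-format measurements keyed by subject, day and (optionally) side."""

    data: pd.DataFrame
    outcome: str = ""
    scope: str = ""

    def __post_init__(self) -> None:
        required = {"subject", "day", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise DesignError(f"faceted data missing columns {sorted(missing)}")
        self.data = self.data.copy()

    @property
    def has_side(self) -> bool:
        return "side" in self.data.columns and self.data["side"].nunique() > 1

    @property
    def facets(self) -> list[str]:
        return ["subject", "day", "side"] if self.has_side else ["subject", "day"]

    @property
    def n_subjects(self) -> int:
        return self.data["subject"].nunique()

    @property
    def n_days(self) -> int:
        return self.data["day"].nunique()

    @property
    def n_sides(self) -> int:
        return self.data["side"].nunique() if self.has_side else 1

    def is_balanced(self) -> bool:
        counts = self.data.groupby(self.facets, observed=True).size()
        expected = self.n_subjects * self.n_days * (self.n_sides if self.has_side else 1)
        return len(counts) == expected and (counts == 1).all()

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise DesignError("at least 2 subjects required for identifiability")
        if self.n_days < 2:
            raise DesignError("at least 2 days required for identifiability")


@dataclass
class VarianceComponents:
    """Estimated variance components of a G-study."""

    sigma2: dict[str, float]
    estimator: str
    design: str  # "two_facet" | "one_facet"
    negative_truncated: tuple[str, ...] = ()
    mean_squares: dict[str, float] = field(default_factory=dict)
    n_levels: dict[str, int] = field(default_factory=dict)

    @property
    def components(self) -> tuple[str, ...]:
        return TWO_FACET_COMPONENTS if self.design == "two_facet" else ONE_FACET_COMPONENTS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"component": c, "sigma2": self.sigma2[c],
              "truncated": c in self.negative_truncated} for c in self.components]
        )


def _balanced_cube(ds: FacetedDataset) -> np.ndarray:
    """Pivot a balanced dataset to an array indexed (subject, day[, side])."""
    if ds.has_side:
        piv = ds.data.pivot_table(index="subject", columns=["day", "side"], values="value")
        a, b, c = ds.n_subjects, ds.n_days, ds.n_sides
        return piv.to_numpy().reshape(a, b, c)
    piv = ds.data.pivot_table(index="subject", columns="day", values="value")
    return piv.to_numpy()


def _anova_ems_two_facet(y: np.ndarray) -> tuple[dict, dict]:
    a, b, c = y.shape
    gm = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_d = y.mean(axis=(0, 2))
    m_l = y.mean(axis=(0, 1))
    m_sd = y.mean(axis=2)
    m_sl = y.mean(axis=1)
    ss_s = b * c * np.sum((m_s - gm) ** 2)
    ss_d = a * c * np.sum((m_d - gm) ** 2)
    ss_l = a * b * np.sum((m_l - gm) ** 2)
    ss_sd = c * np.sum((m_sd - m_s[:, None] - m_d[None, :] + gm) ** 2)
    ss_sl = b * np.sum((m_sl - m_s[:, None] - m_l[None, :] + gm) ** 2)
    ss_tot = np.sum((y - gm) ** 2)
    ss_res = ss_tot - (ss_s + ss_d + ss_l + ss_sd + ss_sl)
    df = {
        "subject": a - 1, "day": b - 1, "side": c - 1,
        "subject:day": (a - 1) * (b - 1), "subject:side": (a - 1) * (c - 1),
        "residual": a * (b - 1) * (c - 1),
    }
    ms = {
        "subject": ss_s / df["subject"], "day": ss_d / df["day"], "side": ss_l / df["side"],
        "subject:day": ss_sd / df["subject:day"], "subject:side": ss_sl / df["subject:side"],
        "residual": max(ss_res, 0.0) / df["residual"] if df["residual"] > 0 else 0.0,
    }
    sig = {}
    sig["residual"] = ms["residual"]
    sig["subject:day"] = (ms["subject:day"] - ms["residual"]) / c
    sig["subject:side"] = (ms["subject:side"] - ms["residual"]) / b
    sig["day"] = (ms["day"] - ms["subject:day"]) / (a * c)
    sig["side"] = (ms["side"] - ms["subject:side"]) / (a * b)
    sig["subject"] = (ms["subject"] - ms["subject:day"] - ms["subject:side"] + ms["residual"]) / (b * c)
    return sig, ms


def _anova_ems_one_facet(y: np.ndarray) -> tuple[dict, dict]:
    a, b = y.shape
    gm = y.mean()
    m_s = y.mean(axis=1)
    m_d = y.mean(axis=0)
    ss_s = b * np.sum((m_s - gm) ** 2)
    ss_d = a * np.sum((m_d - gm) ** 2)
    ss_res = np.sum((y - m_s[:, None] - m_d[None, :] + gm) ** 2)
    ms = {
        "subject": ss_s / (a - 1),
        "day": ss_d / (b - 1),
        "residual": ss_res / ((a - 1) * (b - 1)),
    }
    sig = {
        "residual": ms["residual"],
        "day": (ms["day"] - ms["residual"]) / a,
        "subject": (ms["subject"] - ms["residual"]) / b,
    }
    return sig, ms


def _design_matrices(ds: FacetedDataset) -> tuple[np.ndarray, list[tuple[str, np.ndarray]]]:
    df = ds.data
    y = df["value"].to_numpy(dtype=float)

    def onehot(keys: pd.Series) -> np.ndarray:
        codes, _ = pd.factorize(keys)
        z = np.zeros((len(codes), codes.max() + 1))
        z[np.arange(len(codes)), codes] = 1.0
        return z

    zs: list[tuple[str, np.ndarray]] = [("subject", onehot(df["subject"]))]
    zs.append(("day", onehot(df["day"])))
    if ds.has_side:
        zs.append(("side", onehot(df["side"])))
        zs.append(("subject:day", onehot(df["subject"].astype(str) + "/" + df["day"].astype(str))))
        zs.append(("subject:side", onehot(df["subject"].astype(str) + "/" + df["side"].astype(str))))
    return y, zs


def _reml_neg2loglik(log_sig: np.ndarray, y: np.ndarray,
                     grams: list[np.ndarray]) -> float:
    n = len(y)
    sig = np.exp(log_sig)
    v = sig[-1] * np.eye(n)
    for s2, g in zip(sig[:-1], grams):
        v += s2 * g
    try:
        cf = cho_factor(v, lower=True)
    except np.linalg.LinAlgError:
        return 1e12
    logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
    x = np.ones(n)
    vi_y = cho_solve(cf, y)
    vi_x = cho_solve(cf, x)
    xvx = float(x @ vi_x)
    xvy = float(x @ vi_y)
    quad = float(y @ vi_y) - xvy**2 / xvx
    return logdet_v + np.log(xvx) + quad


def _reml(ds: FacetedDataset, components: tuple[str, ...]) -> dict[str, float]:
    y, zs = _design_matrices(ds)
    names = [name for name, _ in zs]
    grams = [z @ z.T for _, z in zs]
    var_y = float(np.var(y, ddof=1))
    if var_y == 0:
        return {c: 0.0 for c in components}
    k = len(grams) + 1
    x0 = np.log(np.full(k, var_y / k).clip(1e-10))
    res = optimize.minimize(
        _reml_neg2loglik, x0, args=(y, grams), method="L-BFGS-B",
        bounds=[(np.log(1e-10 * var_y), np.log(10 * var_y))] * k,
    )
    sig = np.exp(res.x)
    floor = 1e-6 * var_y
    out = {name: (float(s) if s > floor else 0.0) for name, s in zip(names, sig[:-1])}
    out["residual"] = float(sig[-1]) if sig[-1] > floor else 0.0
    return {c: out.get(c, 0.0) for c in components}


def estimate_components(data: FacetedDataset, method: str = "reml") -> VarianceComponents:
    """Estimate the G-study variance components of a faceted dataset.

    ``anova_ems`` requires a balanced design (every subject × day × side
    cell filled exactly once) and solves the expected-mean-square
    equations in closed form, truncating negative estimates to zero with
    a flag. ``reml`` maximizes the restricted likelihood and also
    handles unbalanced data.
    """
    data.validate()
    design = "two_facet" if data.has_side else "one_facet"
    components = TWO_FACET_COMPONENTS if design == "two_facet" else ONE_FACET_COMPONENTS
    n_levels = {"subject": data.n_subjects, "day": data.n_days}
    if design == "two_facet":
        n_levels["side"] = data.n_sides

    if method == "anova_ems":
        if not data.is_balanced():
            raise MethodError("anova_ems requires a balanced design; use method='reml'")
        y = _balanced_cube(data)
        raw, ms = (_anova_ems_two_facet(y) if design == "two_facet" else _anova_ems_one_facet(y))
        truncated = tuple(c for c in components if raw[c] < 0)
        sigma2 = {c: float(max(raw[c], 0.0)) for c in components}
        return VarianceComponents(sigma2, "anova_ems", design, truncated, ms, n_levels)
    if method == "reml":
        sigma2 = _reml(data, components)
        return VarianceComponents(sigma2, "reml", design, (), {}, n_levels)
    raise MethodError(f"unknown estimator {method!r}")


def absolute_error_variance(
    vc: VarianceComponents, n_days_decision: int = 1, n_sides_decision: int = 2
) -> float:
    """Absolute (criterion-referenced) error variance of the decision study.

    Every non-subject component contributes, divided by the number of
    conditions of its facet averaged over in the decision protocol. For
    side-aggregated outcomes (one-facet design) the side terms are absent
    and ``n_sides_decision`` is ignored.
    """
    if n_days_decision < 1 or n_sides_decision < 1:
        raise ParameterError("decision-study facet sizes must be >= 1")
    s = vc.sigma2
    if vc.design == "two_facet":
        return (
            s["day"] / n_days_decision
            + s["side"] / n_sides_decision
            + s["subject:day"] / n_days_decision
            + s["subject:side"] / n_sides_decision
            + s["residual"] / (n_days_decision * n_sides_decision)
        )
    return s["day"] / n_days_decision + s["residual"] / n_days_decision


def d_label(d: float) -> str:
    """Qualitative ICC-style label: .4–.6 moderate, .6–.75 good, >.75 excellent."""
    if d > 0.75:
        return "excellent"
    if d >= 0.6:
        return "good"
    if d >= 0.4:
        return "moderate"
    return "poor"


@dataclass
class ReliabilityResult:
    """Dependability of one outcome/scope under a given decision study."""

    components: VarianceComponents
    abs_error_variance: float
    d_coefficient: float
    sem_absolute: float
    n_days_decision: int
    n_sides_decision: int
    label: str
    outcome: str = ""
    scope: str = ""

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "scope": self.scope,
            "estimator": self.components.estimator,
            "design": self.components.design,
            "sigma2": dict(self.components.sigma2),
            "negative_truncated": list(self.components.negative_truncated),
            "n_days_decision": self.n_days_decision,
            "n_sides_decision": self.n_sides_decision,
            "abs_error_variance": self.abs_error_variance,
            "d_coefficient": self.d_coefficient,
            "sem_absolute": self.sem_absolute,
            "label": self.label,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [{"quantity": f"sigma2_{c}", "value": self.components.sigma2[c]}
                for c in self.components.components]
        rows += [
            {"quantity": "abs_error_variance", "value": self.abs_error_variance},
            {"quantity": "d_coefficient", "value": self.d_coefficient},
            {"quantity": "sem_absolute", "value": self.sem_absolute},
        ]
        return pd.DataFrame(rows)


def dependability(
    vc: VarianceComponents,
    n_days_decision: int = 1,
    n_sides_decision: int = 2,
    outcome: str = "",
    scope: str = "",
) -> ReliabilityResult:
    """Dependability coefficient D, absolute error variance and SEM.

    D = σ²_subject / (σ²_subject + σ²_abs) ∈ [0, 1]; SEM = sqrt(σ²_abs).
    """
    s2_abs = absolute_error_variance(vc, n_days_decision, n_sides_decision)
    s2_subj = vc.sigma2["subject"]
    denom = s2_subj + s2_abs
    if denom == 0:
        raise DesignError("D undefined: subject and error variance are both zero")
    d = s2_subj / denom
    return ReliabilityResult(
        components=vc,
        abs_error_variance=float(s2_abs),
        d_coefficient=float(d),
        sem_absolute=float(np.sqrt(s2_abs)),
        n_days_decision=n_days_decision,
        n_sides_decision=n_sides_decision,
        label=d_label(d),
        outcome=outcome,
        scope=scope,
    )


def reliability_report(
    table: pd.DataFrame,
    group_col: "str | None" = "age_group",
    outcomes: tuple[str, ...] = ("imf", "slope_hzs", "slope_norm"),
    scopes: tuple[str, ...] = ("all", "L5", "L2", "L1", "most_negative"),
    method: str = "reml",
    n_days_decision: int = 1,
    n_sides_decision: int = 2,
) -> pd.DataFrame:
    """Reliability summary per outcome × scope (× group).

    ``table`` is the long fatigue table (subject, day, side, scope,
    outcome, value[, group_col]). Per-level scopes use the left/right
    rows (two-facet design); the side-aggregated scopes use the
    side == "both" rows (one-facet design). Output columns: one row per
    outcome × scope × group with D, absolute SEM and error variance.
    """
    rows = []
    groups = sorted(table[group_col].dropna().unique()) if group_col and group_col in table else [None]
    for outcome in outcomes:
        for scope in scopes:
            sub = table[(table["outcome"] == outcome) & (table["scope"] == scope)]
            if scope in ("all", "most_negative"):
                sub = sub[sub["side"] == "both"]
                cols = ["subject", "day", "value"]
            else:
                sub = sub[sub["side"].isin(["left", "right"])]
                cols = ["subject", "day", "side", "value"]
            for grp in groups:
                part = sub if grp is None else sub[sub[group_col] == grp]
                if part.empty:
                    continue
                ds = FacetedDataset(part[cols], outcome=outcome, scope=scope)
                rel = dependability(
                    estimate_components(ds, method=method),
                    n_days_decision, n_sides_decision, outcome=outcome, scope=scope,
                )
                rows.append({
                    "outcome": outcome, "scope": scope, "group": grp,
                    "d_coefficient": rel.d_coefficient,
                    "sem_absolute": rel.sem_absolute,
                    "error_variance": rel.abs_error_variance,
                    "label": rel.label,
                    "estimator": method,
                })
    return pd.DataFrame(rows)
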