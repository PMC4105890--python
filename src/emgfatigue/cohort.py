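"""Cohort-level statistics: age × gender ANOVA and bootstrap contrasts.

Outcomes are compared between two age groups (young < 50 years, old
≥ 50) and genders with a two-way ANOVA (type II sums of squares — the
2×2 design is unbalanced) and with stratified percentile-bootstrap
confidence intervals for the two main-effect mean differences. A thin
Shapiro–Wilk wrapper is provided as an advisory normality diagnostic; it
never gates the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .exceptions import AnalysisError, DesignError, ParameterError

AGE_THRESHOLD = 50.0

#: Contrast orientation: value reported is mean(first) − mean(second).
FACTOR_LEVELS = {"age_group": ("young", "old"), "gender": ("male", "female")}


def age_group(age: float) -> str:
    """Dichotomize age at the 50-year threshold."""
    return "old" if age >= AGE_THRESHOLD else "young"


def two_way_anova(
    cohort: pd.DataFrame,
    value: str = "value",
    age: str = "age_group",
    gender: str = "gender",
    ss_type: int = 2,
) -> pd.DataFrame:
    """Two-way age × gender ANOVA of one outcome.

    Returns a table with F and p for the two main effects and their
    interaction. Requires at least 2 subjects per cell of the 2×2 design
    and a non-degenerate outcome.
    """
    df = cohort[[value, age, gender]].dropna()
    cells = df.groupby([age, gender], observed=True).size()
    if len(cells) < 4 or (cells < 2).any():
        raise DesignError(f"need >= 2 observations in every age × gender cell, got:\n{cells}")
    if float(np.var(df[value])) == 0:
        raise DesignError(f"outcome {value!r} is constant; ANOVA undefined")
    model = ols(f"Q('{value}') ~ C(Q('{age}')) * C(Q('{gender}'))", data=df).fit()
    tab = anova_lm(model, typ=ss_type)
    out = pd.DataFrame({
        "effect": ["age", "gender", "age:gender"],
        "F": tab["F"].iloc[:3].to_numpy(),
        "p": tab["PR(>F)"].iloc[:3].to_numpy(),
        "sum_sq": tab["sum_sq"].iloc[:3].to_numpy(),
    })
    out.attrs["ss_type"] = ss_type
    return out


@dataclass(frozen=True)
class BootstrapCI:
    """A bootstrap mean difference with its percentile CI."""

    difference: float
    ci_low: float
    ci_high: float
    factor: str
    levels: tuple[str, str]
    n_boot: int


def bootstrap_mean_diff(
    cohort: pd.DataFrame,
    value: str = "value",
    factor: str = "age_group",
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
    levels: "tuple[str, str] | None" = None,
) -> BootstrapCI:
    """Stratified percentile-bootstrap CI of a two-level mean difference.

    Resamples with replacement within each factor level (stratified), so
    group sizes are preserved; the reported difference is
    mean(levels[0]) − mean(levels[1]). Deterministic for a given seed.
    """
    if n_boot < 100:
        raise ParameterError("n_boot must be >= 100")
    df = cohort[[value, factor]].dropna()
    if levels is None:
        levels = FACTOR_LEVELS.get(factor)
    if levels is None:
        uniq = tuple(sorted(df[factor].unique()))
        if len(uniq) != 2:
            raise DesignError(f"factor {factor!r} must have exactly 2 levels, got {uniq}")
        levels = uniq
    a = df.loc[df[factor] == levels[0], value].to_numpy(dtype=float)
    b = df.loc[df[factor] == levels[1], value].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DesignError(f"each level of {factor!r} needs >= 2 subjects")
    rng = np.random.default_rng(seed)
    boot_a = a[rng.integers(0, len(a), size=(n_boot, len(a)))].mean(axis=1)
    boot_b = b[rng.integers(0, len(b), size=(n_boot, len(b)))].mean(axis=1)
    diffs = boot_a - boot_b
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    return BootstrapCI(
        difference=float(a.mean() - b.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        factor=factor,
        levels=levels,
        n_boot=n_boot,
    )


def normality_check(values: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk statistic and p-value (diagnostic only)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise AnalysisError("normality check needs at least 3 values")
    if np.ptp(x) == 0:
        raise AnalysisError("normality check undefined for a constant sample")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)
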