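"""G-theory: variance components, dependability, decision-study algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emgfatigue import (
    DesignError,
    FacetedDataset,
    GStudyGenSpec,
    MethodError,
    absolute_error_variance,
    dependability,
    estimate_components,
    generate_gstudy,
    reliability_report,
)
from emgfatigue.gtheory import TWO_FACET_COMPONENTS, VarianceComponents, d_label


def vc_of(sigma2, design="two_facet"):
    return VarianceComponents(dict(sigma2), "anova_ems", design)


def ems_brute_force(ds: FacetedDataset) -> dict:
    """Independent EMS solution: explicit mean squares + linear solve.

    Builds the expected-mean-square coefficient matrix of the crossed
    two-facet random design and solves it against mean squares computed
    with plain pandas groupbys — no shared code with the estimator.
    """
    df = ds.data
    a = df["subject"].nunique()
    b = df["day"].nunique()
    c = df["side"].nunique()
    gm = df["value"].mean()

    def ss(groupcols, mult):
        m = df.groupby(groupcols, observed=True)["value"].mean()
        return mult * ((m - gm) ** 2).sum()

    ss_s = ss("subject", b * c)
    ss_d = ss("day", a * c)
    ss_l = ss("side", a * b)
    m_sd = df.groupby(["subject", "day"], observed=True)["value"].mean()
    m_s = df.groupby("subject", observed=True)["value"].mean()
    m_d = df.groupby("day", observed=True)["value"].mean()
    ss_sd = c * sum(
        (m_sd[s, d] - m_s[s] - m_d[d] + gm) ** 2 for s, d in m_sd.index
    )
    m_sl = df.groupby(["subject", "side"], observed=True)["value"].mean()
    m_l = df.groupby("side", observed=True)["value"].mean()
    ss_sl = b * sum(
        (m_sl[s, l] - m_s[s] - m_l[l] + gm) ** 2 for s, l in m_sl.index
    )
    ss_tot = ((df["value"] - gm) ** 2).sum()
    ss_e = ss_tot - ss_s - ss_d - ss_l - ss_sd - ss_sl
    ms = np.array([
        ss_s / (a - 1), ss_d / (b - 1), ss_l / (c - 1),
        ss_sd / ((a - 1) * (b - 1)), ss_sl / ((a - 1) * (c - 1)),
        ss_e / (a * (b - 1) * (c - 1)),
    ])
    # EMS coefficients, order: subject, day, side, s x d, s x l, residual
    coeff = np.array([
        [b * c, 0, 0, c, b, 1],
        [0, a * c, 0, c, 0, 1],
        [0, 0, a * b, 0, b, 1],
        [0, 0, 0, c, 0, 1],
        [0, 0, 0, 0, b, 1],
        [0, 0, 0, 0, 0, 1],
    ], dtype=float)
    sol = np.linalg.solve(coeff, ms)
    return dict(zip(TWO_FACET_COMPONENTS, sol))


class TestEstimators:
    def test_identical_observations_give_zero_components(self):
        ds = generate_gstudy(GStudyGenSpec(
            sigma2={k: 0.0 for k in TWO_FACET_COMPONENTS},
            n_subjects=8, seed=0))
        vc = estimate_components(ds, "anova_ems")
        assert all(v == 0.0 for v in vc.sigma2.values())

    def test_anova_ems_matches_independent_solution_exactly(self):
        ds = generate_gstudy(GStudyGenSpec(n_subjects=25, seed=5))
        vc = estimate_components(ds, "anova_ems")
        brute = ems_brute_force(ds)
        for k, v in brute.items():
            assert vc.sigma2[k] == pytest.approx(max(v, 0.0), abs=1e-9)
        if any(v < 0 for v in brute.values()):
            assert vc.negative_truncated

    def test_subject_and_residual_only_design(self):
        sigma2 = {"subject": 25.0, "day": 0.0, "side": 0.0,
                  "subject:day": 0.0, "subject:side": 0.0, "residual": 4.0}
        ds = generate_gstudy(GStudyGenSpec(sigma2=sigma2, n_subjects=200, seed=8))
        vc = estimate_components(ds, "anova_ems")
        for k in ("day", "side", "subject:day", "subject:side"):
            assert vc.sigma2[k] < 0.1 * vc.sigma2["residual"]
        assert vc.sigma2["subject"] == pytest.approx(25.0, rel=0.3)

    def test_reml_agrees_with_ems_on_balanced_data(self):
        ds = generate_gstudy(GStudyGenSpec(n_subjects=60, seed=12))
        ems = estimate_components(ds, "anova_ems")
        reml = estimate_components(ds, "reml")
        for k, v in ems.sigma2.items():
            if v > 0.05:
                assert reml.sigma2[k] == pytest.approx(v, rel=0.05)

    def test_reml_handles_unbalanced_data(self):
        ds = generate_gstudy(GStudyGenSpec(n_subjects=30, seed=2))
        ds.data = ds.data.drop(index=ds.data.index[:7])
        vc = estimate_components(ds, "reml")
        assert vc.sigma2["subject"] > 0
        with pytest.raises(MethodError):
            estimate_components(ds, "anova_ems")

    def test_single_subject_rejected(self):
        df = pd.DataFrame({"subject": [1] * 6, "day": [1, 1, 2, 2, 3, 3],
                           "side": ["left", "right"] * 3, "value": np.arange(6.0)})
        with pytest.raises(DesignError):
            estimate_components(FacetedDataset(df), "anova_ems")

    def test_one_facet_design_detected(self):
        ds = generate_gstudy(GStudyGenSpec(n_subjects=20, n_sides=1, seed=3))
        vc = estimate_components(ds, "anova_ems")
        assert vc.design == "one_facet"
        assert set(vc.sigma2) == {"subject", "day", "residual"}


class TestDecisionStudy:
    def test_absolute_error_variance_hand_example(self):
        vc = vc_of({"subject": 25, "day": 1, "side": 0.5,
                    "subject:day": 2, "subject:side": 1, "residual": 4})
        # 1/1 + 0.5/2 + 2/1 + 1/2 + 4/2
        assert absolute_error_variance(vc, 1, 2) == pytest.approx(5.75)

    def test_zero_error_components(self):
        vc = vc_of({"subject": 25, "day": 0, "side": 0,
                    "subject:day": 0, "subject:side": 0, "residual": 0})
        assert absolute_error_variance(vc, 1, 2) == 0.0

    def test_monotone_in_facet_sizes(self):
        vc = vc_of({"subject": 25, "day": 1, "side": 0.5,
                    "subject:day": 2, "subject:side": 1, "residual": 4})
        v1 = absolute_error_variance(vc, 1, 2)
        v2 = absolute_error_variance(vc, 2, 2)
        assert v2 < v1
        assert v2 == pytest.approx(1.0 / 2 + 0.25 + 2.0 / 2 + 0.5 + 4.0 / 4)

    def test_dependability_arithmetic(self):
        vc = vc_of({"subject": 25, "day": 1, "side": 0.5,
                    "subject:day": 2, "subject:side": 1, "residual": 4})
        rel = dependability(vc, 1, 2)
        assert rel.d_coefficient == pytest.approx(25 / 30.75, abs=5e-4)  # 0.813
        assert rel.sem_absolute == pytest.approx(np.sqrt(5.75), abs=5e-4)  # 2.398
        assert rel.label == "excellent"

    def test_perfect_and_zero_reliability(self):
        perfect = vc_of({"subject": 25, "day": 0, "side": 0,
                         "subject:day": 0, "subject:side": 0, "residual": 0})
        rel = dependability(perfect, 1, 2)
        assert rel.d_coefficient == 1.0 and rel.sem_absolute == 0.0
        none = vc_of({"subject": 0, "day": 1, "side": 0,
                      "subject:day": 0, "subject:side": 0, "residual": 1})
        assert dependability(none, 1, 2).d_coefficient == 0.0

    def test_undefined_d_raises(self):
        zero = vc_of({k: 0.0 for k in TWO_FACET_COMPONENTS})
        with pytest.raises(DesignError):
            dependability(zero, 1, 2)

    @settings(max_examples=100, deadline=None)
    @given(
        subj=st.floats(0.1, 100), day=st.floats(0, 10), side=st.floats(0, 10),
        sd=st.floats(0, 10), sl=st.floats(0, 10), res=st.floats(0.01, 10),
        bump=st.floats(0.1, 5),
    )
    def test_d_monotone_in_components(self, subj, day, side, sd, sl, res, bump):
        base = {"subject": subj, "day": day, "side": side,
                "subject:day": sd, "subject:side": sl, "residual": res}
        d0 = dependability(vc_of(base), 1, 2).d_coefficient
        up = dict(base, subject=subj + bump)
        assert dependability(vc_of(up), 1, 2).d_coefficient >= d0
        for err in ("day", "side", "subject:day", "subject:side", "residual"):
            worse = dict(base)
            worse[err] += bump
            assert dependability(vc_of(worse), 1, 2).d_coefficient <= d0

    def test_sem_scales_linearly_with_units(self):
        ds = generate_gstudy(GStudyGenSpec(n_subjects=30, seed=9))
        rel = dependability(estimate_components(ds, "anova_ems"), 1, 2)
        scaled = FacetedDataset(ds.data.assign(value=ds.data["value"] * 10.0))
        rel10 = dependability(estimate_components(scaled, "anova_ems"), 1, 2)
        assert rel10.sem_absolute == pytest.approx(10.0 * rel.sem_absolute, rel=1e-6)
        assert rel10.d_coefficient == pytest.approx(rel.d_coefficient, rel=1e-9)


class TestReport:
    def make_table(self, n_subjects=8, seed=0):
        """Long fatigue-style table with per-side and side-aggregated rows."""
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subjects):
            grp = "young" if s % 2 else "old"
            base = rng.normal(90, 6)
            for day in (1, 2, 3):
                for outcome in ("imf", "slope_hzs", "slope_norm"):
                    for scope in ("L1", "L2", "L5"):
                        for side in ("left", "right"):
                            rows.append({"subject": s, "day": day, "side": side,
                                         "scope": scope, "outcome": outcome,
                                         "value": base + rng.normal(0, 1),
                                         "age_group": grp})
                    for scope in ("all", "most_negative"):
                        rows.append({"subject": s, "day": day, "side": "both",
                                     "scope": scope, "outcome": outcome,
                                     "value": base + rng.normal(0, 1),
                                     "age_group": grp})
        return pd.DataFrame(rows)

    def test_report_shape_and_sem_consistency(self):
        report = reliability_report(self.make_table(), method="anova_ems")
        assert len(report) == 30  # 3 outcomes x 5 scopes x 2 groups
        np.testing.assert_allclose(
            report["sem_absolute"], np.sqrt(report["error_variance"]), rtol=1e-9
        )

    def test_high_subject_variance_gives_high_d(self):
        sigma2 = {"subject": 100.0, "day": 0.1, "side": 0.1,
                  "subject:day": 0.2, "subject:side": 0.2, "residual": 0.5}
        ds = generate_gstudy(GStudyGenSpec(sigma2=sigma2, n_subjects=60, seed=4))
        rel = dependability(estimate_components(ds, "anova_ems"), 1, 2)
        assert rel.d_coefficient > 0.9

    def test_labels_follow_icc_conventions(self):
        assert d_label(0.5) == "moderate"
        assert d_label(0.65) == "good"
        assert d_label(0.8) == "excellent"
        assert d_label(0.2) == "poor"
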