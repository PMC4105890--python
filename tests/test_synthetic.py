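"""Synthetic generators: determinism, spectral ground truth, design structure."""

import numpy as np
import pytest

from emgfatigue import (
    EMGGenSpec,
    GStudyGenSpec,
    ParameterError,
    SpectrumTemplate,
    generate_cohort,
    generate_emg,
    generate_gstudy,
    template_for_median,
)
from emgfatigue.simulate import ChannelSpec


def brute_force_median(template: SpectrumTemplate, n_grid: int = 400_001) -> float:
    """Numeric median of the template: dense-grid shoulder mass + carrier line."""
    lo, hi = template.band
    f = np.linspace(lo, hi, n_grid)
    shoulder = template.shoulder_psd(f)
    shoulder_mass = np.trapezoid(shoulder, f)
    df_masses = np.diff(f) * 0.5 * (shoulder[1:] + shoulder[:-1])
    q = template.carrier_fraction
    w = (1 - q) / shoulder_mass
    cum = np.concatenate([[0.0], np.cumsum(df_masses)]) * w
    cum = cum + q * (f >= template.center)
    k = int(np.searchsorted(cum, 0.5))
    return float(f[k])


class TestTemplate:
    @pytest.mark.parametrize("target", [70.0, 85.0, 100.0, 115.0, 250.0])
    def test_analytic_median_matches_brute_force(self, target):
        tmpl = template_for_median(target)
        assert tmpl.median() == pytest.approx(target, abs=1e-6)
        assert brute_force_median(tmpl) == pytest.approx(target, abs=0.05)

    def test_cumulative_is_half_at_median(self):
        tmpl = template_for_median(95.0)
        m = tmpl.median()
        assert tmpl.cumulative(m - 1e-9) <= 0.5 <= tmpl.cumulative(m)

    def test_target_outside_band_rejected(self):
        with pytest.raises(ParameterError):
            template_for_median(10.0)
        with pytest.raises(ParameterError):
            SpectrumTemplate(center=500.0)

    def test_commanded_trajectory_is_exact_ground_truth(self):
        """Template median at block midpoints equals the commanded line."""
        spec = EMGGenSpec(imf0=100.0, slope=-0.4)
        t_mid = 0.125 + 0.125 * np.arange(0, 230)
        commanded = spec.trajectory(t_mid)
        for m in commanded[:: 23]:
            tmpl = template_for_median(float(m), spec.carrier_fraction, spec.shoulder_width)
            assert tmpl.median() == pytest.approx(float(m), abs=0.5)


class TestEMGGenerator:
    def test_bit_identical_for_same_seed(self):
        a = generate_emg(EMGGenSpec(seed=5, channels=("L5_left", "L5_right")))
        b = generate_emg(EMGGenSpec(seed=5, channels=("L5_left", "L5_right")))
        for ch in a.samples:
            np.testing.assert_array_equal(a.samples[ch], b.samples[ch])
        c = generate_emg(EMGGenSpec(seed=6, channels=("L5_left", "L5_right")))
        assert not np.array_equal(a.samples["L5_left"], c.samples["L5_left"])

    def test_rms_and_shape(self):
        rec = generate_emg(EMGGenSpec(rms=80.0, duration=10.0, seed=1, channels=("L1_left",)))
        x = rec.channel("L1_left")
        assert len(x) == 20000
        assert np.sqrt(np.mean(x**2)) == pytest.approx(80.0, rel=1e-6)

    def test_channel_override_changes_one_channel_only(self):
        ov = {"L5_right": ChannelSpec(imf0=110.0)}
        rec = generate_emg(EMGGenSpec(seed=2, channel_overrides=ov,
                                      channels=("L5_left", "L5_right")))
        truth = rec.metadata["ground_truth"]
        assert truth["L5_right"]["imf0"] == pytest.approx(110.0)
        assert truth["L5_left"]["imf0"] == pytest.approx(100.0)

    def test_artifact_spikes_inserted(self):
        rec = generate_emg(EMGGenSpec(seed=3, channels=("L2_left",),
                                      artifacts=((5.0, 9999.0, 20),)))
        i0 = int(5.0 * 2000)
        assert np.all(rec.channel("L2_left")[i0:i0 + 20] == 9999.0)

    def test_out_of_band_trajectory_rejected(self):
        with pytest.raises(ParameterError):
            generate_emg(EMGGenSpec(imf0=25.0, slope=-0.3))

    def test_null_slope_recovery_contains_zero(self):
        """Estimated slope CI covers 0 for a stationary generator."""
        from scipy import stats

        from emgfatigue import bandpass_filter, detect_artifacts, mf_series

        hits = 0
        for seed in range(20):
            rec = generate_emg(EMGGenSpec(imf0=90.0, slope=0.0, seed=seed,
                                          channels=("L1_right",)))
            filt = bandpass_filter(rec)
            series = mf_series(filt, mask=detect_artifacts(filt))
            t, v = series.channel_points("L1_right")
            res = stats.linregress(t, v)
            half = 3.0 * res.stderr
            hits += (res.slope - half) <= 0.0 <= (res.slope + half)
        assert hits >= 18  # >= 90% of seeds, 3-SE interval


class TestGStudyGenerator:
    def test_zero_variances_give_constant(self):
        zero = {k: 0.0 for k in ("subject", "day", "side",
                                 "subject:day", "subject:side", "residual")}
        ds = generate_gstudy(GStudyGenSpec(sigma2=zero, grand_mean=42.0,
                                           n_subjects=5, seed=0))
        assert np.allclose(ds.data["value"], 42.0)
        assert len(ds.data) == 5 * 3 * 2

    def test_subject_variance_only_structure(self):
        sigma2 = {"subject": 9.0, "day": 0.0, "side": 0.0,
                  "subject:day": 0.0, "subject:side": 0.0, "residual": 0.0}
        ds = generate_gstudy(GStudyGenSpec(sigma2=sigma2, n_subjects=6, seed=1))
        spread = ds.data.groupby("subject")["value"].std()
        assert np.allclose(spread, 0.0)
        assert ds.data.groupby("subject")["value"].mean().std() > 0

    def test_balanced_and_deterministic(self):
        a = generate_gstudy(GStudyGenSpec(n_subjects=7, seed=3))
        b = generate_gstudy(GStudyGenSpec(n_subjects=7, seed=3))
        assert a.data.equals(b.data)
        assert a.is_balanced()

    def test_negative_variance_rejected(self):
        bad = {"subject": -1.0, "day": 0.0, "side": 0.0,
               "subject:day": 0.0, "subject:side": 0.0, "residual": 1.0}
        with pytest.raises(Exception):
            generate_gstudy(GStudyGenSpec(sigma2=bad))


class TestCohortGenerator:
    def test_reference_cell_sizes(self):
        df = generate_cohort(seed=0)
        counts = df.groupby(["age_group", "gender"]).size()
        assert counts[("young", "female")] == 19
        assert counts[("young", "male")] == 25
        assert counts[("old", "female")] == 21
        assert counts[("old", "male")] == 21

    def test_age_group_consistent_with_age(self):
        df = generate_cohort(seed=1)
        assert ((df["age"] >= 50) == (df["age_group"] == "old")).all()

    def test_effects_shift_group_means(self):
        from emgfatigue.simulate import OutcomeEffect

        eff = {"y": OutcomeEffect(mean=0.0, sd=0.5, age_effect=3.0, gender_effect=1.0)}
        df = generate_cohort(n_young=200, n_old=200, n_young_female=100,
                             n_old_female=100, effects=eff, seed=2)
        by_age = df.groupby("age_group")["y"].mean()
        assert by_age["old"] - by_age["young"] == pytest.approx(3.0, abs=0.3)

    def test_deterministic(self):
        assert generate_cohort(seed=9).equals(generate_cohort(seed=9))

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ParameterError):
            generate_cohort(n_young=5, n_young_female=10)
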