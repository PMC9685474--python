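"""The synthetic-data generator and its closed-form ground truth."""

import numpy as np
import pandas as pd
import pytest

from heatattr import io as hio
from heatattr.simulate import (
    DEFAULT_SCENARIO_OFFSETS,
    GeneratorConfig,
    generate_counterfactual,
    generate_counts,
    generate_dataset,
    generate_scenarios,
    generate_weather,
    true_attributable_percent,
)


class TestGenerateWeather:
    def test_deterministic_under_seed(self):
        cfg = GeneratorConfig(seed=3)
        pd.testing.assert_frame_equal(generate_weather(cfg), generate_weather(cfg))

    def test_no_amplitude_no_noise_is_constant(self):
        cfg = GeneratorConfig(
            seed=0, years=(2011,), tmax_amplitude=0.0, innovation_sd=1e-12,
            dew_noise_sd=0.0,
        )
        w = generate_weather(cfg)
        np.testing.assert_allclose(w["tmax"], cfg.tmax_base, atol=1e-9)

    def test_temperature_ordering_invariant(self):
        w = generate_weather(GeneratorConfig(seed=4))
        assert (w["tmin"] <= w["tmean"]).all()
        assert (w["tmean"] <= w["tmax"]).all()
        assert (w["tdew"] <= w["tmax"]).all()

    def test_sample_moments_match_configuration(self):
        """Across 10 seasons, mean and sd of the AR(1) anomaly agree with
        the configured stationary values within Monte-Carlo error."""
        cfg = GeneratorConfig(seed=6, years=tuple(range(2006, 2016)))
        w = generate_weather(cfg)
        # reconstruct anomaly against the known seasonal mean curve
        anom = []
        for _, grp in w.groupby(w["date"].dt.year):
            n = len(grp)
            d = np.arange(n)
            curve = cfg.tmax_base + cfg.tmax_amplitude * np.sin(np.pi * (d + 0.5) / n)
            anom.append(grp["tmax"].to_numpy() - curve)
        anom = np.concatenate(anom)
        stat_sd = cfg.innovation_sd / np.sqrt(1 - cfg.ar_coef**2)
        se_mean = stat_sd / np.sqrt(len(anom) / 10)  # ~effective n under AR(1)
        assert abs(anom.mean()) < 3 * se_mean
        assert abs(anom.std() - stat_sd) < 0.15 * stat_sd

    def test_season_dates_are_may_through_september(self):
        w = generate_weather(GeneratorConfig(seed=1, years=(2012,)))
        assert w["date"].iloc[0] == pd.Timestamp("2012-05-01")
        assert w["date"].iloc[-1] == pd.Timestamp("2012-09-30")
        assert len(w) == 153


class TestCounterfactual:
    def test_zero_offset_is_identity(self):
        w = generate_weather(GeneratorConfig(seed=2))
        cf = generate_counterfactual(w, 0.0)
        np.testing.assert_array_equal(cf["tmax"], w["tmax"])

    def test_hot_day_count_never_increases(self):
        w = generate_weather(GeneratorConfig(seed=2))
        cf = generate_counterfactual(w, 1.0)
        assert (cf["tmax"] >= 30).sum() <= (w["tmax"] >= 30).sum()

    def test_default_config_hot_day_contrast_about_30_percent(self):
        """The study-condition default: factual hot-day frequency roughly
        30% above counterfactual."""
        cfg = GeneratorConfig()
        w = generate_weather(cfg)
        cf = generate_counterfactual(w, cfg.warming_offset)
        ratio = (w["tmax"] >= 30).mean() / (cf["tmax"] >= 30).mean()
        assert 1.15 < ratio < 1.55

    def test_negative_offset_rejected(self):
        w = generate_weather(GeneratorConfig(seed=2, years=(2011,)))
        with pytest.raises(ValueError):
            generate_counterfactual(w, -0.5)


class TestGenerateCounts:
    def test_deterministic_under_seed(self):
        cfg = GeneratorConfig(seed=5)
        w = generate_weather(cfg)
        pd.testing.assert_frame_equal(
            generate_counts(w, cfg), generate_counts(w, cfg)
        )

    def test_vanishing_rate_suppresses_everything(self):
        cfg = GeneratorConfig(seed=5, years=(2011,), rate_at_knee=1e-12)
        fac = generate_counts(generate_weather(cfg), cfg)
        assert fac["suppressed"].all()
        assert fac["hri_count"].isna().all()

    def test_empirical_mean_rate_matches_curve(self):
        """Monte-Carlo average of counts tracks the integrated risk curve."""
        cfg = GeneratorConfig(seed=8, dow_effects={})
        w = generate_weather(cfg)
        fac = generate_counts(w, cfg)
        lam = cfg.population / 1e5 * np.exp(cfg.log_rate_curve(w["tmax"].to_numpy()))
        total = lam.sum()
        assert abs(fac["hri_count_true"].sum() - total) < 4 * np.sqrt(total)

    def test_suppression_exactly_below_threshold(self):
        cfg = GeneratorConfig(seed=9, population=800_000)  # small counts
        fac = generate_counts(generate_weather(cfg), cfg)
        assert fac["suppressed"].any() and (~fac["suppressed"]).any()
        assert (fac.loc[fac["suppressed"], "hri_count_true"] < 5).all()
        assert (fac.loc[~fac["suppressed"], "hri_count_true"] >= 5).all()


class TestGroundTruth:
    def test_zero_offset_gives_zero_percent(self):
        assert true_attributable_percent(
            GeneratorConfig(seed=1, warming_offset=0.0)
        ) == pytest.approx(0.0)

    def test_linear_curve_closed_form(self):
        """With every day above the knee the percent is exactly
        100 (exp(slope * offset) - 1), independent of the weather draw."""
        cfg = GeneratorConfig(seed=13, curve_knee=-50.0, warming_offset=1.0)
        expected = 100 * (np.exp(cfg.curve_slope * 1.0) - 1)
        assert true_attributable_percent(cfg) == pytest.approx(expected, abs=1e-9)

    def test_default_config_near_fifteen_percent(self):
        """The default calibration echoes a 3-in-20 attributable share."""
        assert true_attributable_percent(GeneratorConfig()) == pytest.approx(15.0, abs=1.0)

    def test_pure_function_of_config(self):
        cfg = GeneratorConfig(seed=17)
        assert true_attributable_percent(cfg) == true_attributable_percent(cfg)


class TestScenarios:
    def test_zero_offsets_give_identical_series(self):
        w = generate_weather(GeneratorConfig(seed=2, years=(2011,)))
        offs = {k: 0.0 for k in DEFAULT_SCENARIO_OFFSETS}
        sc = generate_scenarios(w, offsets=offs, models={"m": 0.0})
        for _, grp in sc.groupby(["period", "scenario"]):
            np.testing.assert_array_equal(grp["tmax"].to_numpy(), w["tmax"].to_numpy())

    def test_incomplete_offset_table_rejected(self):
        w = generate_weather(GeneratorConfig(seed=2, years=(2011,)))
        with pytest.raises(ValueError, match="missing"):
            generate_scenarios(w, offsets={("mid", "high"): 1.0})

    def test_monotone_offsets_monotone_means(self, dataset):
        sc = dataset["scenarios"]
        means = sc.groupby(["period", "scenario"])["tmax"].mean()
        assert (
            means[("baseline", "high")]
            < means[("mid", "high")]
            < means[("late", "high")]
        )


def test_generated_artifacts_round_trip_through_io(tmp_path, dataset):
    """The bundle writes and reads back through the io layer faithfully."""
    p = tmp_path / "factual.csv"
    hio.write_daily_series(dataset["factual"], p)
    back = hio.read_daily_series(p)
    fac = dataset["factual"]
    assert len(back) == len(fac)
    assert back["suppressed"].tolist() == fac["suppressed"].tolist()
    np.testing.assert_allclose(back["tmax"], fac["tmax"], atol=1e-9)
    mask = ~fac["suppressed"]
    np.testing.assert_array_equal(
        back.loc[mask, "hri_count"], fac.loc[mask, "hri_count"]
    )
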