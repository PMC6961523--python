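import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shelfbed.constants import DAYS_PER_YEAR, MMOL_C_PER_G
from shelfbed.forcing import (
    ForcingConfig,
    ForcingConfigError,
    ForcingSeries,
    config_from_yaml,
    config_to_yaml,
    generate_forcing,
    generate_observation_fixtures,
    tidal_stress,
)


class TestGenerateForcing:
    def test_annual_integral_matches_configured_input(self, short_forcing):
        for y in range(2):
            total = short_forcing.detritus_C_flux[
                y * DAYS_PER_YEAR : (y + 1) * DAYS_PER_YEAR
            ].sum()
            assert total == pytest.approx(20.0, rel=1e-3)

    def test_zero_bloom_gives_zero_flux(self):
        cfg = ForcingConfig(years=1, bloom_scale=0.0, autumn_bloom_fraction=0.0)
        series = generate_forcing(cfg)
        assert np.all(series.detritus_C_flux == 0.0)

    def test_deterministic_given_config(self):
        cfg = ForcingConfig(years=2, seed=42)
        a = generate_forcing(cfg)
        b = generate_forcing(cfg)
        for name in ForcingSeries._COLUMNS:
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_redfield_stoichiometry_constant(self, short_forcing):
        mask = short_forcing.detritus_C_flux > 0
        flux_c_mmol = short_forcing.detritus_C_flux[mask] * MMOL_C_PER_G
        ratio_n = short_forcing.detritus_N_flux[mask] / flux_c_mmol
        np.testing.assert_allclose(ratio_n, 16.0 / 106.0, rtol=1e-12)
        ratio_p = short_forcing.detritus_P_flux[mask] / flux_c_mmol
        np.testing.assert_allclose(ratio_p, 1.0 / 106.0, rtol=1e-12)

    def test_everything_nonnegative_and_right_length(self, short_forcing):
        assert len(short_forcing) == 2 * DAYS_PER_YEAR
        for name in ForcingSeries._COLUMNS:
            if name == "bottom_temperature":
                continue
            assert np.all(getattr(short_forcing, name) >= 0.0), name

    def test_invalid_strat_window_rejected(self):
        with pytest.raises(ForcingConfigError):
            ForcingConfig(strat_onset_doy=300, remix_doy=100)

    def test_negative_input_rejected(self):
        with pytest.raises(ForcingConfigError):
            ForcingConfig(annual_benthic_C_input=-1.0)


class TestTidalStress:
    def test_zero_amplitudes_give_zero_stress(self):
        t = np.linspace(0.0, 30.0, 1000)
        tau = tidal_stress(0.0, 0.0, 0.03 / 7, t)
        assert np.all(tau == 0.0)

    def test_springneap_beat_period(self):
        # oracle: beat period = 1/(1/12 - 1/12.4206) hours = 14.765 days
        expected_days = (1.0 / (1.0 / 12.0 - 1.0 / 12.4206)) / 24.0
        t = np.arange(0.0, 120.0, 1.0 / 240.0)
        tau = tidal_stress(0.2, 0.07, 0.03 / 7, t)
        # envelope via daily maxima; parabolic interpolation through each
        # local maximum gives sub-day peak positions
        daily_max = tau.reshape(120, 240).max(axis=1)
        peaks = []
        for i in range(1, 119):
            if daily_max[i] >= daily_max[i - 1] and daily_max[i] >= daily_max[i + 1]:
                a, b, c = daily_max[i - 1], daily_max[i], daily_max[i + 1]
                denom = a - 2 * b + c
                shift = 0.5 * (a - c) / denom if denom != 0 else 0.0
                peaks.append(i + shift)
        spacings = np.diff(peaks)
        spacings = spacings[spacings > 5]  # discard adjacent-day plateaus
        assert np.mean(spacings) == pytest.approx(expected_days, abs=0.05)

    def test_quadratic_in_velocity(self):
        t = np.linspace(0.0, 5.0, 500)
        tau1 = tidal_stress(0.1, 0.03, 0.03 / 7, t)
        tau2 = tidal_stress(0.2, 0.06, 0.03 / 7, t)
        np.testing.assert_allclose(tau2, 4.0 * tau1, rtol=1e-12)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            tidal_stress(-0.1, 0.0, 0.03 / 7, np.arange(10.0))

    def test_envelope_contrast_grows_with_s2(self):
        t = np.arange(0.0, 30.0, 1.0 / 240.0)
        contrasts = []
        for s2 in (0.0, 0.02, 0.05):
            tau = tidal_stress(0.2, s2, 0.03 / 7, t)
            daily = tau.reshape(30, 240).max(axis=1)
            contrasts.append(daily.max() / daily.min())
        assert contrasts[0] < contrasts[1] < contrasts[2]


class TestObservationFixtures:
    def _truth(self):
        return pd.DataFrame(
            {
                "site": ["A", "A", "G"],
                "date": ["2015-03-01", "2015-08-01", "2015-03-01"],
                "quantity": ["TOU", "TOU", "D1"],
                "value": [3.0, 8.0, 0.05],
            }
        )

    def test_zero_noise_reproduces_truth(self):
        obs = generate_observation_fixtures(self._truth(), 0.0, 3, seed=1)
        merged = obs.merge(self._truth(), on=["site", "date", "quantity"])
        np.testing.assert_allclose(merged["value_x"], merged["value_y"])

    def test_replicate_count(self):
        obs = generate_observation_fixtures(self._truth(), 0.3, 3, seed=1)
        counts = obs.groupby(["site", "date", "quantity"]).size()
        assert (counts == 3).all()

    def test_replicate_mean_converges(self):
        # law of large numbers with the lognormal bias correction applied
        truth = pd.DataFrame(
            {"site": ["A"], "date": ["2015-01-01"], "quantity": ["TOU"], "value": [5.0]}
        )
        obs = generate_observation_fixtures(truth, 0.5, 1000, seed=7)
        assert obs["value"].mean() == pytest.approx(5.0, rel=0.05)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_observation_fixtures(self._truth(), -0.1, 3, seed=0)
        with pytest.raises(ValueError):
            generate_observation_fixtures(self._truth(), 0.1, 0, seed=0)


class TestSerialisation:
    def test_series_csv_roundtrip(self, tmp_path, short_forcing):
        path = tmp_path / "forcing.csv"
        short_forcing.to_csv(path)
        back = ForcingSeries.from_csv(path)
        for name in ForcingSeries._COLUMNS:
            np.testing.assert_allclose(
                getattr(back, name), getattr(short_forcing, name), rtol=1e-12
            )
        assert back.t_start == short_forcing.t_start

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = ForcingConfig(years=3, bloom_day=100, seed=9,
                            t_start=datetime.date(2014, 1, 1))
        path = tmp_path / "forcing.yml"
        config_to_yaml(cfg, path)
        assert config_from_yaml(path) == cfg

    def test_unknown_yaml_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yml"
        path.write_text("years: 2\nbloom_dayz: 100\n")
        with pytest.raises(ForcingConfigError, match="bloom_dayz"):
            config_from_yaml(path)


@settings(max_examples=25, deadline=None)
@given(
    annual=st.floats(min_value=1.0, max_value=100.0),
    autumn=st.floats(min_value=0.0, max_value=0.9),
)
def test_annual_conservation_property(annual, autumn):
    cfg = ForcingConfig(
        years=1, annual_benthic_C_input=annual, autumn_bloom_fraction=autumn
    )
    series = generate_forcing(cfg)
    assert series.detritus_C_flux.sum() == pytest.approx(annual, rel=1e-3)
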