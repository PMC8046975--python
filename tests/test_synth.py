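"""Generator contracts: determinism, coupling identities, injection rates,
snow clamping, moisture dynamics, and the NDVI curve."""

import numpy as np
import pandas as pd
import pytest

from microbuffer import synth
from microbuffer.stats import fit_line_ols
from microbuffer.synth import (
    SynthConfig,
    generate_campaign,
    generate_ndvi_series,
    ndvi_curve,
    site_south,
)


def quiet_site(**overrides):
    """A noise-free single site with flat hourly profile."""
    base = dict(ar1_sd=0.0, synoptic_sd=0.0, offset_random_sd_month=0.0,
                offset_random_sd_day=0.0, offset_random_sd_hour=0.0,
                hourly_slope_profile=tuple([1.0] * 24),
                gap_fraction=0.0, outlier_fraction=0.0, snow_windows={})
    base.update(overrides)
    return site_south(**base)


def air_pivot(records, site="S"):
    air = records[(records.site == site) & (records.variable == "air_T")]
    return air.pivot_table(index="timestamp", columns="position",
                           values="value")


class TestCouplingIdentities:
    def test_identity_coupling_reproduces_open_field(self):
        cfg = SynthConfig(sites=(quiet_site(coupling_intercept=0.0,
                                            coupling_slope=1.0),), seed=1)
        records, _ = generate_campaign(cfg)
        piv = air_pivot(records)
        assert np.allclose(piv["below_canopy"], piv["open_field"],
                           rtol=0, atol=0)

    def test_zero_noise_daily_ols_recovers_configured_line(self):
        # intercept 3.65 / slope 0.60 must come back to machine precision
        cfg = SynthConfig(sites=(quiet_site(coupling_intercept=3.65,
                                            coupling_slope=0.60),), seed=1)
        records, _ = generate_campaign(cfg)
        piv = air_pivot(records)
        daily = piv.resample("D").mean().dropna()
        fit = fit_line_ols(daily["open_field"], daily["below_canopy"])
        assert fit.intercept == pytest.approx(3.65, abs=1e-9)
        assert fit.slope == pytest.approx(0.60, abs=1e-12)

    def test_zero_noise_offset_matches_ground_truth_exactly(self):
        site = quiet_site(coupling_slope=0.8, coupling_intercept=2.0)
        cfg = SynthConfig(sites=(site,), seed=2)
        records, truth = generate_campaign(cfg)
        piv = air_pivot(records)
        gs = piv[piv.index.month.isin([5, 6, 7, 8, 9])]
        empirical = (gs["below_canopy"] - gs["open_field"]).mean()
        assert empirical == pytest.approx(
            truth.sites["S"].offset_mean["GS"], abs=1e-10)


class TestInjection:
    def test_gap_fraction_matches_binomial_rate(self):
        site = quiet_site(gap_fraction=0.05)
        cfg = SynthConfig(sites=(site,), seed=5)
        records, truth = generate_campaign(cfg)
        n = truth.n_grid
        for pos in ("below_canopy", "open_field"):
            missing = truth.n_gap_slots[("S", pos)] / n
            se = np.sqrt(0.05 * 0.95 / n)
            assert abs(missing - 0.05) < 4 * se

    def test_outlier_log_matches_records(self):
        site = quiet_site(outlier_fraction=0.01, ar1_sd=1.0)
        cfg = SynthConfig(sites=(site,), seed=6)
        records, truth = generate_campaign(cfg)
        log = truth.outlier_log
        assert len(log) > 50
        merged = log.merge(records, on=["timestamp", "site", "position",
                                        "variable"], how="left")
        assert np.allclose(merged["value_spiked"], merged["value"])

    def test_snow_clamp_bounds_soil_temperature(self):
        site = quiet_site(ar1_sd=1.0,
                          snow_windows={"open_field":
                                        (("2016-12-01", "2017-02-28"),)})
        cfg = SynthConfig(sites=(site,), seed=7)
        records, _ = generate_campaign(cfg)
        soil = records[(records.position == "open_field")
                       & (records.variable == "soil_T")].set_index(
                           "timestamp")["value"]
        window = soil[(soil.index >= "2016-12-01")
                      & (soil.index < "2017-03-01")]
        assert window.abs().max() <= synth.SNOW_CLAMP + 1e-12


class TestMoisture:
    def test_non_increasing_between_rain_events(self):
        site = quiet_site(rain_rate=0.0)
        cfg = SynthConfig(sites=(site,), seed=8)
        records, _ = generate_campaign(cfg)
        for pos in ("below_canopy", "open_field"):
            m = records[(records.position == pos)
                        & (records.variable == "soil_m")].set_index(
                            "timestamp")["value"]
            assert (m.diff().dropna() <= 1e-15).all()

    def test_bounds_and_interception(self):
        site = quiet_site(rain_rate=1.0, interception_fraction=0.5)
        cfg = SynthConfig(sites=(site,), seed=9)
        records, _ = generate_campaign(cfg)
        m = records[records.variable == "soil_m"]
        assert m["value"].between(0.0, 1.0).all()
        means = m.groupby("position")["value"].mean()
        # interception keeps the canopy soil drier on average
        assert means["below_canopy"] < means["open_field"]


class TestDeterminism:
    def test_identical_seed_identical_records(self):
        cfg = synth.paired_treeline_config(seed=3)
        rec_a, _ = generate_campaign(cfg)
        rec_b, _ = generate_campaign(cfg)
        pd.testing.assert_frame_equal(rec_a, rec_b)

    def test_different_seed_differs(self):
        rec_a, _ = generate_campaign(
            SynthConfig(sites=(site_south(),), seed=1))
        rec_b, _ = generate_campaign(
            SynthConfig(sites=(site_south(),), seed=2))
        assert not rec_a["value"].equals(rec_b["value"])


class TestValidation:
    def test_rejects_degenerate_date_range(self):
        with pytest.raises(ValueError, match="end must be after"):
            SynthConfig(sites=(site_south(),), start=pd.Timestamp("2017-01-01").date(),
                        end=pd.Timestamp("2016-01-01").date())

    def test_rejects_bad_step(self):
        with pytest.raises(ValueError, match="step"):
            SynthConfig(sites=(site_south(),), step_minutes=45)

    def test_rejects_overlapping_snow_windows(self):
        with pytest.raises(ValueError, match="overlapping"):
            site_south(snow_windows={"open_field":
                                     (("2017-01-01", "2017-02-01"),
                                      ("2017-01-20", "2017-03-01"))})

    def test_rejects_bad_slope_and_profile(self):
        with pytest.raises(ValueError):
            site_south(coupling_slope=1.5)
        with pytest.raises(ValueError):
            site_south(hourly_slope_profile=tuple([1.0] * 23))
        with pytest.raises(ValueError):
            site_south(hourly_slope_profile=tuple([1.0] * 23 + [-0.2]))


class TestNdvi:
    def test_half_amplitude_crossings_at_sos_eos(self):
        df = generate_ndvi_series(sos=120, eos=340, base=0.3, amplitude=0.4,
                                  noise_sd=0.0)
        dense = np.linspace(1, 366, 4000)
        curve = ndvi_curve(dense, 120, 340, 0.3, 0.4)
        half = 0.3 + 0.2
        up = dense[np.flatnonzero((curve[:-1] < half)
                                  & (curve[1:] >= half))[0]]
        down = dense[np.flatnonzero((curve[:-1] >= half)
                                    & (curve[1:] < half))[-1]]
        assert up == pytest.approx(120, abs=8)
        assert down == pytest.approx(340, abs=8)
        assert len(df) == 23

    def test_extrema_match_base_and_amplitude(self):
        dense = np.linspace(1, 366, 4000)
        curve = ndvi_curve(dense, 120, 340, base=0.3, amplitude=0.4)
        assert curve.max() == pytest.approx(0.7, abs=0.01)
        assert curve.min() == pytest.approx(0.3, abs=0.01)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            generate_ndvi_series(sos=120, eos=340, base=0.3, amplitude=0.0)
        with pytest.raises(ValueError):
            generate_ndvi_series(sos=300, eos=120, base=0.3, amplitude=0.4)
        with pytest.raises(ValueError):
            generate_ndvi_series(sos=120, eos=340, base=0.8, amplitude=0.4)


class TestCalibration:
    def test_truth_hits_requested_targets(self, default_campaign):
        _, _, truth = default_campaign
        assert truth.sites["S"].offset_mean["GS"] == pytest.approx(
            -2.41, abs=1e-6)
        assert truth.sites["NW"].offset_mean["GS"] == pytest.approx(
            -1.01, abs=1e-6)
        assert truth.sites["S"].daily_line[1] == pytest.approx(
            0.60, abs=1e-6)
        assert truth.sites["NW"].daily_line[1] == pytest.approx(
            0.76, abs=1e-6)
        assert truth.sites["S"].offset_daily_max["JJA"] == pytest.approx(
            -8.63, abs=2e-3)
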