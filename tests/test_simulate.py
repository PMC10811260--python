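"""Synthetic-trial generator: determinism, degenerate limits, fault injection."""

import numpy as np
import pandas as pd
import pytest

from cloverpheno.design import classify_maturity
from cloverpheno.simulate import (
    SimulationParams,
    VarComponents,
    WeatherParams,
    inject_faults,
    simulate_trial,
    simulate_weather,
)
from cloverpheno.timeline import YEAR1_TIMELINE

from conftest import small_params


class TestWeather:
    def test_zero_rain_probability(self):
        w = simulate_weather(params=WeatherParams(rain_prob=0.0), seed=1)
        assert (w["precipitation"] == 0).all()

    def test_fixed_seed_reproducible(self):
        pd.testing.assert_frame_equal(simulate_weather(seed=9), simulate_weather(seed=9))
        assert not simulate_weather(seed=9)["et0"].equals(simulate_weather(seed=10)["et0"])

    def test_et0_mean_matches_generator_target(self):
        """Monte-Carlo: sample ET0 mean within 3 SE of the stated seasonal mean."""
        params = WeatherParams()
        w = simulate_weather(params=params, n_days=365, seed=3)
        target = params.et0_mean(np.arange(1, 366)).mean()
        se = w["et0"].std(ddof=1) / np.sqrt(len(w))
        assert abs(w["et0"].mean() - target) < 3 * se

    def test_invariants(self):
        w = simulate_weather(seed=2)
        assert (w["precipitation"] >= 0).all()
        assert (w["et0"] >= 0).all()
        assert list(w["doy"]) == list(range(1, 366))


class TestSimulateTrial:
    def test_noiseless_degenerate_case(self, small_design):
        """All variances 0, no drought effect: every plot identical per variable/DOY."""
        params = small_params(
            variance_components={
                "CH": VarComponents(0.0, 0.0),
                "CC": VarComponents(0.0, 0.0),
            },
            obs_doys={"CH": (165, 256), "CC": (165,)},
            delta_max=0.0,
            gxe_sd=0.0,
            early_fraction=0.0,
        )
        trial = simulate_trial(small_design, params, YEAR1_TIMELINE)
        obs = trial.phenotypes
        for (var, doy, field), sub in obs[obs.variable != "FLD"].groupby(
            ["variable", "doy", "field"]
        ):
            assert sub["value"].nunique() == 1, (var, doy, field)

    def test_reproducible_for_fixed_seed(self, small_design):
        a = simulate_trial(small_design, small_params(seed=5), YEAR1_TIMELINE).phenotypes
        b = simulate_trial(small_design, small_params(seed=5), YEAR1_TIMELINE).phenotypes
        pd.testing.assert_frame_equal(a, b)

    def test_cc_bounded_and_values_finite(self, small_table):
        cc = small_table[small_table.variable == "CC"]["value"]
        assert cc.between(0, 100).all()
        assert np.isfinite(small_table["value"]).all()

    def test_drought_field_lower_for_growth_traits(self, small_design):
        """With δ>0 and no G×E, drought field means fall below control (20 seeds)."""
        diffs = []
        for seed in range(20):
            params = small_params(seed=seed, gxe_sd=0.0, obs_doys={"CH": (178,)})
            obs = simulate_trial(small_design, params, YEAR1_TIMELINE).phenotypes
            ch = obs[obs.variable == "CH"]
            diffs.append(
                ch[ch.field == "control"]["value"].mean()
                - ch[ch.field == "drought"]["value"].mean()
            )
        assert np.mean(diffs) > 0
        assert np.mean([d > 0 for d in diffs]) >= 0.9

    def test_maturity_recovered_from_fld(self, small_design):
        trial = simulate_trial(small_design, small_params(seed=8), YEAR1_TIMELINE)
        fld = trial.phenotypes[trial.phenotypes.variable == "FLD"]
        classified = classify_maturity(fld)
        truth = trial.truth.maturity
        agree = (classified["maturity"].reindex(truth.index) == truth).mean()
        assert agree > 0.95

    def test_flowering_boost_creates_bimodal_heights(self, small_design):
        """Early accessions sit ~boost higher than late ones inside flowering windows."""
        params = small_params(seed=4, early_fraction=0.5, flowering_ch_boost=15.0,
                              obs_doys={"CH": (165,)})
        trial = simulate_trial(small_design, params, YEAR1_TIMELINE)
        obs = trial.phenotypes
        ch = obs[(obs.variable == "CH") & (obs.field == "control")].set_index("accession_id")
        early = trial.truth.maturity == "early"
        gap = (
            ch.loc[early[early].index, "value"].mean()
            - ch.loc[early[~early].index, "value"].mean()
        )
        assert gap > 7.0  # boost dominates the genetic spread

    def test_truth_record_dimensions(self, small_trial, small_design):
        truth = small_trial.truth
        assert set(truth.genetic_effects.index) == set(small_design.accession_ids)
        assert len(truth.sensitivity) == len(small_design.accession_ids)
        assert ("control", "CH") in truth.spatial_effects

    def test_thermal_scenes_encode_drought_stress(self, small_trial):
        scenes = {(s.doy, i): s for i, s in enumerate(small_trial.thermal_scenes)}
        assert len(scenes) == 2  # one per field
        temps = [s.tc.mean() for s in small_trial.thermal_scenes]
        assert temps[1] > temps[0]  # drought canopy warmer than control


class TestInjectFaults:
    def test_rate_zero_is_identity(self, small_table):
        out = inject_faults(small_table, 0.0, seed=1)
        assert out is small_table

    def test_flag_count_binomial(self, small_table):
        rate = 0.05
        out = inject_faults(small_table, rate, seed=2)
        n = len(out)
        flagged = (out["flag"] != "ok").sum()
        # 4 sigma binomial band
        sd = np.sqrt(n * rate * (1 - rate))
        assert abs(flagged - n * rate) < 4 * sd

    def test_outlier_shift_is_local(self, small_table):
        out = inject_faults(small_table, 0.10, seed=3, outlier_offset=500.0)
        moved = out["value"] != small_table["value"]
        assert (out.loc[moved, "flag"] == "outlier").all()
        untouched = out.loc[~moved, "value"]
        assert (untouched == small_table.loc[~moved, "value"]).all()

    def test_bad_rate_rejected(self, small_table):
        with pytest.raises(ValueError):
            inject_faults(small_table, 1.0)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs", [dict(delta_max=1.2), dict(early_fraction=-0.1), dict(fault_rate=1.0), dict(gxe_sd=-1)]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationParams(**kwargs)

    def test_delta_profile(self):
        p = SimulationParams(delta_max=0.4, recovery_days=50)
        t = YEAR1_TIMELINE  # window 134..184
        assert p.delta(120, t) == 0.0
        assert p.delta(184, t) == pytest.approx(0.4)
        assert p.delta(159, t) == pytest.approx(0.2)
        assert p.delta(209, t) == pytest.approx(0.2)  # halfway through recovery
        assert p.delta(300, t) == 0.0

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            VarComponents(V_G=-1.0, V_R=1.0)
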