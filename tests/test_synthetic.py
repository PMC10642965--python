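"""Generator contracts: determinism, boundaries, structure, fixtures."""

import dataclasses

import numpy as np
import pytest

from somnoyoke import (BoutLengthDist, CircadianPropensity, ConfigurationError,
                       MaldiFixtureParams, PairedDesign, generate_cohort,
                       generate_peak_table, generate_trace, reference_params,
                       to_dam_counts)
from somnoyoke.scoring import detect_bouts, immobility_mask, sleep_time

EPD = 8640  # epochs per day


class TestGenerateTrace:
    def test_same_seed_bit_identical(self, ref_params):
        a = generate_trace(ref_params, 2, seed=7)
        b = generate_trace(ref_params, 2, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_different_seed_differs(self, ref_params):
        a = generate_trace(ref_params, 1, seed=7)
        b = generate_trace(ref_params, 1, seed=8)
        assert not np.array_equal(a.values, b.values)

    def test_length_is_whole_days(self, ref_params):
        for days in (1, 3):
            assert generate_trace(ref_params, days, seed=0).n_epochs == days * EPD

    def test_sleepless_limit(self, sleepless_params):
        """Zero sleep propensity: no epoch below 1 mm/s, total sleep zero."""
        tr = generate_trace(sleepless_params, 1, seed=3)
        assert np.all(tr.values > 1.0)
        bouts = detect_bouts(immobility_mask(tr))
        assert sleep_time(bouts, 300) == 0.0

    def test_speed_immobility_boundary(self, ref_params):
        """Rest speeds strictly below and active speeds strictly above 1 mm/s."""
        tr = generate_trace(ref_params, 2, seed=5)
        assert not np.any(tr.values == 1.0)
        assert np.any(tr.values < 1.0) and np.any(tr.values > 1.0)

    def test_invalid_distribution_raises(self):
        with pytest.raises(ConfigurationError):
            reference_params(homeostatic_gain=-1.0)
        with pytest.raises(ConfigurationError):
            from somnoyoke import RestSpeedDist
            reference_params(rest_speed_dist=RestSpeedDist(low=0.0, high=1.2))

    def test_n_days_must_be_positive(self, ref_params):
        with pytest.raises(ConfigurationError):
            generate_trace(ref_params, 0, seed=0)


class TestGenerateCohort:
    def test_counts_and_labels(self, ref_params):
        design = PairedDesign(pairs=(("f0", "y0"), ("f1", "y1")),
                              unperturbed_ids=("u0",))
        cohort = generate_cohort(design, ref_params, 1, seed=0)
        assert len(cohort) == 5
        assert cohort["f0"].condition == "focal"
        assert cohort["y1"].condition == "yoked"
        assert cohort["u0"].condition == "unperturbed"
        assert all(t.n_epochs == EPD for t in cohort.values())

    def test_per_id_substreams_order_invariant(self, ref_params):
        d1 = PairedDesign(pairs=(("a", "b"),), unperturbed_ids=("c",))
        d2 = PairedDesign(pairs=(("c", "a"),), unperturbed_ids=("b",))
        c1 = generate_cohort(d1, ref_params, 1, seed=9)
        c2 = generate_cohort(d2, ref_params, 1, seed=9)
        for fid in "abc":
            np.testing.assert_array_equal(c1[fid].values, c2[fid].values)

    def test_duplicate_ids_rejected(self):
        from somnoyoke import DesignError
        with pytest.raises(DesignError):
            PairedDesign(pairs=(("a", "b"),), unperturbed_ids=("a",))
        with pytest.raises(DesignError):
            PairedDesign(pairs=(("a", "a"),))


class TestCircadianStructure:
    def test_propensity_bimodal_and_night_dominant(self, ref_params):
        c = ref_params.circadian_propensity
        zt = np.linspace(0, 24, 1441)[:-1]
        v = c.at(zt)
        siesta = v[(zt > 4) & (zt < 8)].max()
        night = v[(zt > 16) & (zt < 20)].max()
        trough = v[(zt > 10.5) & (zt < 11.5)].max()
        assert trough < siesta < night
        assert night / siesta > 1.3

    def test_night_day_long_bout_ratio_near_two(self, ref_params):
        """Long-bout (>=25 min) sleep at night is roughly twice the daytime
        amount for unperturbed flies under the frozen reference parameters."""
        day = night = 0.0
        n_flies, days = 12, 3
        for i in range(n_flies):
            tr = generate_trace(ref_params, days, seed=1, fly_id=f"r{i:02d}")
            bouts = detect_bouts(immobility_mask(tr))
            for k in range(days):
                day += sleep_time(bouts, 1500, (k * EPD, k * EPD + EPD // 2))
                night += sleep_time(bouts, 1500, (k * EPD + EPD // 2, (k + 1) * EPD))
        assert 1.5 <= night / day <= 2.5


class TestHomeostaticStructure:
    def test_deprived_fly_outsleeps_twin_in_long_bouts(self, ref_params):
        """24 h of enforced waking is followed by more sleep over the next
        three days than the same-seed undisturbed twin shows, with the
        surplus concentrated in >= 25 min bouts."""
        from somnoyoke import EngineConfig, run_inactivity_triggered
        design = PairedDesign(pairs=(("f0", "y0"),))
        cfg = EngineConfig(mode="inactivity_triggered", trigger_threshold_s=220,
                           window_start_h=24.0, window_h=24.0)
        traces, _ = run_inactivity_triggered(design, ref_params, cfg, 5, seed=42)
        twin = generate_trace(ref_params, 5, seed=42, fly_id="f0")
        post = (2 * EPD, 5 * EPD)
        bd = detect_bouts(immobility_mask(traces["f0"]))
        bt = detect_bouts(immobility_mask(twin))
        std_surplus = sleep_time(bd, 300, post) - sleep_time(bt, 300, post)
        lb_surplus = sleep_time(bd, 1500, post) - sleep_time(bt, 1500, post)
        assert std_surplus > 0
        assert lb_surplus > 0
        # surplus concentrated in long bouts: they account for more than all
        # of the standard-criterion surplus (short-bout sleep may shrink)
        assert lb_surplus >= 0.5 * std_surplus


class TestHyperactivityStructure:
    def test_speed_elevation_after_stimulation(self, ref_params):
        """Stimulation without arousal (so no sleep is lost) elevates mean
        speed over the following 24 h, and the elevation around the
        light-to-dark transition exceeds the late-night elevation."""
        from somnoyoke import EngineConfig, run_fixed_interval
        p = dataclasses.replace(ref_params, arousal_prob=0.0)
        cfg = EngineConfig(mode="fixed_interval", interval_s=220,
                          window_start_h=24.0, window_h=24.0)
        ids = [f"s{i}" for i in range(6)]
        traces, _ = run_fixed_interval(ids, p, cfg, 3, seed=4)
        diffs, transition, late_night = [], [], []
        for fid in ids:
            twin = generate_trace(p, 3, seed=4, fly_id=fid)
            d = traces[fid].values[2 * EPD:3 * EPD] - twin.values[2 * EPD:3 * EPD]
            diffs.append(d.mean())
            transition.append(d[12 * 360:18 * 360].mean())
            late_night.append(d[18 * 360:].mean())
        assert np.mean(diffs) > 0
        assert np.mean(transition) > np.mean(late_night)


class TestToDamCounts:
    def test_all_immobile_all_zero(self, immobile_params):
        tr = generate_trace(immobile_params, 1, seed=0)
        tr.values[:] = 0.2
        assert np.all(to_dam_counts(tr, 60) == 0)

    def test_single_active_epoch_single_bin(self, ref_params):
        tr = generate_trace(ref_params, 1, seed=0)
        tr.values[:] = 0.0
        tr.values[1234] = 5.0
        counts = to_dam_counts(tr, 60, deterministic=True)
        assert np.count_nonzero(counts) == 1
        assert counts[1234 // 6] > 0

    def test_poisson_mean_tracks_rate(self, ref_params):
        """Empirical mean over ~10^4 bins matches rate_per_speed x speed."""
        tr = generate_trace(ref_params, 2, seed=0)
        speed = 3.0
        tr.values[:] = speed
        counts = to_dam_counts(tr, 20, seed=1, rate_per_speed=0.6)
        assert counts.size == 8640
        assert np.mean(counts) == pytest.approx(0.6 * speed, rel=0.05)

    def test_bin_not_multiple_of_epoch_raises(self, ref_params):
        tr = generate_trace(ref_params, 1, seed=0)
        with pytest.raises(ConfigurationError):
            to_dam_counts(tr, 15)


class TestMaldiFixture:
    def test_planted_ordering_by_construction(self):
        fix = MaldiFixtureParams(
            n_peaks_per_category={"sleep_pressure": 5, "mechanical": 5,
                                  "sleep_absence": 5},
            noise_log_sd=0.01, effect_size=4.0, seed=1)
        table, truth = generate_peak_table(fix)
        for k, cat in enumerate(truth):
            f = np.median(table.condition_columns("focal")[k])
            y = np.median(table.condition_columns("yoked")[k])
            u = np.median(table.condition_columns("unperturbed")[k])
            if cat == "sleep_pressure":
                assert u < y < f
            elif cat == "mechanical":
                assert u < y and u < f and abs(np.log(f / y)) < 0.2
            elif cat == "sleep_absence":
                assert f > y and f > u and abs(np.log(y / u)) < 0.2

    def test_null_effect_collapses_to_ns_with_warning(self):
        fix = MaldiFixtureParams(
            n_peaks_per_category={"sleep_pressure": 3, "NS": 3},
            effect_size=1.0, seed=0)
        with pytest.warns(UserWarning, match="collapse"):
            _, truth = generate_peak_table(fix)
        assert set(truth) == {"NS"}

    def test_negative_effect_rejected(self):
        with pytest.raises(ConfigurationError):
            MaldiFixtureParams(effect_size=-1.0).validate()

    def test_intensities_positive_and_labeled(self):
        fix = MaldiFixtureParams(seed=5)
        table, truth = generate_peak_table(fix)
        assert len(truth) == table.n_peaks == sum(
            fix.n_peaks_per_category.values())
        assert np.all(table.intensities > 0)
        assert table.n_sections("focal") == 6
        assert table.n_sections("yoked") == 3
        assert table.n_sections("unperturbed") == 4
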