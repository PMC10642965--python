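"""Sleep scoring: thresholds, bouts, sleep quantities, P(doze), DAM files."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnoyoke import (Bout, ConfigurationError, DataError, ScoringConfig,
                       dam_sleep, detect_bouts, generate_trace,
                       immobility_mask, p_doze, p_wake, read_dam_monitor,
                       short_sleep_time, sleep_time, summarize,
                       to_dam_counts, write_dam_monitor)
from somnoyoke.scoring import dam_monitor_from_counts


def bouts_from(spec, epoch_s=10):
    """Helper: build bouts from (start, end) epoch pairs."""
    return [Bout(s, e, epoch_s) for s, e in spec]


class TestImmobilityMask:
    def test_strict_one_mm_s_boundary(self):
        mask = immobility_mask(np.array([0.0, 0.99, 1.0, 2.0]))
        np.testing.assert_array_equal(mask, [True, True, False, False])

    def test_all_zero_all_immobile(self):
        assert immobility_mask(np.zeros(100)).all()

    def test_matches_elementwise_oracle(self, rng):
        v = rng.uniform(0, 3, 5000)
        np.testing.assert_array_equal(immobility_mask(v),
                                      np.array([x < 1.0 for x in v]))


class TestDetectBouts:
    def test_single_thirty_epoch_run_is_300s(self):
        mask = np.zeros(100, dtype=bool)
        mask[10:40] = True
        (bout,) = detect_bouts(mask)
        assert (bout.start_epoch, bout.end_epoch) == (10, 40)
        assert bout.duration_s == 300

    def test_fully_mobile_no_bouts(self):
        assert detect_bouts(np.zeros(50, dtype=bool)) == []

    def test_empty_mask_rejected(self):
        with pytest.raises(DataError):
            detect_bouts(np.array([], dtype=bool))

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=300))
    def test_matches_rle_oracle(self, bits):
        """Run-length-encoding oracle: walk the mask, collect maximal runs."""
        mask = np.array(bits, dtype=bool)
        expected, start = [], None
        for i, b in enumerate(bits):
            if b and start is None:
                start = i
            if not b and start is not None:
                expected.append((start, i))
                start = None
        if start is not None:
            expected.append((start, len(bits)))
        got = [(b.start_epoch, b.end_epoch) for b in detect_bouts(mask)]
        assert got == expected

    def test_reconstructs_mask(self, rng):
        mask = rng.random(2000) < 0.6
        rebuilt = np.zeros_like(mask)
        for b in detect_bouts(mask):
            rebuilt[b.start_epoch:b.end_epoch] = True
        np.testing.assert_array_equal(rebuilt, mask)


class TestSleepTime:
    def test_300s_bout_at_standard_criterion_is_five_minutes(self):
        assert sleep_time(bouts_from([(0, 30)]), 300) == 5.0

    def test_290s_bout_excluded(self):
        assert sleep_time(bouts_from([(0, 29)]), 300) == 0.0

    def test_criterion_monotonicity_and_filter_oracle(self, rng):
        for _ in range(50):
            n = rng.integers(1, 20)
            starts = np.cumsum(rng.integers(1, 50, n))
            lengths = rng.integers(1, 200, n)
            bouts = bouts_from([(int(s), int(s + l))
                                for s, l in zip(starts + np.arange(n) * 250, lengths)])
            prev = np.inf
            for k in range(60, 1800 + 1, 60):
                got = sleep_time(bouts, k)
                oracle = sum(b.duration_s for b in bouts if b.duration_s >= k) / 60
                assert got == pytest.approx(oracle)
                assert got <= prev
                prev = got

    def test_criterion_must_be_epoch_multiple(self):
        with pytest.raises(ConfigurationError):
            sleep_time(bouts_from([(0, 30)]), 305)
        with pytest.raises(ConfigurationError):
            sleep_time([], 305)

    def test_window_split_and_retest(self):
        """A bout spanning a window boundary is clipped and each fragment is
        re-tested against the criterion in its own window."""
        bouts = bouts_from([(80, 140)])  # 600 s, spanning epoch 100
        left = sleep_time(bouts, 300, window=(0, 100))    # 200 s fragment
        right = sleep_time(bouts, 300, window=(100, 200))  # 400 s fragment
        assert left == 0.0
        assert right == pytest.approx(400 / 60)

    def test_day_totals_additive_under_splitting(self, ref_params):
        tr = generate_trace(ref_params, 3, seed=12)
        bouts = detect_bouts(immobility_mask(tr))
        whole = sleep_time(bouts, 300, (0, 3 * 8640))
        per_day = sum(sleep_time(bouts, 300, (d * 8640, (d + 1) * 8640))
                      for d in range(3))
        # day totals can only drop fragments at boundaries, never add
        assert per_day <= whole
        assert whole - per_day < 3 * 10  # at most two sub-5-min fragments/boundary


class TestShortSleep:
    def test_band_edges(self):
        bouts = bouts_from([(0, 6), (100, 129), (200, 230)])  # 60, 290, 300 s
        assert short_sleep_time(bouts) == pytest.approx((60 + 290) / 60)

    def test_empty_band(self):
        assert short_sleep_time(bouts_from([(0, 3), (100, 160)])) == 0.0

    def test_random_vs_filter_oracle(self, rng):
        for _ in range(20):
            lengths = rng.integers(1, 60, 15)
            starts = np.cumsum(lengths + rng.integers(1, 20, 15))
            bouts = bouts_from([(int(s), int(s + l))
                                for s, l in zip(starts, lengths)])
            oracle = sum(b.duration_s for b in bouts
                         if 60 <= b.duration_s < 300) / 60
            assert short_sleep_time(bouts) == pytest.approx(oracle)


class TestConditionalProbabilities:
    def test_alternating_bins_full_doze(self):
        # epochs alternate activity at the 60-s bin scale
        mask = np.tile([False] * 6 + [True] * 6, 20)  # active, inactive, ...
        assert p_doze(mask, bin_s=60) == 1.0
        assert p_wake(mask, bin_s=60) == 1.0

    def test_all_active_doze_zero_wake_undefined(self):
        mask = np.zeros(600, dtype=bool)  # never immobile
        assert p_doze(mask, bin_s=60) == 0.0
        assert p_wake(mask, bin_s=60) is None

    def test_all_inactive_doze_undefined(self):
        mask = np.ones(600, dtype=bool)
        assert p_doze(mask, bin_s=60) is None
        assert p_wake(mask, bin_s=60) == 0.0

    def test_transition_counting_oracle(self, rng):
        for _ in range(30):
            mask = rng.random(1200) < 0.5
            active = ~mask.reshape(-1, 6).all(axis=1)
            a2i = sum(1 for i in range(len(active) - 1)
                      if active[i] and not active[i + 1])
            denom = sum(1 for i in range(len(active) - 1) if active[i])
            expected = a2i / denom if denom else None
            assert p_doze(mask, bin_s=60) == (pytest.approx(expected)
                                              if expected is not None else None)


class TestPartition:
    def test_immobile_plus_mobile_covers_window(self, ref_params):
        tr = generate_trace(ref_params, 2, seed=3)
        mask = immobility_mask(tr)
        assert mask.sum() + (~mask).sum() == tr.n_epochs

    def test_summary_fields(self, ref_params):
        tr = generate_trace(ref_params, 2, seed=3)
        s = summarize(tr, ScoringConfig(), window=(0, 8640))
        assert 0 <= s.total_sleep_min <= 1440
        assert s.bout_count >= 0
        assert s.p_doze is None or 0 <= s.p_doze <= 1
        assert s.p_wake is None or 0 <= s.p_wake <= 1


class TestDamSleep:
    def test_fifteen_zero_bins_make_standard_sleep(self):
        counts = np.ones(100, dtype=int)
        counts[10:25] = 0  # 15 x 20 s = 300 s
        bouts = dam_sleep(counts, bin_s=20)
        assert len(bouts) == 1 and bouts[0].duration_s == 300
        assert sleep_time(bouts, 300, epoch_length_s=20) == 5.0

    def test_single_crossing_splits_run(self):
        counts = np.zeros(30, dtype=int)
        counts[15] = 2
        assert len(dam_sleep(counts, bin_s=20)) == 2

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            dam_sleep(np.array([1, -1, 0]), bin_s=20)

    def test_cross_modality_consistency(self, ref_params):
        """Noise-free DAM conversion of a velocity trace yields the same
        standard sleep as the velocity path whenever bouts are bin-aligned."""
        tr = generate_trace(ref_params, 1, seed=9)
        # force bin alignment: make immobility constant within each 20-s bin
        v = tr.values.reshape(-1, 2)
        v[:, 1] = v[:, 0]
        counts = to_dam_counts(tr, 20, deterministic=True)
        dam_bouts = dam_sleep(counts, bin_s=20)
        vel_bouts = detect_bouts(immobility_mask(tr))
        assert sleep_time(dam_bouts, 300, epoch_length_s=20) == pytest.approx(
            sleep_time(vel_bouts, 300))


class TestDamMonitorIO:
    def test_round_trip(self, tmp_path, rng):
        counts = rng.integers(0, 30, size=(3, 12))
        mon = dam_monitor_from_counts(counts, bin_s=20)
        path = tmp_path / "Monitor1.txt"
        write_dam_monitor(mon, path)
        back = read_dam_monitor(path)
        assert back.counts.shape == (12, 32)
        np.testing.assert_array_equal(back.counts[:, :3], counts.T)
        assert back.flagged_rows == []
        # second round trip is byte-identical
        path2 = tmp_path / "Monitor2.txt"
        write_dam_monitor(back, path2)
        assert path.read_text() == path2.read_text()

    def test_wrong_column_count_names_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        good = "\t".join(["1", "1 Jan 24", "00:00:00", "1"] + ["0"] * 6
                         + ["0"] * 32)
        path.write_text(good + "\n" + "1\t2\t3\n")
        with pytest.raises(DataError, match="line 2"):
            read_dam_monitor(path)

    def test_invalid_status_flagged(self, tmp_path):
        mon = dam_monitor_from_counts(np.ones((1, 3), dtype=int), bin_s=60)
        mon.status[1] = 51
        path = tmp_path / "m.txt"
        write_dam_monitor(mon, path)
        back = read_dam_monitor(path)
        assert back.flagged_rows == [(2, "status 51")]
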