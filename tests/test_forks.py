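"""Origin-activity filtering, probe geometry, peak logic and group statistics."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

import traelkit as tk
from traelkit.forks import ForkParams, find_signal_peaks
from conftest import ends_frame, make_probe


def catalogue(rows):
    return pd.DataFrame(rows, columns=["origin_id", "chrom", "pos"])


class TestCallActiveOrigins:
    def make_scored(self, scores, spacing=20_000):
        """One origin per score, reads of that multiplicity at the origin."""
        cat = catalogue(
            [(f"o{i}", "chr1", 10_000 + i * spacing) for i in range(len(scores))]
        )
        ends = ends_frame(
            [("chr1", 10_000 + i * spacing, "+", s) for i, s in enumerate(scores) if s > 0]
        )
        return ends, cat

    def test_bottom_40_percent_removed(self):
        ends, cat = self.make_scored(list(range(1, 101)))
        active = tk.call_active_origins(ends, cat)
        assert len(active) == 60
        assert sorted(active["activity_score"]) == list(range(41, 101))

    def test_fraction_zero_keeps_all(self):
        ends, cat = self.make_scored([5, 1, 9])
        active = tk.call_active_origins(ends, cat, ForkParams(activity_fraction=0.0))
        assert len(active) == 3

    def test_five_origins_ranking(self):
        ends, cat = self.make_scored([10, 20, 30, 40, 50])
        active = tk.call_active_origins(ends, cat)
        assert sorted(active["activity_score"]) == [30, 40, 50]

    def test_retained_count_is_ceiling_for_any_n(self):
        import math

        for n in (1, 2, 3, 7, 11, 50):
            ends, cat = self.make_scored(list(range(1, n + 1)))
            active = tk.call_active_origins(ends, cat)
            assert len(active) == math.ceil(0.6 * n)

    def test_boundary_ties_keep_earlier_coordinate(self):
        # cut falls inside the tied block of 6s: earlier coordinates win
        ends, cat = self.make_scored([9, 6, 6, 6, 2])
        active = tk.call_active_origins(ends, cat)
        assert len(active) == 3
        # retained: the 9 plus the two earliest-coordinate 6s
        assert active["activity_score"].tolist() == [9, 6, 6]
        assert active["pos"].is_monotonic_increasing

    def test_empty_catalogue_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tk.call_active_origins(ends_frame([]), catalogue([]))

    def test_all_equal_scores_warns(self, caplog):
        ends, cat = self.make_scored([4, 4, 4, 4])
        with caplog.at_level(logging.WARNING):
            active = tk.call_active_origins(ends, cat)
        assert len(active) == 3
        assert any("equal" in r.message for r in caplog.records)

    def test_windowed_signal_source(self, desk_layout):
        ends, cat = self.make_scored([10, 20, 30])
        ws = tk.windowed_signal(ends, tk.GenomeLayout({"chr1": 100_000}), 1000, 1000)
        active = tk.call_active_origins(ws, cat)
        assert sorted(active["activity_score"]) == [20, 30]


class TestBuildProbes:
    layout = tk.GenomeLayout({"chrA": 200_000})
    active = catalogue([("ori1", "chrA", 100_000)])

    def test_upstream_axis_is_reflected(self):
        ends = ends_frame([("chrA", 88_000, "+", 5)])
        up, down = self._probes(ends)
        assert up.raw[120] == 5 and up.raw.sum() == 5
        assert down.raw.sum() == 0

    def test_no_reads_gives_zero_probes_and_undefined_distance(self):
        up, down = self._probes(ends_frame([]))
        assert up.raw.sum() == 0 and down.raw.sum() == 0
        smoothed = tk.detect_peaks(tk.smooth_probe(up))
        assert tk.fork_distance(smoothed) is None

    def test_mirror_symmetry(self):
        ends = ends_frame([("chrA", 95_000, "-", 3), ("chrA", 105_000, "+", 3)])
        up, down = self._probes(ends)
        np.testing.assert_array_equal(up.raw, down.raw)

    def test_probe_past_chromosome_end_is_truncated_and_excluded(self, caplog):
        active = catalogue([("edge", "chrA", 10_000)])
        with caplog.at_level(logging.WARNING):
            probes = tk.build_probes(ends_frame([("chrA", 5_000, "-", 2)]), active, self.layout)
        up = next(p for p in probes if p.side == "upstream")
        assert up.truncated
        assert tk.fork_distance(tk.detect_peaks(tk.smooth_probe(up))) is None

    def test_leading_strand_mode_splits_by_strand(self):
        ends = ends_frame([("chrA", 95_000, "+", 4), ("chrA", 105_000, "+", 4)])
        params = ForkParams(strand_mode="leading")
        up, down = self._probes(ends, params)
        assert up.raw.sum() == 0  # upstream probe only accepts reverse reads
        assert down.raw.sum() == 4

    def _probes(self, ends, params=ForkParams()):
        probes = tk.build_probes(ends, self.active, self.layout, params)
        up = next(p for p in probes if p.side == "upstream")
        down = next(p for p in probes if p.side == "downstream")
        return up, down


class TestPeakDetection:
    def test_all_zero_probe_has_no_peaks_and_is_retained(self):
        probe = tk.detect_peaks(tk.smooth_probe(make_probe(np.zeros(200))))
        assert probe.peaks == [] and probe.retained

    def test_single_gaussian_bump_single_peak_at_mode(self):
        x = np.arange(200)
        probe = make_probe(100 * np.exp(-((x - 80) ** 2) / (2 * 15**2)))
        probe = tk.detect_peaks(tk.smooth_probe(probe))
        assert len(probe.peaks) == 1 and probe.retained
        assert abs(probe.peaks[0][0] - 8_000) <= 100

    def test_two_equal_bumps_remove_probe(self):
        x = np.arange(200)
        y = 50 * np.exp(-((x - 50) ** 2) / 50) + 50 * np.exp(-((x - 150) ** 2) / 50)
        probe = tk.detect_peaks(tk.smooth_probe(make_probe(y)))
        assert len(probe.peaks) == 2
        assert not probe.retained

    def test_unsmoothed_probe_rejected(self):
        with pytest.raises(ValueError, match="smoothed"):
            tk.detect_peaks(make_probe(np.zeros(200)))

    @staticmethod
    def brute_force_peaks(y, prominence_fraction, min_sep):
        """Independent peak oracle: exhaustive scan + walk-out prominence."""
        y = np.asarray(y, dtype=float)
        if len(y) == 0 or max(y) <= 0:
            return []
        maxima = [i for i in range(1, len(y) - 1) if y[i] > y[i - 1] and y[i] > y[i + 1]]
        cands = []
        for i in maxima:
            lmin = y[i]
            for v in y[:i][::-1]:
                if v > y[i]:
                    break
                lmin = min(lmin, v)
            rmin = y[i]
            for v in y[i + 1 :]:
                if v > y[i]:
                    break
                rmin = min(rmin, v)
            prom = y[i] - max(lmin, rmin)
            if prom >= prominence_fraction * max(y):
                cands.append(i)
        chosen = []
        for i in sorted(cands, key=lambda i: (-y[i], i)):
            if all(abs(i - j) >= min_sep for j in chosen):
                chosen.append(i)
        return sorted(chosen)

    @given(
        y=st.lists(st.floats(0, 100, allow_nan=False), min_size=3, max_size=50),
        frac=st.sampled_from([0.2, 0.5, 0.8]),
        sep=st.integers(1, 8),
    )
    @settings(max_examples=120, deadline=None)
    def test_detector_matches_exhaustive_oracle(self, y, frac, sep):
        assume(all(a != b for a, b in zip(y, y[1:])))  # no plateaus
        got = [i for i, _, _ in find_signal_peaks(np.array(y), frac, sep)]
        assert got == self.brute_force_peaks(y, frac, sep)


class TestForkDistance:
    def test_all_mass_at_origin_bin_gives_zero(self):
        raw = np.zeros(200)
        raw[0] = 100
        probe = tk.detect_peaks(tk.smooth_probe(make_probe(raw)))
        assert tk.fork_distance(probe) == 0.0

    def test_planted_fork_recovered_within_one_bin(self):
        layout = tk.GenomeLayout({"chrA": 200_000})
        params = tk.ForkSimParams(
            origins={"chrA": (100_000,)}, firing_probability=1.0,
            distance_mean=12_000, distance_spread=0, read_noise=0,
            background_rate=0, duplicate_rate=0, seed=3,
        )
        ends, truth = tk.simulate_trael_experiment(layout, params)
        active = catalogue([("o", "chrA", 100_000)])
        _, table = tk.analyze_probes(ends, active, layout)
        for d in table["fork_distance"]:
            assert abs(d - 12_000) <= 100

    def test_non_retained_probe_has_undefined_distance(self):
        x = np.arange(200)
        y = 50 * np.exp(-((x - 50) ** 2) / 50) + 50 * np.exp(-((x - 150) ** 2) / 50)
        probe = tk.detect_peaks(tk.smooth_probe(make_probe(y)))
        assert tk.fork_distance(probe) is None


class TestCountFiredOrigins:
    def test_three_origins_sixty_kb_apart(self):
        layout = tk.GenomeLayout({"chrA": 300_000})
        params = tk.ForkSimParams(
            origins={"chrA": (90_000, 150_000, 210_000)}, firing_probability=1.0,
            distance_mean=10_000, distance_spread=500, read_noise=300,
            background_rate=0.1, seed=5,
        )
        ends, truth = tk.simulate_trael_experiment(layout, params)
        assert tk.genome_peak_count(ends, layout) == 6
        assert tk.count_fired_origins(ends, layout) == 3

    def test_no_reads_counts_zero(self, desk_layout):
        assert tk.count_fired_origins(ends_frame([]), desk_layout) == 0

    def test_matches_simulator_truth_across_seeds(self):
        layout = tk.uniform_layout(2, 700_000)
        origins = tk.evenly_spaced_origins(layout, 10, margin=50_000)
        for seed in range(10):
            params = tk.ForkSimParams(
                origins=origins, firing_probability=1.0, distance_mean=10_000,
                distance_spread=500, read_noise=300, seed=seed,
            )
            ends, truth = tk.simulate_trael_experiment(layout, params)
            assert tk.count_fired_origins(ends, layout) == len(truth.fired)


class TestMedianRecovery:
    def test_planted_distance_recovered_within_half_kb(self):
        layout = tk.uniform_layout(3, 700_000)
        origins = tk.evenly_spaced_origins(layout, 10, margin=50_000)
        params = tk.ForkSimParams(
            origins=origins, firing_probability=1.0, distance_mean=12_000,
            distance_spread=1_000, read_noise=300, seed=42,
        )
        ends, truth = tk.simulate_trael_experiment(layout, params)
        cat = tk.origin_catalogue(params)
        active = tk.call_active_origins(ends, cat, ForkParams(activity_fraction=0.0))
        _, table = tk.analyze_probes(ends, active, layout)
        summary = tk.ConditionSummary.from_probe_table(table, "wt", "1")
        assert len(summary.distances) >= 50
        truth_median = np.median(
            np.concatenate([truth.fired["left_distance"], truth.fired["right_distance"]])
        )
        assert abs(summary.median_distance - truth_median) <= 500


def medians_summary(condition, replicate, values):
    return tk.ConditionSummary(condition, replicate, np.asarray(values, dtype=float))


class TestCompareConditions:
    def make_groups(self, g, reps=3, seed=0):
        rng = np.random.default_rng(seed)
        return [
            medians_summary(f"g{i}", str(r), rng.normal(10_000, 500, 40))
            for i in range(g)
            for r in range(reps)
        ]

    @pytest.mark.parametrize("g,expected_pairs", [(2, 1), (3, 3), (6, 15)])
    def test_all_pairs_comparison_count(self, g, expected_pairs):
        result = tk.compare_conditions(self.make_groups(g))
        assert len(result.pairwise) == expected_pairs

    def test_single_replicate_group_excluded_from_pairwise(self, caplog):
        groups = self.make_groups(3)
        groups.append(medians_summary("lonely", "1", [9_000.0] * 10))
        with caplog.at_level(logging.WARNING):
            result = tk.compare_conditions(groups)
        assert len(result.pairwise) == 3  # only the 3 full groups pair up
        assert any("single-replicate" in r.message for r in caplog.records)

    @pytest.mark.parametrize("method", ["sidak", "bonferroni"])
    def test_alternative_corrections(self, method):
        result = tk.compare_conditions(self.make_groups(3), method=method)
        assert len(result.pairwise) == 3
        assert result.method == method

    def test_clear_separation_is_detected(self):
        rng = np.random.default_rng(1)
        groups = [
            medians_summary("near", str(r), rng.normal(5_000, 200, 40)) for r in range(4)
        ] + [
            medians_summary("far", str(r), rng.normal(12_000, 200, 40)) for r in range(4)
        ]
        result = tk.compare_conditions(groups)
        assert result.p_value < 1e-4
        assert bool(result.pairwise.iloc[0]["reject"])

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError, match="two condition groups"):
            tk.compare_conditions(self.make_groups(1))
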