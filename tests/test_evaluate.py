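"""Metrics, ROC, per-FOV aggregation, motility and onset analyses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import catrace.evaluate as ev
from catrace.preprocess import BaselineFit
from catrace.synthetic import CellTrack


def _arrays(n, called, reactive, specific):
    z = np.zeros(n, dtype=bool)
    c, r, s = z.copy(), z.copy(), z.copy()
    c[list(called)] = True
    r[list(reactive)] = True
    s[list(specific)] = True
    return c, r, s


class TestEfficiencies:
    def test_model_efficiency_hand_count(self):
        # 50 reactive-labelled specific cells, 47 of them called
        c, r, s = _arrays(60, range(47), range(50), range(55))
        assert ev.model_efficiency(c, r, s) == pytest.approx(0.94)

    def test_model_efficiency_perfect(self):
        c, r, s = _arrays(20, range(10), range(10), range(15))
        assert ev.model_efficiency(c, r, s) == 1.0

    def test_model_efficiency_undefined_without_reactive_specific(self):
        c, r, s = _arrays(10, range(3), [], range(5))
        assert math.isnan(ev.model_efficiency(c, r, s))

    def test_overall_efficiency(self):
        c, _, s = _arrays(150, range(60), [], range(100))
        assert ev.overall_efficiency(c, s) == pytest.approx(0.6)
        assert ev.overall_efficiency(np.zeros(150, bool), s) == 0.0
        assert math.isnan(ev.overall_efficiency(c, np.zeros(150, bool)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            ev.model_efficiency([True], [True, False], [True, False])


class TestFalseDiscoveryRate:
    # cells 30-40 are nonspecific; calls hit 0-31, so 2 calls are nonspecific
    specific = [i for i in range(100) if not 30 <= i <= 40]

    def test_predicted_variant_hand_count(self):
        c, r, s = _arrays(100, range(32), range(40), self.specific)
        assert ev.false_discovery_rate(c, r, s) == pytest.approx(2 / 32)

    def test_labeled_variant_hand_count(self):
        # same calls, denominator = 40 reactive-labelled cells
        c, r, s = _arrays(100, range(32), range(40), self.specific)
        assert ev.false_discovery_rate(c, r, s, "labeled") == pytest.approx(0.05)

    def test_no_positive_calls_undefined(self):
        c, r, s = _arrays(10, [], range(4), range(5))
        assert math.isnan(ev.false_discovery_rate(c, r, s))

    def test_unknown_variant_rejected(self):
        c, r, s = _arrays(4, [0], [0], [0])
        with pytest.raises(ValueError):
            ev.false_discovery_rate(c, r, s, "bogus")


class TestPerformanceMetric:
    def test_hand_arithmetic_value(self):
        pm = ev.performance_metric(0.9, 0.9, 0.1, 0.1,
                                   ev.PerformanceWeights(1, 5))
        assert pm == pytest.approx(1 / math.sqrt(0.12), abs=1e-9)
        assert pm == pytest.approx(2.886751, abs=1e-5)

    def test_perfect_classifier_is_infinite(self):
        assert math.isinf(ev.performance_metric(1, 1, 0, 0))

    def test_strictly_decreasing_in_fdr(self):
        pms = [ev.performance_metric(0.9, 0.9, f, 0.1) for f in
               (0.0, 0.05, 0.1, 0.2)]
        assert all(a > b for a, b in zip(pms, pms[1:]))

    def test_strictly_increasing_in_efficiency(self):
        pms = [ev.performance_metric(e, 0.9, 0.1, 0.1) for e in
               (0.6, 0.8, 0.95)]
        assert all(a < b for a, b in zip(pms, pms[1:]))

    def test_symmetric_in_conditions(self):
        assert ev.performance_metric(0.8, 0.95, 0.02, 0.1) == \
            ev.performance_metric(0.95, 0.8, 0.1, 0.02)

    def test_literal_mode_repeats_first_fdr(self):
        lit = ev.performance_metric(0.9, 0.9, 0.1, 0.3, literal=True)
        assert lit == ev.performance_metric(0.9, 0.9, 0.1, 0.1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ev.performance_metric(1.2, 0.9, 0.1, 0.1)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_property(self, ea, eb, fa, fb):
        a = ev.performance_metric(ea, eb, fa, fb)
        b = ev.performance_metric(eb, ea, fb, fa)
        assert a == pytest.approx(b, rel=1e-12) or (math.isinf(a) and math.isinf(b))


def _concordance_auc(probs, labels):
    """Pairwise concordance with ties counted 0.5 (independent oracle)."""
    pos = probs[labels]
    neg = probs[~labels]
    wins = ties = 0
    for p in pos:
        wins += (p > neg).sum()
        ties += (p == neg).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocCurve:
    def test_hand_counted_case(self):
        probs = np.array([0.9, 0.4, 0.6, 0.1])
        labels = np.array([True, True, False, False])
        roc = ev.roc_curve(probs, labels)
        assert roc.auc == pytest.approx(0.75)   # 3 of 4 concordant pairs

    def test_perfect_separation(self):
        roc = ev.roc_curve(np.array([0.9, 0.8, 0.2, 0.1]),
                           np.array([True, True, False, False]))
        assert roc.auc == 1.0

    def test_all_ties_give_half(self):
        roc = ev.roc_curve(np.full(10, 0.5), np.arange(10) % 2 == 0)
        assert roc.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            ev.roc_curve(np.array([0.1, 0.9]), np.array([True, True]))

    def test_tpr_fpr_monotone(self):
        rng = np.random.default_rng(0)
        roc = ev.roc_curve(rng.random(200), rng.random(200) < 0.4)
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_matches_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # discretized probabilities force ties to exercise the 0.5 rule
        probs = np.round(rng.random(1000), 2)
        labels = rng.random(1000) < 0.45
        roc = ev.roc_curve(probs, labels)
        assert roc.auc == pytest.approx(_concordance_auc(probs, labels),
                                        abs=1e-9)


class TestPerFovSummary:
    def test_perfect_predictions(self):
        c, r, s = _arrays(20, range(10), range(10), range(10))
        per_fov, report = ev.per_fov_summary(c, r, s, ["f0"] * 20,
                                             ["OVA_like"] * 20)
        assert per_fov[0].eff_times_one_minus_fdr == 1.0
        assert math.isinf(report.pm)

    def test_condition_mean_weights_fovs_equally(self):
        # FOV a: eff 0.8 (4/5 called), FOV b: eff 0.6 (3/5 called)
        calls = [True] * 4 + [False] + [True] * 3 + [False] * 2
        reactive = [True] * 5 + [True] * 5
        specific = reactive
        fovs = ["a"] * 5 + ["b"] * 5
        _, report = ev.per_fov_summary(calls, reactive, specific, fovs,
                                       ["OVA_like"] * 10)
        assert report.condition_efficiency["OVA_like"] == pytest.approx(0.7)

    def test_report_pm_recomputable_from_means(self):
        rng = np.random.default_rng(3)
        n = 200
        calls = rng.random(n) < 0.5
        reactive = rng.random(n) < 0.5
        specific = rng.random(n) < 0.5
        fovs = [f"f{i % 4}" for i in range(n)]
        conds = ["OVA_like" if i % 4 < 2 else "gp33_like" for i in range(n)]
        _, report = ev.per_fov_summary(calls, reactive, specific, fovs, conds)
        assert report.pm == ev.aggregate_pm_from_means(
            report.condition_efficiency, report.condition_fdr, report.weights)

    def test_unknown_condition_tag_rejected(self):
        c, r, s = _arrays(4, [0], [0], [0])
        with pytest.raises(ValueError, match="condition"):
            ev.per_fov_summary(c, r, s, ["f0"] * 4, ["weird"] * 4,
                               known_conditions=("OVA_like",))

    def test_counts_reproduce_fractions(self):
        rng = np.random.default_rng(4)
        n = 150
        calls = rng.random(n) < 0.4
        reactive = rng.random(n) < 0.5
        specific = rng.random(n) < 0.5
        per_fov, _ = ev.per_fov_summary(calls, reactive, specific,
                                        ["f0"] * n, ["OVA_like"] * n)
        m = per_fov[0]
        k = m.counts
        assert m.model_efficiency == pytest.approx(
            (k["n_specific_called"] and
             sum(1 for i in range(n) if calls[i] and reactive[i] and specific[i])
             ) / k["n_specific_reactive"])
        assert m.fdr == pytest.approx(k["n_nonspecific_called"] / k["n_called"])


class TestMotility:
    def test_three_four_five_speed(self):
        t = CellTrack("c", "f", [0, 1], [0.0, 3.0], [0.0, 4.0])
        np.testing.assert_allclose(ev.instantaneous_speed(t), [5.0])

    def test_stationary_zero(self):
        t = CellTrack("c", "f", np.arange(5), np.ones(5), np.ones(5))
        np.testing.assert_allclose(ev.instantaneous_speed(t), 0.0)

    def test_single_point_empty(self):
        t = CellTrack("c", "f", [0], [1.0], [1.0])
        assert ev.instantaneous_speed(t).size == 0

    def test_arrest_factor_recovered_from_simulation(self):
        import catrace as ct

        cfg = ct.SimulationConfig(cells_per_fov=80, arrest_factor=0.25,
                                  n_frames=300, fov_size_px=2000)
        fov = ct.simulate_field_of_view(cfg, "f0", "d0",
                                        np.random.default_rng(0))
        ratios = []
        for cell, track in zip(fov.truth, fov.tracks):
            if cell.onset_frame is None or not 50 < cell.onset_frame < 250:
                continue
            speeds = ev.instantaneous_speed(track)
            ratios.append(speeds[cell.onset_frame:].mean()
                          / speeds[:cell.onset_frame].mean())
        assert np.mean(ratios) == pytest.approx(0.25, rel=0.15)


class TestDetectOnset:
    fit = BaselineFit(mu_lo=1.0, sigma_lo=0.1, weight_lo=0.7,
                      mu_hi=3.0, sigma_hi=0.3, weight_hi=0.3)

    def test_flat_trace_none(self):
        assert ev.detect_onset(np.ones(100), self.fit) is None

    def test_clean_onset_found(self):
        v = np.ones(100)
        v[50:] = 3.0
        assert ev.detect_onset(v, self.fit) == 50

    def test_short_excursion_ignored(self):
        v = np.ones(100)
        v[50:52] = 3.0      # 2 frames < min_run_frames=3
        assert ev.detect_onset(v, self.fit) is None

    def test_degenerate_fit_gives_none(self):
        fit = BaselineFit(1.0, 0.1, 1.0, None, None, None, degenerate=True)
        v = np.ones(100)
        v[50:] = 3.0
        assert ev.detect_onset(v, fit) is None


class TestAlignSpeedToOnset:
    def _fov(self, arrest):
        import catrace as ct

        cfg = ct.SimulationConfig(cells_per_fov=60, arrest_factor=arrest,
                                  n_frames=200, fov_size_px=2000)
        return ct.simulate_field_of_view(cfg, "f0", "d0",
                                         np.random.default_rng(1))

    def test_arrest_shows_in_profile(self):
        fov = self._fov(0.25)
        onsets = [c.onset_frame for c in fov.truth]
        profile = ev.align_speed_to_onset(fov.tracks, onsets, window=30)
        pre = profile[profile.offset < 0].mean_speed.mean()
        post = profile[profile.offset > 0].mean_speed.mean()
        assert post < pre

    def test_no_arrest_null_control(self):
        fov = self._fov(1.0)
        onsets = [c.onset_frame for c in fov.truth]
        profile = ev.align_speed_to_onset(fov.tracks, onsets, window=30)
        pre = profile[profile.offset < 0].mean_speed.mean()
        post = profile[profile.offset > 0].mean_speed.mean()
        assert abs(post - pre) < 0.15 * pre

    def test_no_onsets_empty_profile(self):
        fov = self._fov(0.25)
        profile = ev.align_speed_to_onset(fov.tracks, [None] * len(fov.tracks),
                                          window=10)
        assert profile.empty

    def test_window_truncation_reflected_in_counts(self):
        fov = self._fov(0.25)
        onsets = [c.onset_frame for c in fov.truth]
        profile = ev.align_speed_to_onset(fov.tracks, onsets, window=500)
        assert profile.offset.min() >= -200
        assert profile.offset.max() <= 200
        assert profile.n_cells.max() <= sum(o is not None for o in onsets)


class TestSpeedCalciumAnticorrelation:
    def test_negative_correlation_for_reactive_cells(self):
        import catrace as ct

        cfg = ct.SimulationConfig(cells_per_fov=100, n_frames=241,
                                  fov_size_px=2000)
        fov = ct.simulate_field_of_view(cfg, "f0", "d0",
                                        np.random.default_rng(2))
        corrs = []
        for cell, track, trace in zip(fov.truth, fov.tracks, fov.traces):
            if cell.onset_frame is None or not 20 < cell.onset_frame < 220:
                continue
            speeds = ev.instantaneous_speed(track)
            corrs.append(np.corrcoef(trace.values[:-1], speeds)[0, 1])
        assert len(corrs) >= 20
        assert np.mean(np.array(corrs) < 0) >= 0.9
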