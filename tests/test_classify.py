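"""Classifiers: threshold baseline, CNN internals, training, selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import catrace.classify as cc
from catrace._nn import CNN1d, softmax
from catrace.evaluate import PerformanceWeights
from catrace.preprocess import TrainingSet


class TestTimeAbove:
    @pytest.mark.parametrize("trace,theta,expected", [
        ((1, 1, 3, 3, 1), 2.0, 60.0),
        ((1, 1, 1), 2.0, 0.0),
        (tuple([5.0] * 241), 2.0, 7230.0),
    ])
    def test_counting(self, trace, theta, expected):
        assert cc.time_above(np.array(trace), theta, 30.0) == expected

    @given(st.lists(st.floats(0.1, 10.0), min_size=1, max_size=50),
           st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_naive_count(self, values, theta):
        naive = sum(30.0 for v in values if v > theta)
        assert cc.time_above(np.array(values), theta, 30.0) == naive


def _brute_force_threshold(values_list, reactive, genotypes, fovs, conds,
                           ca_grid, t_grid, interval, weights):
    """Independent exhaustive search: plain loops and the pM formula."""
    best = None
    for ca in ca_grid:
        for t in t_grid:
            calls = [sum(interval for v in vals if v > ca) > t
                     for vals in values_list]
            by_cond = {}
            for cond in sorted(set(conds)):
                effs, fdrs = [], []
                for fov in sorted(set(fovs)):
                    idx = [i for i in range(len(calls))
                           if fovs[i] == fov and conds[i] == cond]
                    if not idx:
                        continue
                    den_e = sum(1 for i in idx if genotypes[i] and reactive[i])
                    num_e = sum(1 for i in idx
                                if genotypes[i] and reactive[i] and calls[i])
                    if den_e:
                        effs.append(num_e / den_e)
                    den_f = sum(1 for i in idx if calls[i])
                    num_f = sum(1 for i in idx if not genotypes[i] and calls[i])
                    if den_f:
                        fdrs.append(num_f / den_f)
                by_cond[cond] = (np.mean(effs) if effs else 0.0,
                                 np.mean(fdrs) if fdrs else 0.0)
            pairs = sorted(by_cond)
            if len(pairs) == 1:
                pairs = pairs * 2
            rad = sum(weights.w_eff * (1 - by_cond[c][0]) ** 2 for c in pairs) \
                + sum(weights.w_fdr * by_cond[c][1] ** 2 for c in pairs)
            pm = math.inf if rad <= 0 else 1 / math.sqrt(rad)
            key = (pm, -ca, t)
            if best is None or key > best[0]:
                best = (key, ca, t, pm)
    return best[1], best[2], best[3]


class TestThresholdFit:
    def _random_instance(self, seed, n_cells=200):
        rng = np.random.default_rng(seed)
        values, reactive, genotypes, fovs, conds = [], [], [], [], []
        for i in range(n_cells):
            specific = rng.random() < 0.5
            active = rng.random() < (0.7 if specific else 0.1)
            v = rng.normal(1.0, 0.1, 40)
            if active:
                v[rng.integers(0, 30):] += rng.uniform(0.5, 2.5)
            values.append(np.abs(v))
            reactive.append(active)
            genotypes.append(specific)
            fovs.append(f"f{i % 4}")
            conds.append("OVA_like" if i % 4 < 3 else "gp33_like")
        return values, np.array(reactive), np.array(genotypes), fovs, conds

    @pytest.mark.parametrize("seed", [0, 1])
    def test_equals_brute_force_oracle(self, seed):
        values, reactive, genotypes, fovs, conds = self._random_instance(seed)
        ca_grid = np.round(np.arange(1.0, 3.01, 0.25), 3)
        t_grid = np.arange(0.0, 1801.0, 300.0)
        w = PerformanceWeights()
        model, pm = cc.threshold_fit(values, reactive, genotypes, fovs, conds,
                                     ca_grid, t_grid, 30.0, w)
        ca_o, t_o, pm_o = _brute_force_threshold(
            values, reactive, genotypes, fovs, conds, ca_grid, t_grid, 30.0, w)
        assert model.ca_threshold == ca_o
        assert model.time_threshold_s == t_o
        assert pm == pytest.approx(pm_o, rel=1e-12) or (
            math.isinf(pm) and math.isinf(pm_o))

    def test_result_independent_of_grid_order(self):
        values, reactive, genotypes, fovs, conds = self._random_instance(3)
        ca_grid = np.round(np.arange(1.0, 3.01, 0.25), 3)
        t_grid = np.arange(0.0, 1801.0, 300.0)
        fwd, _ = cc.threshold_fit(values, reactive, genotypes, fovs, conds,
                                  ca_grid, t_grid, 30.0)
        rev, _ = cc.threshold_fit(values, reactive, genotypes, fovs, conds,
                                  ca_grid[::-1], t_grid[::-1], 30.0)
        assert fwd == rev

    def test_all_negative_returns_min_ca_max_t(self):
        values = [np.ones(20) for _ in range(30)]
        labels = np.zeros(30, dtype=bool)
        fovs = ["f0"] * 30
        conds = ["OVA_like"] * 30
        model, _ = cc.threshold_fit(values, labels, labels, fovs, conds,
                                    ca_grid=[1.0, 2.0, 3.0],
                                    time_grid_s=[0.0, 300.0, 600.0])
        assert model.ca_threshold == 1.0
        assert model.time_threshold_s == 600.0

    def test_single_pair_grid(self):
        values = [np.ones(10)]
        model, _ = cc.threshold_fit(values, [True], [True], ["f0"], ["OVA_like"],
                                    ca_grid=[1.5], time_grid_s=[300.0])
        assert model == cc.ThresholdModel(1.5, 300.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            cc.threshold_fit([np.ones(5)], [True], [True], ["f"], ["OVA_like"],
                             ca_grid=[], time_grid_s=[0.0])


class TestThresholdPredict:
    def test_exact_time_threshold_is_negative(self):
        # 2 frames above at 30 s -> 60 s; theta_t = 60 s exactly -> nonspecific
        trace = np.array([1.0, 3.0, 3.0, 1.0])
        model = cc.ThresholdModel(ca_threshold=2.0, time_threshold_s=60.0)
        assert cc.threshold_predict(trace, model, 30.0) is False
        assert cc.threshold_predict(trace, model, 31.0) is True

    def test_flat_trace_negative(self):
        model = cc.ThresholdModel(2.0, 0.0)
        assert cc.threshold_predict(np.ones(50), model, 30.0) is False


class TestCNNInternals:
    def test_forward_probabilities_sum_to_one(self):
        net = CNN1d(n_channels=1, n_frames=64, n_filters=16, kernel_size=11)
        probs = net.predict_proba(np.zeros((5, 1, 64)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert probs.shape == (5, 2)

    def test_three_input_channels_accepted(self):
        net = CNN1d(n_channels=3, n_frames=64, n_filters=8, kernel_size=5)
        assert net.predict_proba(np.zeros((2, 3, 64))).shape == (2, 2)

    def test_kernel_must_fit_input(self):
        with pytest.raises(ValueError, match="kernel"):
            CNN1d(n_channels=1, n_frames=16, n_filters=4, kernel_size=21)

    def test_same_seed_identical_init(self):
        a = CNN1d(1, 64, 8, 5, seed=3).get_weights()
        b = CNN1d(1, 64, 8, 5, seed=3).get_weights()
        for wa, wb in zip(a, b):
            np.testing.assert_array_equal(wa, wb)

    def test_parameter_count(self):
        net = CNN1d(n_channels=1, n_frames=64, n_filters=8, kernel_size=5)
        # conv1: 8*1*5+8, conv2: 8*8*5+8, dense: 8*2+2
        assert net.parameter_count() == (8 * 5 + 8) + (8 * 8 * 5 + 8) + (16 + 2)

    def test_backprop_matches_numerical_gradient(self):
        """Finite-difference check of every parameter gradient on a tiny net."""
        rng = np.random.default_rng(0)
        net = CNN1d(n_channels=2, n_frames=12, n_filters=3, kernel_size=3, seed=1)
        x = rng.normal(size=(4, 2, 12))
        y = np.array([0, 1, 1, 0])

        def loss():
            probs = softmax(net.forward(x))
            return -np.log(probs[np.arange(4), y] + 1e-8).mean()

        probs = softmax(net.forward(x))
        dlogits = probs.copy()
        dlogits[np.arange(4), y] -= 1.0
        dlogits /= 4
        net.backward(dlogits)

        eps = 1e-6
        for layer in net.layers:
            for name, arr, grad_name in (layer.params or ()):
                grad = getattr(layer, grad_name)
                flat = arr.ravel()
                for k in rng.choice(flat.size, size=min(5, flat.size),
                                    replace=False):
                    orig = flat[k]
                    flat[k] = orig + eps
                    lp = loss()
                    flat[k] = orig - eps
                    lm = loss()
                    flat[k] = orig
                    num = (lp - lm) / (2 * eps)
                    assert grad.ravel()[k] == pytest.approx(num, rel=1e-4,
                                                            abs=1e-7)


def _training_set(X, y, channels=("ratio",)):
    return TrainingSet(trace_matrix=X, labels=np.asarray(y, dtype=bool),
                       cell_ids=[f"c{i}" for i in range(len(y))],
                       fov_ids=["f0"] * len(y), ground_truth_mode="manual",
                       channels=channels)


class TestCnnTrain:
    def test_no_signal_control_near_chance(self):
        """Identical flat traces for both classes: held-out AUC ~ 0.5."""
        rng = np.random.default_rng(0)
        X = np.ones((200, 40, 1)) + rng.normal(0, 0.01, (200, 40, 1))
        y = np.arange(200) % 2
        hp = cc.CNNHyperparams(epochs=3, seed=0)
        clf = cc.cnn_train(cc.cnn_build(hp, 1, 40), _training_set(X, y), hp)
        Xh = np.ones((400, 40, 1)) + rng.normal(0, 0.01, (400, 40, 1))
        yh = np.arange(400) % 2
        p = cc.probabilities(cc.cnn_predict(clf, Xh))
        from catrace.evaluate import roc_curve

        assert 0.4 <= roc_curve(p, yh.astype(bool)).auc <= 0.6

    def test_separable_toy_problem_learned(self):
        rng = np.random.default_rng(1)
        n = 300
        X = np.ones((n, 60, 1)) + rng.normal(0, 0.08, (n, 60, 1))
        y = rng.random(n) < 0.5
        X[y, 25:, 0] += 2.0
        hp = cc.CNNHyperparams(epochs=8, seed=0)
        clf = cc.cnn_train(cc.cnn_build(hp, 1, 60), _training_set(X, y), hp)
        Xh = np.ones((200, 60, 1)) + rng.normal(0, 0.08, (200, 60, 1))
        yh = rng.random(200) < 0.5
        Xh[yh, 25:, 0] += 2.0
        p = cc.probabilities(cc.cnn_predict(clf, Xh))
        from catrace.evaluate import roc_curve

        assert roc_curve(p, yh).auc > 0.95

    def test_nonfinite_loss_aborts_with_diagnostics(self):
        X = np.ones((20, 16, 1))
        X[0, 0, 0] = np.nan
        hp = cc.CNNHyperparams(epochs=1, minibatch_size=20, seed=0)
        with pytest.raises(FloatingPointError, match="non-finite"):
            cc.cnn_train(cc.cnn_build(hp, 1, 16), _training_set(X, [0, 1] * 10), hp)

    def test_seeded_training_reproducible(self):
        rng = np.random.default_rng(2)
        X = rng.normal(1, 0.2, (60, 30, 1))
        y = np.arange(60) % 2
        hp = cc.CNNHyperparams(epochs=2, seed=5)
        a = cc.cnn_train(cc.cnn_build(hp, 1, 30), _training_set(X, y), hp)
        b = cc.cnn_train(cc.cnn_build(hp, 1, 30), _training_set(X, y), hp)
        for wa, wb in zip(a.net.get_weights(), b.net.get_weights()):
            np.testing.assert_array_equal(wa, wb)


@pytest.fixture(scope="module")
def clf():
    rng = np.random.default_rng(3)
    X = rng.normal(1, 0.3, (80, 24, 1))
    y = (X.mean(axis=(1, 2)) > 1).astype(int)
    hp = cc.CNNHyperparams(epochs=3, seed=0)
    return cc.cnn_train(cc.cnn_build(hp, 1, 24), _training_set(X, y), hp)


class TestCnnPredict:

    def test_call_boundary_is_geq(self, clf):
        preds = cc.cnn_predict(clf, np.ones((10, 24, 1)))
        for p in preds:
            assert p.call == (p.p_antigen_spe >= clf.p_threshold)

    def test_raising_threshold_never_adds_positives(self, clf):
        rng = np.random.default_rng(4)
        X = rng.normal(1, 0.3, (100, 24, 1))
        p = cc.probabilities(cc.cnn_predict(clf, X))
        counts = [(p >= t).sum() for t in np.linspace(0.01, 0.99, 20)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_inference_deterministic(self, clf):
        X = np.random.default_rng(5).normal(1, 0.3, (20, 24, 1))
        p1 = cc.probabilities(cc.cnn_predict(clf, X))
        p2 = cc.probabilities(cc.cnn_predict(clf, X))
        np.testing.assert_array_equal(p1, p2)

    def test_channel_mismatch_rejected(self, clf):
        with pytest.raises(ValueError, match="channels"):
            cc.cnn_predict(clf, np.ones((5, 24, 2)))


class TestSelectProbabilityThreshold:
    def test_bimodal_ties_resolve_to_smallest(self):
        probs = np.array([0.95, 0.92, 0.91, 0.08, 0.05, 0.03])
        pos = np.array([True, True, True, False, False, False])
        grid = [0.05, 0.3, 0.5, 0.7, 0.9]
        thr, pm = cc.select_probability_threshold(
            probs, pos, pos, ["f0"] * 6, ["OVA_like"] * 6, grid)
        assert thr == 0.3      # smallest grid point separating the modes
        assert math.isinf(pm)

    def test_single_point_grid(self):
        thr, _ = cc.select_probability_threshold(
            np.array([0.9, 0.1]), [True, False], [True, False],
            ["f0", "f0"], ["OVA_like"] * 2, [0.5])
        assert thr == 0.5

    def test_equals_exhaustive_scan(self):
        from catrace.evaluate import score_calls

        rng = np.random.default_rng(6)
        probs = rng.random(100)
        reactive = rng.random(100) < 0.5
        genotypes = reactive ^ (rng.random(100) < 0.2)
        fovs = [f"f{i % 3}" for i in range(100)]
        conds = ["OVA_like"] * 100
        grid = np.linspace(0.05, 0.95, 19)
        thr, pm = cc.select_probability_threshold(
            probs, reactive, genotypes, fovs, conds, grid)
        scores = [score_calls(probs >= t, reactive, genotypes, fovs, conds)
                  for t in grid]
        assert pm == max(scores)
        assert thr == grid[int(np.argmax(scores))]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            cc.select_probability_threshold(np.array([0.5]), [True], [True],
                                            ["f"], ["OVA_like"], [])


class TestHyperoptimize:
    def _data(self):
        rng = np.random.default_rng(7)
        X = np.ones((120, 30, 1)) + rng.normal(0, 0.1, (120, 30, 1))
        y = rng.random(120) < 0.5
        X[y, 10:, 0] += 1.5
        train = _training_set(X[:80], y[:80])
        truth = {"reactive": y[80:], "genotype": y[80:],
                 "fov_ids": np.array(["f1"] * 40),
                 "conditions": np.array(["OVA_like"] * 40)}
        return train, X[80:], truth

    def test_single_combination(self):
        train, Xe, truth = self._data()
        hp = cc.CNNHyperparams(epochs=2, seed=0)
        best, board = cc.hyperoptimize([hp], train, Xe, truth)
        assert best == hp
        assert len(board) == 1

    def test_argmax_equals_leaderboard_max(self):
        train, Xe, truth = self._data()
        grid = [cc.CNNHyperparams(n_filters=f, kernel_size=k, epochs=2, seed=0)
                for f in (4, 8) for k in (3, 5)]
        best, board = cc.hyperoptimize(grid, train, Xe, truth)
        finite = board[~board.pm.isna()]
        assert board.loc[finite.pm.idxmax(), "n_filters"] == best.n_filters
        assert board.loc[finite.pm.idxmax(), "kernel_size"] == best.kernel_size

    def test_identical_combinations_identical_pm(self):
        train, Xe, truth = self._data()
        hp = cc.CNNHyperparams(epochs=2, seed=0)
        _, board = cc.hyperoptimize([hp, hp], train, Xe, truth)
        assert board.pm.iloc[0] == board.pm.iloc[1]

    def test_empty_grid_rejected(self):
        train, Xe, truth = self._data()
        with pytest.raises(ValueError):
            cc.hyperoptimize([], train, Xe, truth)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        X = rng.normal(1, 0.2, (40, 20, 1))
        y = np.arange(40) % 2
        hp = cc.CNNHyperparams(epochs=2, seed=1)
        clf = cc.cnn_train(cc.cnn_build(hp, 1, 20), _training_set(X, y), hp)
        cc.save_classifier(clf, tmp_path / "model")
        loaded = cc.load_classifier(tmp_path / "model")
        Xt = rng.normal(1, 0.2, (10, 20, 1))
        np.testing.assert_array_equal(
            cc.probabilities(cc.cnn_predict(clf, Xt)),
            cc.probabilities(cc.cnn_predict(loaded, Xt)))
        assert loaded.p_threshold == clf.p_threshold
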