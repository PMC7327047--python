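"""Window discrimination: fitting, matching, conflict resolution."""

import numpy as np
import pytest

import salientsort as ss
from salientsort.errors import ParameterError, TrainingError
from salientsort.saliency import SalientFeatureSet
from salientsort.windows import DiscriminationWindow, balanced_accuracy


def _fs(label, indices, K=4):
    L = len(indices)
    return SalientFeatureSet(
        class_label=label, indices=list(indices),
        saliencies=[1.0] * L, correlations=np.eye(L), K=K,
    )


def _separable_1d():
    """Two classes separated on feature 0; feature 1 is shared noise."""
    rng = np.random.default_rng(0)
    a = np.column_stack([rng.normal(0, 1, 50), rng.normal(0, 1, 50)])
    b = np.column_stack([rng.normal(20, 1, 50), rng.normal(0, 1, 50)])
    pad = np.zeros((100, 2))
    m = ss.SpikeMatrix(
        waveforms=np.hstack([np.vstack([a, b]), pad]),
        labels=np.array(["a"] * 50 + ["b"] * 50),
    )
    sets = {"a": _fs("a", [0]), "b": _fs("b", [0])}
    return m, sets


class TestFitWindows:
    def test_separable_classes_reach_perfect_balanced_accuracy(self):
        m, sets = _separable_1d()
        config = ss.fit_windows(m, sets, refine=True)
        W = m.waveforms.astype(float)
        for w in config.windows:
            own = W[m.labels == w.class_label][:, w.feature_indices]
            others = W[m.labels != w.class_label][:, w.feature_indices]
            assert balanced_accuracy(own, others, w.lower, w.upper) == 1.0

    def test_extreme_percentiles_without_refine_give_min_max(self):
        m, sets = _separable_1d()
        config = ss.fit_windows(m, sets, p_lo=0, p_hi=100,
                                refine=False, margin=False)
        for w in config.windows:
            own = m.waveforms[m.labels == w.class_label][:, w.feature_indices]
            np.testing.assert_allclose(w.lower, own.min(axis=0))
            np.testing.assert_allclose(w.upper, own.max(axis=0))

    @pytest.mark.parametrize("seed", range(8))
    def test_refinement_never_decreases_training_j(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        W = np.hstack([
            np.vstack([rng.normal(0, 2, (n, 2)), rng.normal(3, 2, (n, 2))]),
            np.zeros((2 * n, 2)),
        ])
        m = ss.SpikeMatrix(W, np.array(["a"] * n + ["b"] * n))
        sets = {"a": _fs("a", [0, 1]), "b": _fs("b", [0, 1])}
        base = ss.fit_windows(m, sets, refine=False, margin=False)
        refined = ss.fit_windows(m, sets, refine=True, margin=False)
        Wf = m.waveforms.astype(float)
        for wb, wr in zip(base.windows, refined.windows):
            own = Wf[m.labels == wb.class_label][:, wb.feature_indices]
            oth = Wf[m.labels != wb.class_label][:, wb.feature_indices]
            j0 = balanced_accuracy(own, oth, wb.lower, wb.upper)
            j1 = balanced_accuracy(own, oth, wr.lower, wr.upper)
            assert j1 >= j0 - 1e-12

    def test_margin_expansion_never_decreases_training_j(self):
        m, sets = _separable_1d()
        tight = ss.fit_windows(m, sets, refine=True, margin=False)
        wide = ss.fit_windows(m, sets, refine=True, margin=True)
        Wf = m.waveforms.astype(float)
        for wt, ww in zip(tight.windows, wide.windows):
            assert np.all(ww.lower <= wt.lower)
            assert np.all(ww.upper >= wt.upper)
            own = Wf[m.labels == wt.class_label][:, wt.feature_indices]
            oth = Wf[m.labels != wt.class_label][:, wt.feature_indices]
            assert balanced_accuracy(own, oth, ww.lower, ww.upper) >= \
                balanced_accuracy(own, oth, wt.lower, wt.upper) - 1e-12

    def test_missing_feature_set_rejected(self):
        m, sets = _separable_1d()
        del sets["b"]
        with pytest.raises(TrainingError, match="b"):
            ss.fit_windows(m, sets)

    def test_bad_percentiles_rejected(self):
        m, sets = _separable_1d()
        with pytest.raises(ParameterError):
            ss.fit_windows(m, sets, p_lo=50, p_hi=50)


def _toy_config():
    wa = DiscriminationWindow("a", [0, 1], np.array([0.0, 0.0]),
                              np.array([10.0, 10.0]))
    wb = DiscriminationWindow("b", [0, 1], np.array([20.0, 0.0]),
                              np.array([30.0, 10.0]))
    return ss.SorterConfig(channel_id="ch", windows=[wa, wb], L=2, K=4)


class TestClassifySpike:
    def test_point_inside_single_window(self):
        res = ss.classify_spike(np.array([5.0, 5.0, 0, 0]), _toy_config())
        assert res.matched_labels == ["a"]
        assert res.resolved_label == "a"

    def test_point_outside_all_windows_unclassified(self):
        res = ss.classify_spike(np.array([15.0, 5.0, 0, 0]), _toy_config())
        assert res.matched_labels == []
        assert res.resolved_label == ss.UNCLASSIFIED

    def test_boundary_value_is_inside(self):
        res = ss.classify_spike(np.array([10.0, 10.0, 0, 0]), _toy_config())
        assert "a" in res.matched_labels

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_border_check(self, seed):
        rng = np.random.default_rng(seed)
        K = 6
        windows = []
        for c in range(3):
            lo = rng.uniform(-50, 30, 2)
            hi = lo + rng.uniform(0, 40, 2)
            idx = rng.choice(K, 2, replace=False).tolist()
            windows.append(DiscriminationWindow(f"c{c}", idx, lo, hi))
        config = ss.SorterConfig("ch", windows, L=2, K=K)
        for _ in range(2000):
            x = rng.uniform(-60, 60, K)
            res = ss.classify_spike(x, config)
            expected = [
                w.class_label for w in windows
                if all(w.lower[l] <= x[w.feature_indices[l]] <= w.upper[l]
                       for l in range(2))
            ]
            assert res.matched_labels == expected


class TestResolveLabel:
    def test_single_match_is_identity(self):
        assert ss.resolve_label(["b"], np.zeros(4), _toy_config()) == "b"

    def test_nested_windows_resolve_to_deeper(self):
        outer = DiscriminationWindow("z_outer", [0], np.array([-10.0]),
                                     np.array([10.0]))
        inner = DiscriminationWindow("a_inner", [0], np.array([4.0]),
                                     np.array([6.0]))
        config = ss.SorterConfig("ch", [outer, inner], L=1, K=2)
        # at the inner center, inner depth = 1 beats outer depth = 0.5
        x = np.array([5.0, 0.0])
        assert ss.resolve_label(["z_outer", "a_inner"], x, config) == "a_inner"

    def test_identical_windows_tie_to_smallest_label(self):
        w1 = DiscriminationWindow("b", [0], np.array([0.0]), np.array([10.0]))
        w2 = DiscriminationWindow("a", [0], np.array([0.0]), np.array([10.0]))
        config = ss.SorterConfig("ch", [w1, w2], L=1, K=1)
        assert ss.resolve_label(["b", "a"], np.array([3.0]), config) == "a"

    def test_empty_matches_unclassified(self):
        assert ss.resolve_label([], np.zeros(4), _toy_config()) == \
            ss.UNCLASSIFIED


class TestSortStream:
    def test_empty_matrix_gives_empty_labels(self):
        out = ss.sort_stream(ss.SpikeMatrix(np.empty((0, 4))), _toy_config())
        assert out.size == 0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        m = ss.SpikeMatrix(rng.uniform(-30, 30, (50, 4)))
        config = _toy_config()
        base = ss.sort_stream(m, config)
        perm = rng.permutation(50)
        permuted = ss.sort_stream(ss.SpikeMatrix(m.waveforms[perm]), config)
        np.testing.assert_array_equal(permuted, base[perm])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            ss.sort_stream(ss.SpikeMatrix(np.zeros((3, 7))), _toy_config())

    def test_containment_monotonicity(self):
        rng = np.random.default_rng(4)
        m = ss.SpikeMatrix(rng.uniform(-40, 40, (200, 4)))
        config = _toy_config()
        grown = ss.SorterConfig(
            "ch",
            [DiscriminationWindow(w.class_label, w.feature_indices,
                                  w.lower - 5, w.upper + 5)
             for w in config.windows],
            L=2, K=4,
        )
        for row in m.waveforms:
            before = set(ss.classify_spike(row, config).matched_labels)
            after = set(ss.classify_spike(row, grown).matched_labels)
            assert before <= after

    def test_config_json_round_trip(self, tmp_path):
        config = _toy_config()
        path = tmp_path / "cfg.json"
        config.save(path)
        back = ss.SorterConfig.load(path)
        assert back.to_dict() == config.to_dict()
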