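"""Discrimination index, saliency, and greedy salient feature selection.

The greedy selector is checked against an independent brute-force oracle
that rescores every remaining feature at every step from first principles.
"""

import numpy as np
import pytest

import salientsort as ss
from salientsort.errors import EstimationError, ParameterError
from salientsort.saliency import (
    ClassStatistics,
    DegenerateVarianceWarning,
    E_MAX,
    discrimination_vector,
)


def _stats(label, mean, std, prior, count=10):
    return ClassStatistics(
        label=label,
        mean=np.atleast_1d(np.asarray(mean, float)),
        std=np.atleast_1d(np.asarray(std, float)),
        prior=prior,
        count=count,
    )


class TestClassStatistics:
    def test_hand_computed_moments(self):
        m = ss.SpikeMatrix(
            waveforms=np.array([[0, 2], [2, 2], [5, 5], [7, 5]]),
            labels=np.array(["a", "a", "b", "b"]),
        )
        stats = {s.label: s for s in ss.estimate_class_stats(m)}
        np.testing.assert_allclose(stats["a"].mean, [1, 2])
        np.testing.assert_allclose(stats["a"].std, [np.sqrt(2), 0])
        assert stats["a"].prior == stats["b"].prior == 0.5

    def test_identical_spikes_have_zero_std(self, tiny_labeled_matrix):
        m = ss.SpikeMatrix(
            waveforms=np.tile([1, 2, 3, 4], (6, 1)),
            labels=np.array(["a"] * 3 + ["b"] * 3),
        )
        for s in ss.estimate_class_stats(m):
            np.testing.assert_array_equal(s.std, 0)

    def test_priors_sum_to_one(self, three_unit_channel):
        stats = ss.estimate_class_stats(three_unit_channel)
        assert abs(sum(s.prior for s in stats) - 1.0) < 1e-12

    def test_undersized_class_rejected_by_name(self):
        m = ss.SpikeMatrix(
            waveforms=np.array([[1, 2], [3, 4], [5, 6]]),
            labels=np.array(["a", "a", "b"]),
        )
        with pytest.raises(EstimationError, match="'b'"):
            ss.estimate_class_stats(m)


class TestDiscriminationIndex:
    def test_equal_means_give_one(self):
        a = _stats("a", [3.0], [2.0], 0.5)
        b = _stats("b", [3.0], [9.0], 0.5)
        assert ss.discrimination_index(a, b, 0) == 1.0

    def test_closed_form_value(self):
        # |gap|=3, variances 4, priors 0.5 -> pooled sqrt(0.5*4+0.5*4)=2
        a = _stats("a", [0.0], [2.0], 0.5)
        b = _stats("b", [3.0], [2.0], 0.5)
        d = ss.discrimination_index(a, b, 0)
        assert abs(d - np.exp(1.5)) < 1e-9

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = _stats("a", rng.normal(size=3), rng.uniform(0.1, 2, 3), 0.3)
            b = _stats("b", rng.normal(size=3), rng.uniform(0.1, 2, 3), 0.7)
            for k in range(3):
                assert ss.discrimination_index(a, b, k) == \
                    ss.discrimination_index(b, a, k)

    def test_at_least_one_everywhere(self):
        rng = np.random.default_rng(1)
        a = _stats("a", rng.normal(size=8), rng.uniform(0.1, 2, 8), 0.4)
        b = _stats("b", rng.normal(size=8), rng.uniform(0.1, 2, 8), 0.6)
        assert np.all(discrimination_vector(a, b) >= 1.0)

    def test_degenerate_variance_clips_and_warns(self):
        a = _stats("a", [0.0], [0.0], 0.5)
        b = _stats("b", [1.0], [0.0], 0.5)
        with pytest.warns(DegenerateVarianceWarning):
            d = ss.discrimination_index(a, b, 0)
        assert d == pytest.approx(np.exp(E_MAX))

    def test_zero_gap_zero_variance_gives_one(self):
        a = _stats("a", [5.0], [0.0], 0.5)
        b = _stats("b", [5.0], [0.0], 0.5)
        assert ss.discrimination_index(a, b, 0) == 1.0


class TestClassSaliency:
    def test_two_class_closed_form(self):
        # d = e, P_j = 0.5: literal saliency (e^0.5)^2 / (0.5 e) = 2
        sigma = 1.0 / np.sqrt(0.5)  # makes pooled std 1 -> d = e for gap 1
        a = _stats("a", [0.0], [sigma], 0.5)
        b = _stats("b", [1.0], [sigma], 0.5)
        sal, _, _ = ss.class_saliency([a, b], "a", 0)
        assert abs(sal - 2.0) < 1e-9

    def test_three_class_closed_form(self):
        # all d = e, priors 1/3: literal = e^{4/3} / ((2/3) e) = 1.5 e^{1/3}
        sigma = 1.0 / np.sqrt(2.0 / 3.0)
        stats = [
            _stats("a", [0.0], [sigma], 1 / 3),
            _stats("b", [1.0], [sigma], 1 / 3),
            _stats("c", [-1.0], [sigma], 1 / 3),
        ]
        # check the premise: d_ab = d_ac = e
        assert abs(ss.discrimination_index(stats[0], stats[1], 0) - np.e) < 1e-9
        sal, _, hom = ss.class_saliency(stats, "a", 0)
        assert abs(sal - 1.5 * np.exp(1.0 / 3.0)) < 1e-9
        assert abs(hom - 1.0) < 1e-12

    def test_homogeneity_one_iff_equal_distances(self):
        rng = np.random.default_rng(2)
        sigma = 1.0
        # unequal distances -> H < 1
        stats = [
            _stats("a", [0.0], [sigma], 0.4),
            _stats("b", [1.0], [sigma], 0.3),
            _stats("c", [4.0], [sigma], 0.3),
        ]
        _, _, hom = ss.class_saliency(stats, "a", 0)
        assert 0 < hom < 1

    def test_normalized_form_equals_geo_times_hom(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n_c = int(rng.integers(2, 5))
            stats = [
                _stats(f"c{i}", rng.normal(size=4), rng.uniform(0.2, 2, 4),
                       prior)
                for i, prior in enumerate(rng.dirichlet(np.ones(n_c)))
            ]
            sal, geo, hom = ss.class_saliency(
                stats, "c0", 2, normalize_weights=True)
            assert abs(sal - geo * hom) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(EstimationError):
            ss.class_saliency([_stats("a", [0.0], [1.0], 1.0)], "a", 0)


class TestFeatureCorrelation:
    def test_self_correlation_is_one(self, three_unit_channel):
        lab = three_unit_channel.class_labels()[0]
        assert ss.feature_correlation(three_unit_channel, lab, 20, 20) == \
            pytest.approx(1.0)

    def test_anticorrelated_columns_give_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        m = ss.SpikeMatrix(
            waveforms=np.column_stack([x, -2 * x, rng.normal(size=100)]),
            labels=np.array(["a"] * 100),
        )
        # add a second class so the matrix is valid for class selection
        m2 = ss.SpikeMatrix(
            waveforms=np.vstack([m.waveforms, m.waveforms + 5]),
            labels=np.array(["a"] * 100 + ["b"] * 100),
        )
        assert ss.feature_correlation(m2, "a", 0, 1) == pytest.approx(1.0)

    def test_independent_columns_nearly_uncorrelated(self):
        rng = np.random.default_rng(5)
        m = ss.SpikeMatrix(
            waveforms=rng.normal(size=(10_000, 2)),
            labels=np.array(["a"] * 10_000),
        )
        assert ss.feature_correlation(m, "a", 0, 1) < 0.05

    def test_zero_variance_column_gives_zero(self):
        m = ss.SpikeMatrix(
            waveforms=np.column_stack([np.ones(10), np.arange(10)]),
            labels=np.array(["a"] * 10),
        )
        assert ss.feature_correlation(m, "a", 0, 1) == 0.0


def brute_force_greedy(matrix, label, L):
    """Independent oracle: rescore every candidate at every greedy step
    using only the public statistic evaluators."""
    stats = ss.estimate_class_stats(matrix)
    K = matrix.n_samples
    saliency = np.array([
        ss.class_saliency(stats, label, k, normalize_weights=True)[0]
        for k in range(K)
    ])
    chosen = []
    for _ in range(L):
        best_k, best_crit = None, -np.inf
        for kappa in range(K):
            if kappa in chosen:
                continue
            crit = saliency[kappa]
            for h in chosen:
                crit *= 1.0 - ss.feature_correlation(matrix, label, kappa, h)
            if crit > best_crit + 1e-12:
                best_k, best_crit = kappa, crit
        chosen.append(best_k)
    return chosen


class TestSelectSalientFeatures:
    def test_planted_feature_is_most_salient(self):
        matrix, planted = ss.planted_feature_channel(
            planted=(13,), delta_fraction=0.5, snr=8.0, n_spikes=300, seed=0)
        for lab in ("u0", "u1"):
            fs = ss.select_salient_features(matrix, lab, 1)
            assert fs.indices[0] == 13

    def test_full_selection_is_permutation(self, tiny_labeled_matrix):
        rng = np.random.default_rng(6)
        m = ss.SpikeMatrix(
            waveforms=rng.normal(size=(40, 6)),
            labels=np.array(["a"] * 20 + ["b"] * 20),
        )
        fs = ss.select_salient_features(m, "a", 6)
        assert sorted(fs.indices) == list(range(6))

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_c = int(rng.integers(2, 5))
        K = int(rng.integers(4, 13))
        n_per = 12
        waveforms = np.vstack([
            rng.normal(loc=rng.normal(0, 2, size=K), scale=rng.uniform(0.5, 1.5),
                       size=(n_per, K))
            for _ in range(n_c)
        ])
        labels = np.repeat([f"c{i}" for i in range(n_c)], n_per)
        m = ss.SpikeMatrix(waveforms=waveforms, labels=labels)
        L = min(4, K)
        for lab in m.class_labels():
            fs = ss.select_salient_features(m, lab, L)
            assert fs.indices == brute_force_greedy(m, lab, L)

    def test_scale_equivariance(self, three_unit_channel):
        m = three_unit_channel
        scaled = ss.SpikeMatrix(m.waveforms * 3, m.labels)
        for lab in m.class_labels():
            a = ss.select_salient_features(m, lab, 3)
            b = ss.select_salient_features(scaled, lab, 3)
            assert a.indices == b.indices

    def test_max_index_restricts_search(self, three_unit_channel):
        fs = ss.select_salient_features(three_unit_channel, "u0", 2,
                                        max_index=16)
        assert all(i < 16 for i in fs.indices)

    def test_oversized_L_rejected(self, three_unit_channel):
        with pytest.raises(ParameterError):
            ss.select_salient_features(three_unit_channel, "u0", 49)

    def test_jittered_alignment_keeps_selection_near_planted_block(self):
        # alignment jitter of +-1 sample smears the planted block by one
        # sample on each side; the selector should stay in that halo
        hits = 0
        for seed in range(20):
            base = ss.generate_templates(1, 48, seed=seed)[0]
            shifted = base.samples.copy()
            shifted[20:24] += 0.35 * base.peak_to_peak
            spec = ss.ChannelSpec(
                templates=(
                    ss.SpikeTemplate(samples=base.samples, label="u0"),
                    ss.SpikeTemplate(samples=shifted, label="u1"),
                ),
                priors=np.array([0.5, 0.5]),
                snr_per_unit=np.array([6.0, 6.0]),
                n_spikes=400,
                jitter_samples=1,
                seed=seed,
            )
            m = ss.synthesize_channel(spec)
            fs = ss.select_salient_features(m, "u0", 2)
            halo = set(range(19, 25))
            hits += all(i in halo for i in fs.indices)
        assert hits >= 16


class TestBuildProfiles:
    def test_profile_matches_elementwise_saliency(self, three_unit_channel):
        profiles = ss.build_profiles(three_unit_channel)
        stats = ss.estimate_class_stats(three_unit_channel)
        for lab, prof in profiles.items():
            for k in (0, 17, 33):
                sal, geo, hom = ss.class_saliency(
                    stats, lab, k, normalize_weights=True)
                assert prof.saliency[k] == pytest.approx(sal)
                assert prof.geo_mean[k] == pytest.approx(geo)
                assert prof.homogeneity[k] == pytest.approx(hom)

    def test_duplicated_class_has_unit_discrimination(self):
        rng = np.random.default_rng(8)
        block = rng.normal(size=(30, 8))
        m = ss.SpikeMatrix(
            waveforms=np.vstack([block, block, block + 10]),
            labels=np.array(["a"] * 30 + ["b"] * 30 + ["c"] * 30),
        )
        prof = ss.build_profiles(m)["a"]
        j = prof.other_labels.index("b")
        np.testing.assert_allclose(prof.discrimination[j], 1.0)

    def test_profile_argmax_equals_first_selected_feature(self, three_unit_channel):
        profiles = ss.build_profiles(three_unit_channel)
        for lab, prof in profiles.items():
            fs = ss.select_salient_features(three_unit_channel, lab, 1)
            assert fs.indices[0] == int(np.argmax(prof.saliency))

    def test_homogeneity_in_unit_interval(self, three_unit_channel):
        for prof in ss.build_profiles(three_unit_channel).values():
            assert np.all(prof.homogeneity > 0)
            assert np.all(prof.homogeneity <= 1.0 + 1e-12)
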