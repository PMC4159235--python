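import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import mutual_info_score

from striaparc import (
    StabilityResult,
    SyntheticConfig,
    cluster_entropy,
    generate_dataset,
    mutual_information,
    select_optimal_k,
    split_half_stability,
    subject_profiles,
    variation_of_information,
)
from striaparc.stability import _split_indices

LN2 = np.log(2.0)


def brute_force_vi(a, b):
    """Independent oracle: build the contingency table with dict loops and
    evaluate H + H' - 2I from first principles."""
    a, b = list(a), list(b)
    n = len(a)
    joint, pa, pb = {}, {}, {}
    for x, y in zip(a, b):
        joint[(x, y)] = joint.get((x, y), 0) + 1
        pa[x] = pa.get(x, 0) + 1
        pb[y] = pb.get(y, 0) + 1
    H = lambda counts: -sum(c / n * np.log(c / n) for c in counts.values())
    I = sum(
        c / n * np.log((c / n) / ((pa[x] / n) * (pb[y] / n)))
        for (x, y), c in joint.items()
    )
    return H(pa) + H(pb) - 2 * I


class TestEntropy:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            ([1, 1, 1, 1], 0.0),
            ([1, 1, 2, 2], LN2),
            ([1, 1, 1, 2], -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))),
        ],
    )
    def test_worked_values(self, labels, expected):
        assert cluster_entropy(labels) == pytest.approx(expected, abs=1e-12)

    def test_four_element_nested_value(self):
        assert cluster_entropy([1, 1, 1, 2]) == pytest.approx(0.562335, abs=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cluster_entropy([])


class TestMutualInformation:
    def test_identical_equals_entropy(self):
        assert mutual_information([1, 1, 2, 2], [1, 1, 2, 2]) == pytest.approx(LN2)

    def test_independent_is_zero(self):
        assert mutual_information([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(0.0)

    def test_constant_partner_is_zero(self, rng):
        labels = rng.integers(1, 4, 20)
        assert mutual_information(labels, np.ones(20, int)) == pytest.approx(0.0)

    def test_bounded_by_entropies(self, rng):
        for _ in range(30):
            a = rng.integers(1, 5, 25)
            b = rng.integers(1, 5, 25)
            mi = mutual_information(a, b)
            assert -1e-12 <= mi <= min(cluster_entropy(a), cluster_entropy(b)) + 1e-12

    def test_matches_sklearn(self, rng):
        for _ in range(20):
            a = rng.integers(1, 5, 30)
            b = rng.integers(1, 4, 30)
            assert mutual_information(a, b) == pytest.approx(
                mutual_info_score(a, b), abs=1e-12
            )


class TestVariationOfInformation:
    def test_self_distance_zero(self, rng):
        labels = rng.integers(1, 5, 30)
        assert variation_of_information(labels, labels) == 0.0

    def test_relabeling_invariance(self):
        assert variation_of_information([1, 1, 2, 2], [5, 5, 9, 9]) == 0.0

    def test_worked_values(self):
        assert variation_of_information([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(
            2 * LN2, abs=1e-12
        )
        # refining one cluster of (1,1,2,2) into singletons costs half a bit
        assert variation_of_information([1, 1, 2, 2], [1, 2, 3, 3]) == pytest.approx(
            0.5 * LN2, abs=1e-12
        )
        assert variation_of_information([1, 1, 2, 2], [1, 2, 3, 3]) == pytest.approx(
            0.346574, abs=1e-6
        )

    def test_metric_axioms_over_random_triples(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 31))
            a = rng.integers(1, 6, n)
            b = rng.integers(1, 6, n)
            c = rng.integers(1, 6, n)
            vab = variation_of_information(a, b)
            vba = variation_of_information(b, a)
            assert vab == pytest.approx(vba, abs=1e-12)
            assert vab >= 0
            assert vab <= np.log(n) + 1e-12
            assert vab <= (
                variation_of_information(a, c) + variation_of_information(c, b) + 1e-10
            )

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 40))
            a = rng.integers(1, 6, n)
            b = rng.integers(1, 6, n)
            assert variation_of_information(a, b) == pytest.approx(
                brute_force_vi(a, b), abs=1e-12
            )


class TestSplitHalf:
    def test_59_subjects_split_29_30(self, rng):
        for _ in range(100):
            i1, i2 = _split_indices(59, rng)
            assert (len(i1), len(i2)) == (29, 30)
            assert sorted(np.concatenate([i1, i2])) == list(range(59))

    def test_noiseless_data_perfectly_stable_at_k_true(self):
        ds = generate_dataset(SyntheticConfig(n_subjects=8, T=60, noise_sd=0.0,
                                              subject_sd=0.0, nuisance_leak=0.0,
                                              rng_seed=1))
        profiles = [subject_profiles(s.roi_series, s.target_series)
                    for s in ds.subjects]
        res = split_half_stability(profiles, [3], n_perm=5, rng_seed=2,
                                   kmeans_params=dict(n_restarts=10))
        assert np.all(res.vi_samples[3] == 0.0)

    def test_true_k_more_stable_than_overclustering(self, small_profiles):
        res = split_half_stability(small_profiles, [3, 6], n_perm=10, rng_seed=3,
                                   kmeans_params=dict(n_restarts=10))
        assert res.vi_samples[3].mean() < res.vi_samples[6].mean()

    def test_deterministic(self, small_profiles):
        a = split_half_stability(small_profiles, [2, 3], n_perm=4, rng_seed=5,
                                 kmeans_params=dict(n_restarts=5))
        b = split_half_stability(small_profiles, [2, 3], n_perm=4, rng_seed=5,
                                 kmeans_params=dict(n_restarts=5))
        for k in (2, 3):
            np.testing.assert_array_equal(a.vi_samples[k], b.vi_samples[k])

    def test_too_few_subjects_or_perms(self, small_profiles):
        with pytest.raises(ValueError):
            split_half_stability(small_profiles[:3], [2], n_perm=5)
        with pytest.raises(ValueError):
            split_half_stability(small_profiles, [2], n_perm=1)


class TestSelectOptimalK:
    @staticmethod
    def make_result(vi_samples):
        return StabilityResult(
            k_values=tuple(vi_samples),
            vi_samples={k: np.asarray(v, float) for k, v in vi_samples.items()},
            n_perm=len(next(iter(vi_samples.values()))),
        )

    def test_first_flat_transition_selected(self, rng):
        n = 40
        base = rng.standard_normal(n) * 0.01
        vi = {
            2: base + 0.10,
            3: base + 0.30,   # 3 vs 2 significant
            4: base + 0.50,   # 4 vs 3 significant
            5: base + 0.70,   # 5 vs 4 significant
            6: base + 0.70 + rng.standard_normal(n) * 0.002,  # 6 vs 5 flat
        }
        res = self.make_result(vi)
        assert select_optimal_k(res) == 6
        # confirm the designed p-value pattern against the t formula directly
        for k in (3, 4, 5):
            assert stats.ttest_rel(vi[k], vi[k - 1]).pvalue < 0.05
        assert stats.ttest_rel(vi[6], vi[5]).pvalue >= 0.05

    def test_all_transitions_significant_returns_none(self, rng):
        n = 30
        vi = {k: np.full(n, 0.1 * k) + rng.standard_normal(n) * 1e-4
              for k in range(2, 6)}
        assert select_optimal_k(self.make_result(vi)) is None

    def test_identical_samples_give_p_one(self):
        v = np.array([0.3, 0.4, 0.5, 0.6])
        res = self.make_result({2: v.copy(), 3: v.copy()})
        assert select_optimal_k(res) == 3
        assert res.transition_tests[3] == (0.0, 1.0)

    def test_missing_consecutive_k_is_error(self):
        res = self.make_result({2: np.zeros(5), 5: np.zeros(5)})
        with pytest.raises(ValueError):
            select_optimal_k(res)
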