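"""Split-half stability of parcellations via variation of information (VI).

Subjects are repeatedly split into two halves; each half's group-average
profile matrix is clustered at every K, and the two solutions are compared
with VI = H(C) + H(C') - 2 I(C, C'), where H is the entropy of the cluster
occupation probabilities P(k) = n_k / n and I the mutual information from
the joint counts P(k, k') = n_kk' / n.  VI is a true metric on partitions:
zero iff the clusterings coincide up to relabeling, symmetric, and
triangle-obeying, bounded by ln n.  All entropies are in nats.

The number of parcels is chosen as the smallest K (from K = 3 up) whose VI
distribution is statistically indistinguishable from that of K - 1: parsimony
among the stable solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectivity import ConnectivityProfiles, group_average
from .parcellation import contingency_table, kmeans_correlation

__all__ = [
    "StabilityResult",
    "cluster_entropy",
    "mutual_information",
    "variation_of_information",
    "split_half_stability",
    "select_optimal_k",
]


def cluster_entropy(labels: np.ndarray) -> float:
    """H(C) = -sum_k P(k) ln P(k) with P(k) = n_k / n; 0 log 0 = 0."""
    labels = np.asarray(labels).ravel()
    if labels.size == 0:
        raise ValueError("empty labeling has no entropy")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log(p)).sum())


def mutual_information(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """I(C, C') from the contingency table, in nats; 0 <= I <= min(H, H')."""
    table = contingency_table(labels_a, labels_b)
    n = table.sum()
    p_ab = table / n
    p_a = p_ab.sum(axis=1, keepdims=True)
    p_b = p_ab.sum(axis=0, keepdims=True)
    nz = p_ab > 0
    mi = float((p_ab[nz] * np.log(p_ab[nz] / (p_a @ p_b)[nz])).sum())
    return max(mi, 0.0)


def variation_of_information(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """VI(C, C') = H(C) + H(C') - 2 I(C, C') >= 0, in nats."""
    vi = (
        cluster_entropy(labels_a)
        + cluster_entropy(labels_b)
        - 2.0 * mutual_information(labels_a, labels_b)
    )
    # identical-up-to-relabeling pairs cancel exactly up to rounding
    return 0.0 if vi < 1e-12 else vi


@dataclass
class StabilityResult:
    """Per-K VI distributions over split-half permutations plus the K choice."""

    k_values: tuple[int, ...]
    vi_samples: dict[int, np.ndarray]
    transition_tests: dict[int, tuple[float, float]] = field(default_factory=dict)
    optimal_k: int | None = None
    n_perm: int = 0
    rng_seed: int = 0
    split_sizes: tuple[int, int] = (0, 0)

    def mean_vi(self) -> dict[int, float]:
        return {k: float(v.mean()) for k, v in self.vi_samples.items()}


def _split_indices(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    half = n // 2
    return perm[:half], perm[half:]


def split_half_stability(
    subject_profiles: list[ConnectivityProfiles],
    k_values,
    n_perm: int = 100,
    rng_seed: int = 0,
    kmeans_params: dict | None = None,
) -> StabilityResult:
    """VI between clusterings of two random subject halves, per K and permutation.

    Halves have sizes floor(n/2) and ceil(n/2); the same split is reused for
    every K within a permutation so transition tests can pair by permutation.
    Deterministic for a given master seed.
    """
    n = len(subject_profiles)
    if n < 4:
        raise ValueError("need at least 4 subjects to split")
    if n_perm < 2:
        raise ValueError("need at least 2 permutations")
    k_values = tuple(int(k) for k in k_values)
    kmeans_params = dict(kmeans_params or {})
    kmeans_params.setdefault("n_restarts", 20)

    master = np.random.SeedSequence(rng_seed)
    split_rng = np.random.default_rng(master.spawn(1)[0])
    kseed_rng = np.random.default_rng(master.spawn(1)[0])

    vi = {k: np.empty(n_perm) for k in k_values}
    sizes = (n // 2, n - n // 2)
    for p in range(n_perm):
        idx1, idx2 = _split_indices(n, split_rng)
        g1 = group_average([subject_profiles[i] for i in idx1])
        g2 = group_average([subject_profiles[i] for i in idx2])
        for k in k_values:
            s1 = int(kseed_rng.integers(0, 2**31 - 1))
            s2 = int(kseed_rng.integers(0, 2**31 - 1))
            lab1 = kmeans_correlation(g1, k, rng_seed=s1, **kmeans_params).labels
            lab2 = kmeans_correlation(g2, k, rng_seed=s2, **kmeans_params).labels
            vi[k][p] = variation_of_information(lab1, lab2)

    result = StabilityResult(
        k_values=k_values,
        vi_samples=vi,
        n_perm=n_perm,
        rng_seed=rng_seed,
        split_sizes=sizes,
    )
    try:
        result.optimal_k = select_optimal_k(result)
    except ValueError:
        # no consecutive K >= 3 to compare; selection is undefined
        result.optimal_k = None
    return result


def _transition_test(
    vi_k: np.ndarray, vi_prev: np.ndarray, paired: bool
) -> tuple[float, float]:
    """t statistic and two-sided p comparing VI(K) with VI(K-1).

    Identical samples (zero differences everywhere) give t = 0, p = 1: two
    indistinguishable solutions should never look significantly different.
    """
    if paired:
        diffs = vi_k - vi_prev
        if np.allclose(diffs, 0.0):
            return 0.0, 1.0
        if np.std(diffs, ddof=1) == 0:
            return np.inf if diffs.mean() > 0 else -np.inf, 0.0
        t, p = stats.ttest_rel(vi_k, vi_prev)
    else:
        if np.allclose(vi_k, vi_k[0]) and np.allclose(vi_prev, vi_prev[0]):
            if np.isclose(vi_k[0], vi_prev[0]):
                return 0.0, 1.0
            return np.inf if vi_k[0] > vi_prev[0] else -np.inf, 0.0
        t, p = stats.ttest_ind(vi_k, vi_prev)
    return float(t), float(p)


def select_optimal_k(
    result: StabilityResult, alpha: float = 0.05, paired: bool = True
) -> int | None:
    """Smallest K >= 3 whose VI does not differ significantly from K - 1.

    Fills ``result.transition_tests`` as a side effect; returns None when
    every transition is significant (no stable plateau found).
    """
    ks = sorted(result.k_values)
    candidates = [k for k in ks if k - 1 in ks and k >= 3]
    if not candidates:
        raise ValueError("need consecutive K values with K >= 3 to compare")
    chosen = None
    for k in candidates:
        t, p = _transition_test(
            result.vi_samples[k], result.vi_samples[k - 1], paired=paired
        )
        result.transition_tests[k] = (t, p)
        if chosen is None and p >= alpha:
            chosen = k
    return chosen
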