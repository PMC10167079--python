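"""Chance-level machinery for decoding results.

Two complementary routes:

* **Binomial threshold** (large samples, group decoding): the smallest
  accuracy k*/n such that the cumulative Binomial(n, 1/n_classes)
  probability of k* correct guesses reaches 1 - alpha. Accuracies strictly
  above the threshold are declared significant.
* **Permutation null** (small samples, within-participant task decoding):
  condition labels are shuffled across a participant's trials and the full
  pipeline (splits -> xDAWN -> sliding windows -> AUC) is re-run per
  permutation; the null statistic is the maximum over time windows of the
  fold-mean AUC, matching how peak performance is assessed. Per-participant
  null samples are pooled at the group level and the empirical
  (1 - alpha)-quantile (nearest rank) becomes the significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.stats import binom

from . import decoder
from .simgen import EpochSet

__all__ = [
    "SignificanceResult",
    "binomial_threshold",
    "permutation_null",
    "group_threshold",
    "make_within_stat_fn",
    "peak_auc_statistic",
]


@dataclass
class SignificanceResult:
    """A chance-level threshold and how it was obtained."""

    threshold: float
    alpha: float
    method: str                            # "binomial" | "permutation"
    null_distribution: np.ndarray | None = None
    n_permutations: int = 0


def binomial_threshold(n_trials: int, n_classes: int,
                       alpha: float = 0.05) -> float:
    """Significance threshold on accuracy from the binomial CDF.

    Returns k*/n_trials with k* the smallest integer whose cumulative
    Binomial(n_trials, 1/n_classes) probability is >= 1 - alpha.
    """
    if n_trials < 1 or n_classes < 2:
        raise ValueError("need n_trials >= 1 and n_classes >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p = 1.0 / n_classes
    k = int(binom.ppf(1.0 - alpha, n_trials, p))
    # binom.ppf returns the smallest k with CDF >= q; guard float edge cases
    while k > 0 and binom.cdf(k - 1, n_trials, p) >= 1.0 - alpha:
        k -= 1
    while binom.cdf(k, n_trials, p) < 1.0 - alpha:
        k += 1
    return k / n_trials


def peak_auc_statistic(trajectory: decoder.DecodeTrajectory) -> float:
    """Maximum over time windows of the fold-mean score."""
    return float(trajectory.mean_curve.max())


def make_within_stat_fn(plan: decoder.CVPlan,
                        window: decoder.WindowSpec = decoder.WindowSpec(),
                        n_components: int = 5,
                        metric: str = "auc"
                        ) -> Callable[[EpochSet, np.ndarray, int], float]:
    """Build the within-participant decode statistic for permutation tests.

    The returned function runs the complete task-decoding pipeline on the
    supplied labels with split seeds derived from its ``seed`` argument and
    returns the peak (max over windows) fold-mean score.
    """

    def stat_fn(epochs: EpochSet, labels: np.ndarray, seed: int) -> float:
        traj = decoder.decode_time_resolved(
            epochs, replace(plan, seed=seed), window=window, metric=metric,
            n_components=n_components, labels=labels)
        return peak_auc_statistic(traj)

    return stat_fn


def permutation_null(epochs: EpochSet,
                     decode_fn: Callable[[EpochSet, np.ndarray, int], float],
                     n_permutations: int = 1000,
                     seed: int = 0) -> np.ndarray:
    """Label-permutation null sample of a within-participant statistic.

    For each permutation the condition labels are reassigned to trials by a
    seeded shuffle and ``decode_fn(epochs, labels, perm_seed)`` is
    re-evaluated with an independent split seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    labels = np.asarray(epochs.trial_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("permutation test requires at least 2 classes")
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        ss = np.random.SeedSequence([seed, i])
        shuffle_seed, split_seed = (int(s) % (2**31)
                                    for s in ss.generate_state(2))
        rng = np.random.default_rng(shuffle_seed)
        null[i] = decode_fn(epochs, rng.permutation(labels), split_seed)
    return null


def group_threshold(null_samples: list[np.ndarray] | np.ndarray,
                    alpha: float = 0.05) -> SignificanceResult:
    """Pool per-participant nulls; nearest-rank (1 - alpha)-quantile."""
    if isinstance(null_samples, np.ndarray):
        pooled = null_samples.ravel()
    else:
        pooled = np.concatenate([np.asarray(s).ravel()
                                 for s in null_samples]) \
            if null_samples else np.array([])
    if pooled.size == 0:
        raise ValueError("empty null distribution")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    pooled = np.sort(pooled)
    rank = int(np.ceil((1.0 - alpha) * pooled.size))
    threshold = float(pooled[max(rank - 1, 0)])
    return SignificanceResult(threshold=threshold, alpha=alpha,
                              method="permutation",
                              null_distribution=pooled,
                              n_permutations=pooled.size)
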