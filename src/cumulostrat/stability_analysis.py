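"""Drop-10% resampling heterogeneity statistic.

How stable is a differential signature under small perturbations of the
cohort?  The procedure repeats the two-group test ``n_tests`` times, each
time dropping a random fraction of the samples (default 10%, without
replacement, group labels preserved), thresholds each run into a feature
set, and measures the pairwise intersection percentage between every pair
of runs.  The *global variance* -- the sample variance of the off-diagonal
percentages -- is the heterogeneity statistic: homogeneous cohorts yield
nearly identical signatures in every run (percentages all high, variance
low), while heterogeneous cohorts (e.g. strong donor substructure) let the
signature swing with the subsample, inflating the variance.

The intersection percentage is Jaccard similarity x 100
(100 * |A & B| / |A | B|); two empty selections count as identical (100).
The scientific claim rests on the *ordering* of variances between cohorts,
not on their absolute values, so the choice of denominator is a documented
convention (overlap-over-smaller-set is available as an option).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import OmicsMatrix
from .differential_testing import select_features, two_group_test

__all__ = ["StabilityResult", "jackknife_stability", "intersection_percentage"]


@dataclass
class StabilityResult:
    """Per-test selections, pairwise intersection matrix and global variance."""

    n_tests: int
    drop_fraction: float
    selections: list[set]
    kept_samples: list[list[str]]  # subsample membership per test, for audit
    matrix: np.ndarray  # n_tests x n_tests intersection percentages, 100 on the diagonal
    global_variance: float
    seed: int

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.n_tests, k=1)
        return self.matrix[iu]


def intersection_percentage(a: set, b: set, denominator: str = "jaccard") -> float:
    """Intersection percentage between two feature sets, in [0, 100]."""
    a, b = set(a), set(b)
    inter = len(a & b)
    if denominator == "jaccard":
        denom = len(a | b)
    elif denominator == "min":
        denom = min(len(a), len(b))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        return 100.0  # both selections empty: identical
    return 100.0 * inter / denom


def jackknife_stability(
    m: OmicsMatrix,
    groups: pd.Series | dict,
    n_tests: int = 10,
    drop_fraction: float = 0.10,
    rule: str = "p",
    alpha: float = 0.05,
    seed: int = 0,
    denominator: str = "jaccard",
) -> StabilityResult:
    """Repeated subsampled differential tests and their overlap statistics.

    Each test drops ``ceil(drop_fraction * n)`` samples uniformly at random
    (without replacement, labels preserved), reruns the two-group test on
    the remainder, and selects features at ``rule``/``alpha``.  Every group
    must retain >=2 samples even in the worst-case draw, which makes the
    feasibility check deterministic.
    """
    if n_tests < 2:
        raise ValueError("n_tests must be >= 2")
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must lie in [0, 1)")
    labels = pd.Series(groups)
    samples = [s for s in m.sample_ids]
    missing = set(samples) - set(labels.index)
    if missing:
        raise ValueError(f"samples without a group label: {sorted(missing)}")
    labels = labels[samples]
    n = len(samples)
    drop_n = math.ceil(drop_fraction * n)
    for level, count in labels.value_counts().items():
        if count - drop_n < 2:
            raise ValueError(
                f"dropping {drop_n} sample(s) could leave group {level!r} "
                f"(size {count}) below 2"
            )

    rng = np.random.default_rng(seed)
    selections: list[set] = []
    kept_all: list[list[str]] = []
    for _ in range(n_tests):
        drop_idx = set(rng.choice(n, size=drop_n, replace=False).tolist())
        kept = [s for i, s in enumerate(samples) if i not in drop_idx]
        sub = m.subset_samples(kept)
        res = two_group_test(sub, labels[kept])
        selections.append(set(select_features(res, rule=rule, alpha=alpha).features))
        kept_all.append(kept)

    mat = np.full((n_tests, n_tests), 100.0)
    for i in range(n_tests):
        for j in range(i + 1, n_tests):
            pct = intersection_percentage(selections[i], selections[j], denominator)
            mat[i, j] = mat[j, i] = pct
    off = mat[np.triu_indices(n_tests, k=1)]
    global_variance = float(np.var(off, ddof=1)) if len(off) > 1 else 0.0
    return StabilityResult(
        n_tests=n_tests,
        drop_fraction=drop_fraction,
        selections=selections,
        kept_samples=kept_all,
        matrix=mat,
        global_variance=global_variance,
        seed=seed,
    )
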