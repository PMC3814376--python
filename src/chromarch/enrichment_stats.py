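"""Shared statistical kernel for gene-set and profile analyses.

Provides observed/expected enrichment ratios, Fisher's exact test, a bootstrap
null for enrichment ratios, the Wilcoxon rank-sum test, Z-score normalization
(population convention), a trimmed-percentile expression-variability score and
a covariate-ordered moving average.

Conventions
-----------
All tests are two-sided by default; one-sided alternatives are available via
the ``alternative`` argument. Every stochastic operation takes an explicit
``seed`` and is exactly reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class EnrichmentResult:
    """Observed/expected enrichment of a class within a gene subset."""

    subset: str
    class_name: str
    observed: int
    expected: float
    ratio: float
    p_value: float = math.nan
    method: str = "ratio"
    n_trials: int | None = None
    seed: int | None = None

    def as_dict(self) -> dict:
        return {
            "subset": self.subset,
            "class": self.class_name,
            "observed": self.observed,
            "expected": self.expected,
            "ratio": self.ratio,
            "p_value": self.p_value,
            "method": self.method,
            "n_trials": self.n_trials,
            "seed": self.seed,
        }


@dataclass
class VariabilityScore:
    """Trimmed dynamic range of a gene's expression across conditions."""

    gene_id: str
    range: float
    n_conditions: int


def relative_enrichment(subset: set, class_set: set, universe: set,
                        subset_name: str = "subset",
                        class_name: str = "class") -> EnrichmentResult:
    """Ratio of observed over expected members of ``class_set`` inside ``subset``.

    ``expected = |subset| * |class_set & universe| / |universe|``. Raises
    ``ValueError`` when the expected count is zero (empty subset, or class
    absent from the universe), because the ratio is then undefined.
    """
    subset, class_set, universe = set(subset), set(class_set), set(universe)
    if not subset <= universe:
        raise ValueError("subset must be contained in the universe")
    if not universe:
        raise ValueError("universe is empty")
    class_in_universe = class_set & universe
    observed = len(subset & class_in_universe)
    expected = len(subset) * len(class_in_universe) / len(universe)
    if expected == 0:
        raise ValueError(
            f"expected count is zero for class '{class_name}' in subset "
            f"'{subset_name}'; enrichment ratio undefined")
    return EnrichmentResult(subset_name, class_name, observed, expected,
                            observed / expected)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a non-negative integer 2x2 table.

    The two-sided p sums the hypergeometric probabilities of all tables with
    the observed margins that are no more probable than the observed table.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.all(np.equal(np.mod(t, 1), 0)):
        raise ValueError("table entries must be non-negative integers")
    if t.sum() == 0:
        raise ValueError("all margins are zero; Fisher test undefined")
    return float(min(1.0, stats.fisher_exact(t.astype(int), alternative="two-sided")[1]))


def bootstrap_enrichment(subset_size: int, class_set: set, universe: set,
                         observed_ratio: float, n_trials: int = 1000,
                         seed: int | None = None,
                         alternative: str = "two-sided") -> float:
    """Bootstrap p-value for an enrichment ratio against random gene subsets.

    Each trial draws ``subset_size`` ids uniformly without replacement from the
    universe and computes the trial enrichment ratio; the trial overlap count is
    sampled directly from the equivalent hypergeometric distribution. The
    p-value uses add-one smoothing, ``p = (1 + n_extreme) / (1 + n_trials)``,
    so it is never exactly zero. Deviation from the null is measured as
    distance of the ratio from 1 (two-sided) or a one-sided excess.
    """
    universe = set(universe)
    n_universe = len(universe)
    if subset_size > n_universe:
        raise ValueError("subset_size exceeds universe size")
    n_class = len(set(class_set) & universe)
    expected = subset_size * n_class / n_universe
    if expected == 0:
        raise ValueError("expected count is zero; bootstrap ratio undefined")
    rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(n_class, n_universe - n_class, subset_size,
                               size=n_trials)
    ratios = draws / expected
    eps = 1e-12
    if alternative == "two-sided":
        n_extreme = int(np.sum(np.abs(ratios - 1.0) >= abs(observed_ratio - 1.0) - eps))
    elif alternative == "greater":
        n_extreme = int(np.sum(ratios >= observed_ratio - eps))
    elif alternative == "less":
        n_extreme = int(np.sum(ratios <= observed_ratio + eps))
    else:
        raise ValueError(f"unknown alternative: {alternative}")
    return (1 + n_extreme) / (1 + n_trials)


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value with midranks for ties.

    Exact distribution for small samples (``len(a)+len(b) <= 12`` without
    ties), normal approximation with tie correction otherwise. Two groups with
    all values identical are maximally compatible with the null (p = 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(min(1.0, res.pvalue))


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, standard deviation 1 (population, divisor n)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("zscore requires at least two values")
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zscore undefined for a zero-variance vector")
    return (x - x.mean()) / sd


def expression_variability(values, gene_id: str = "") -> VariabilityScore:
    """Dynamic range of expression: |q98 - q2| after dropping the extreme 1%.

    The strictly lowest and highest 1% of values (``floor(0.01 * n)`` on each
    side) are discarded to limit outlier leverage, then the absolute difference
    between the 2nd and 98th percentiles (linear interpolation) of the trimmed
    values is returned.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 10:
        raise ValueError("expression_variability requires at least 10 values")
    k = int(math.floor(0.01 * n))
    trimmed = x[k: n - k] if k > 0 else x
    q2, q98 = np.percentile(trimmed, [2, 98])
    return VariabilityScore(gene_id, float(abs(q98 - q2)), n)


def moving_average_by_covariate(y, covariate, window: int = 100):
    """Moving average of ``y`` over genes ordered by a covariate.

    Genes are sorted by the covariate (stable sort) and each position receives
    the mean of a centered window; near the edges the window shrinks
    symmetrically so every output remains centered on its gene.

    Returns ``(covariate_sorted, smoothed)`` arrays aligned to the sort order.
    """
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    n = y.size
    if cov.size != n:
        raise ValueError("y and covariate must have the same length")
    if window < 1 or window > n:
        raise ValueError("window must satisfy 1 <= window <= len(y)")
    order = np.argsort(cov, kind="stable")
    ys = y[order]
    h = window // 2
    idx = np.arange(n)
    r = np.minimum(h, np.minimum(idx, n - 1 - idx))
    cs = np.concatenate(([0.0], np.cumsum(ys)))
    smoothed = (cs[idx + r + 1] - cs[idx - r]) / (2 * r + 1)
    return cov[order], smoothed
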