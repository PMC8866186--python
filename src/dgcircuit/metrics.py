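"""Pattern-separation metrics: sparsity, selectivity, discriminability.

For an activity matrix A (patterns x units) with "active" meaning activity
above the shared epsilon:

* population sparsity of pattern k: ``1 - F_units,k`` where ``F_units,k`` is
  the fraction of units active for pattern k; defined as 0 (not 1) when no
  unit is active, so that silencing the population is never rewarded.
* unit selectivity of unit i: ``1 - F_patterns,i`` where ``F_patterns,i`` is
  the fraction of patterns the unit responds to; 0 when the unit never
  responds, so silent units are never rewarded.
* pairwise discriminability of patterns k, l: ``1 - C_kl`` with C the cosine
  similarity of the two population vectors, when both patterns activate at
  least one unit; 0 otherwise.

All three metrics live in [0, 1] and larger is better. Cross-condition
comparisons use two-sample two-sided Kolmogorov-Smirnov tests with
Bonferroni adjustment, and distributions across repeated network instances
are summarized as mean +/- sd cumulative-distribution curves on a fixed
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import ACTIVITY_EPS, ActivityMatrix

__all__ = [
    "MetricsReport",
    "KSComparison",
    "CrossInstanceSummary",
    "sparsity",
    "selectivity",
    "cosine_similarity",
    "similarity_matrix",
    "discriminability",
    "compare_distributions",
    "summarize_across_instances",
    "DEFAULT_CDF_GRID",
]

#: Fixed grid of metric values on which cumulative distributions are
#: evaluated so mean +/- sd across instances is well defined.
DEFAULT_CDF_GRID = np.linspace(0.0, 1.0, 513)


def _as_values(activity: ActivityMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(activity, ActivityMatrix):
        return activity.values, activity.active
    values = np.asarray(activity, dtype=float)
    if values.ndim != 2:
        raise ValueError("activity must be a 2-D patterns x units array")
    return values, values > ACTIVITY_EPS


def sparsity(activity: ActivityMatrix | np.ndarray) -> np.ndarray:
    """Per-pattern population sparsity (0 for patterns with no active unit)."""
    _, active = _as_values(activity)
    f_units = active.mean(axis=1)
    return np.where(f_units > 0, 1.0 - f_units, 0.0)


def selectivity(activity: ActivityMatrix | np.ndarray) -> np.ndarray:
    """Per-unit pattern selectivity (0 for units that never respond)."""
    _, active = _as_values(activity)
    f_patterns = active.mean(axis=0)
    return np.where(f_patterns > 0, 1.0 - f_patterns, 0.0)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two nonnegative activity vectors."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"vector lengths differ: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError(
            "cosine similarity undefined for zero vectors; the degenerate "
            "pair is handled by the discriminability exception branch"
        )
    return float(np.dot(u, v) / (nu * nv))


def similarity_matrix(activity: ActivityMatrix | np.ndarray) -> np.ndarray:
    """Pairwise cosine-similarity (representational similarity) matrix.

    Rows with zero norm yield ``nan`` entries; consumers that need a total
    function (discriminability) apply the exception branch instead.
    """
    values, _ = _as_values(activity)
    norms = np.linalg.norm(values, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = values / norms[:, None]
    C = unit @ unit.T
    np.clip(C, -1.0, 1.0, out=C)
    return C


def discriminability(activity: ActivityMatrix | np.ndarray) -> np.ndarray:
    """Pairwise pattern discriminability matrix (1 - cosine similarity).

    Entries where either pattern has no active unit are 0. The matrix is
    symmetric with a zero diagonal.
    """
    values, active = _as_values(activity)
    both_active = np.outer(active.any(axis=1), active.any(axis=1))
    C = similarity_matrix(values)
    D = np.where(both_active, 1.0 - C, 0.0)
    np.clip(D, 0.0, 1.0, out=D)
    np.fill_diagonal(D, 0.0)
    return D


def _offdiag_upper(matrix: np.ndarray) -> np.ndarray:
    """Flattened strict upper triangle: one value per distinct pattern pair."""
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


@dataclass
class MetricsReport:
    """All three metrics plus the similarity matrix for one activity matrix."""

    population: str
    seed: int | None
    sparsity: np.ndarray  # (n_patterns,)
    selectivity: np.ndarray  # (n_units,)
    similarity: np.ndarray  # (n_patterns, n_patterns)
    discriminability: np.ndarray  # (n_patterns, n_patterns)

    @classmethod
    def from_activity(cls, activity: ActivityMatrix | np.ndarray) -> "MetricsReport":
        if isinstance(activity, ActivityMatrix):
            population, seed = activity.population, activity.seed
        else:
            population, seed = "unknown", None
        return cls(
            population=population,
            seed=seed,
            sparsity=sparsity(activity),
            selectivity=selectivity(activity),
            similarity=similarity_matrix(activity),
            discriminability=discriminability(activity),
        )

    @property
    def discriminability_pairs(self) -> np.ndarray:
        """Discriminability of every distinct pattern pair (k < l)."""
        return _offdiag_upper(self.discriminability)

    def metric_samples(self, metric: str) -> np.ndarray:
        if metric == "sparsity":
            return self.sparsity
        if metric == "selectivity":
            return self.selectivity
        if metric == "discriminability":
            return self.discriminability_pairs
        raise KeyError(f"unknown metric {metric!r}")


@dataclass
class KSComparison:
    statistic: float
    pvalue: float
    adjusted_pvalue: float
    n_comparisons: int


def compare_distributions(
    sample_a: np.ndarray, sample_b: np.ndarray, n_comparisons: int = 1
) -> KSComparison:
    """Two-sample two-sided Kolmogorov-Smirnov test with Bonferroni adjustment.

    ``n_comparisons`` is the number of panel-wise comparisons sharing the
    family-wise error budget; the adjusted p-value is
    ``min(1, p * n_comparisons)``.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return KSComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        adjusted_pvalue=float(min(1.0, res.pvalue * n_comparisons)),
        n_comparisons=int(n_comparisons),
    )


@dataclass
class CrossInstanceSummary:
    """Mean +/- sd cumulative distributions across repeated network instances.

    ``cdf_mean[m]`` and ``cdf_sd[m]`` are curves over ``grid`` giving, for
    each metric value x, the mean and standard deviation across instances of
    P(metric <= x). ``pooled[m]`` concatenates the raw per-instance samples
    (used for KS comparisons across conditions).
    """

    grid: np.ndarray
    cdf_mean: dict[str, np.ndarray] = field(default_factory=dict)
    cdf_sd: dict[str, np.ndarray] = field(default_factory=dict)
    pooled: dict[str, np.ndarray] = field(default_factory=dict)
    n_instances: int = 0

    def mean_metric(self, metric: str) -> float:
        """Mean of the pooled per-sample metric values."""
        return float(np.mean(self.pooled[metric]))


def _ecdf_on_grid(samples: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.sort(samples), grid, side="right") / samples.size


def summarize_across_instances(
    reports: list[MetricsReport], grid: np.ndarray | None = None
) -> CrossInstanceSummary:
    """Pool metric distributions across network instances.

    All reports must have identical shapes (same battery, same population
    size). Returns per-metric mean and sd cumulative-distribution curves on
    a fixed grid plus pooled samples.
    """
    if not reports:
        raise ValueError("need at least one MetricsReport")
    shapes = {
        (r.sparsity.shape, r.selectivity.shape, r.discriminability.shape)
        for r in reports
    }
    if len(shapes) != 1:
        raise ValueError(f"reports have mismatched shapes: {shapes}")
    grid = DEFAULT_CDF_GRID if grid is None else np.asarray(grid, dtype=float)
    summary = CrossInstanceSummary(grid=grid, n_instances=len(reports))
    for metric in ("sparsity", "selectivity", "discriminability"):
        samples = [r.metric_samples(metric) for r in reports]
        curves = np.stack([_ecdf_on_grid(s, grid) for s in samples])
        summary.cdf_mean[metric] = curves.mean(axis=0)
        summary.cdf_sd[metric] = curves.std(axis=0)
        summary.pooled[metric] = np.concatenate(samples)
    return summary
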