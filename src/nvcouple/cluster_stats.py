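"""Clustering of fitted kernel parameters and the significance scan.

Each epoch fit contributes a 5-dimensional feature vector (a, b, tau, n, d)
which is standardized, clustered by Ward-linkage agglomeration, and the
dendrogram is cut at every division count N = 2..12. Within each cluster
the per-fit prediction correlations are Fisher-Z transformed; the cluster
statistic is ``z* = sqrt(n) * mean(z)`` and is compared two-sided against a
Bonferroni-corrected normal quantile. The division with the most
significant clusters wins, ties going to the larger division count.

The resulting P values are approximate: the per-epoch observations are not
independent draws from a bivariate normal, and member z-statistics within a
cluster are correlated. They are used for model selection, not inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.stats import norm

from .nvc_model import FitResult, gamma_kernel, GammaParams

__all__ = [
    "FeatureMatrix",
    "LinkageTree",
    "ClusterStat",
    "DivisionResult",
    "ClusterReport",
    "FEATURE_COLUMNS",
    "build_features",
    "ward_linkage",
    "cut_tree",
    "fisher_z",
    "cluster_zstat",
    "significance_scan",
    "select_optimal",
    "representative_kernels",
]

FEATURE_COLUMNS = ("a", "b", "tau", "n", "d")


@dataclass
class FeatureMatrix:
    """Standardized fit parameters, one row per epoch fit.

    Column statistics (population, ddof=0) are retained so cluster means
    can be mapped back to physical parameter values.
    """

    data: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    columns: tuple[str, ...] = FEATURE_COLUMNS

    def unstandardize(self, rows: np.ndarray) -> np.ndarray:
        return rows * self.std + self.mean

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]


@dataclass
class LinkageTree:
    """Ward merge history in scipy linkage-matrix form."""

    merges: np.ndarray  # (n-1, 4): left, right, height, size
    n_leaves: int

    def __post_init__(self) -> None:
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("linkage heights must be non-decreasing")


@dataclass
class ClusterStat:
    label: int
    size: int
    z_mean: float
    z_star: float
    significant: bool
    positive: bool


@dataclass
class DivisionResult:
    n_clusters: int
    labels: np.ndarray
    clusters: list[ClusterStat]
    z_alpha: float

    @property
    def n_significant(self) -> int:
        return sum(c.significant for c in self.clusters)


@dataclass
class ClusterReport:
    divisions: dict[int, DivisionResult]
    alpha: float
    notes: tuple[str, ...] = (
        "P values from the cluster Z-test are approximate and are used for "
        "selecting the dendrogram division, not as exact inference.",
    )

    def significant_counts(self) -> dict[int, int]:
        return {n: div.n_significant for n, div in self.divisions.items()}


def build_features(fits: list[FitResult], use_refined_n: bool = True) -> FeatureMatrix:
    """Assemble and standardize the (a, b, tau, n, d) feature matrix."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to build a feature matrix")
    raw = np.array(
        [
            [
                f.a,
                f.b,
                f.params.tau,
                f.n_refined if use_refined_n else f.params.n,
                f.params.d,
            ]
            for f in fits
        ]
    )
    mean = raw.mean(axis=0)
    std = raw.std(axis=0)  # population statistics
    for j, s in enumerate(std):
        if s == 0.0:
            raise ValueError(f"zero-variance feature column {FEATURE_COLUMNS[j]!r}")
    return FeatureMatrix((raw - mean) / std, mean, std)


def ward_linkage(fm: FeatureMatrix) -> LinkageTree:
    """Agglomerate by Ward's minimum-variance criterion on Euclidean distance."""
    if fm.n_rows < 2:
        raise ValueError("need at least 2 rows")
    merges = hierarchy.linkage(fm.data, method="ward")
    return LinkageTree(merges, fm.n_rows)


def cut_tree(tree: LinkageTree, n_clusters: int) -> np.ndarray:
    """Labels for exactly ``n_clusters`` groups (undo the last N-1 merges)."""
    if not (1 <= n_clusters <= tree.n_leaves):
        raise ValueError(
            f"n_clusters must be in [1, {tree.n_leaves}], got {n_clusters}"
        )
    return hierarchy.cut_tree(tree.merges, n_clusters=n_clusters).ravel()


def fisher_z(r) -> np.ndarray | float:
    """Variance-stabilizing transform ``z = atanh(r)``; |r| >= 1 is clamped."""
    r = np.asarray(r, dtype=float)
    clamp = 1.0 - 1e-12
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("correlation magnitude >= 1 clamped before atanh", stacklevel=2)
        r = np.clip(r, -clamp, clamp)
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def cluster_zstat(zs) -> tuple[float, float]:
    """Mean Fisher-Z and the cluster statistic ``z* = sqrt(n) * mean``."""
    zs = np.asarray(zs, dtype=float)
    if zs.size == 0:
        raise ValueError("empty cluster")
    z_mean = float(zs.mean())
    return z_mean, float(np.sqrt(zs.size) * z_mean)


def bonferroni_z_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Two-sided normal quantile at level ``alpha`` split over ``n_tests``."""
    return float(norm.ppf(1.0 - (alpha / n_tests) / 2.0))


def significance_scan(
    tree: LinkageTree,
    per_fit_r,
    n_range=range(2, 13),
    alpha: float = 0.05,
) -> ClusterReport:
    """Cut at every division count and Z-test each cluster's mean Fisher-Z.

    The threshold is Bonferroni-corrected over the N clusters of each
    division; a cluster is significant when ``|z*|`` exceeds it.
    """
    per_fit_r = np.asarray(per_fit_r, dtype=float)
    if per_fit_r.size != tree.n_leaves:
        raise ValueError("need one correlation per clustered fit")
    zs = np.asarray(fisher_z(per_fit_r))
    divisions: dict[int, DivisionResult] = {}
    for n_clusters in n_range:
        labels = cut_tree(tree, n_clusters)
        z_alpha = bonferroni_z_threshold(n_clusters, alpha)
        stats = []
        for label in np.unique(labels):
            members = zs[labels == label]
            z_mean, z_star = cluster_zstat(members)
            stats.append(
                ClusterStat(
                    label=int(label),
                    size=int(members.size),
                    z_mean=z_mean,
                    z_star=z_star,
                    significant=bool(abs(z_star) > z_alpha),
                    positive=bool(z_star >= 0),
                )
            )
        divisions[n_clusters] = DivisionResult(n_clusters, labels, stats, z_alpha)
    return ClusterReport(divisions, alpha)


def select_optimal(report: ClusterReport) -> int | None:
    """Division with the most significant clusters; ties go to the largest N.

    Returns None when no division has any significant cluster.
    """
    counts = report.significant_counts()
    best = max(counts.values(), default=0)
    if best == 0:
        return None
    return max(n for n, c in counts.items() if c == best)


def representative_kernels(
    labels: np.ndarray,
    fits: list[FitResult],
    fs: float,
    use_refined_n: bool = True,
) -> dict[int, dict]:
    """Per-cluster mean parameters and a unit-area representative kernel.

    The mean shape is rounded to the nearest integer for kernel evaluation
    (the continuous mean is reported alongside); the sampled kernel is
    rescaled so its discrete area (sum times dt) is exactly 1.
    """
    labels = np.asarray(labels)
    if labels.size != len(fits):
        raise ValueError("labels and fits must align")
    out: dict[int, dict] = {}
    for label in np.unique(labels):
        members = [f for f, l in zip(fits, labels) if l == label]
        tau = float(np.mean([f.params.tau for f in members]))
        n_cont = float(
            np.mean([(f.n_refined if use_refined_n else f.params.n) for f in members])
        )
        d = float(np.mean([f.params.d for f in members]))
        n_int = max(1, int(round(n_cont)))
        kernel = gamma_kernel(GammaParams(tau, n_int, d), fs)
        area = kernel.sum() / fs
        if area > 0:
            kernel = kernel / area
        out[int(label)] = {
            "size": len(members),
            "tau": tau,
            "n": n_int,
            "n_continuous": n_cont,
            "d": d,
            "a": float(np.mean([f.a for f in members])),
            "b": float(np.mean([f.b for f in members])),
            "kernel": kernel,
            "fs": fs,
        }
    return out
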