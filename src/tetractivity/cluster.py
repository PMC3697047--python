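"""Two-cluster control analysis of (estimate, observation) point clouds.

Single-linkage agglomerative clustering on Euclidean distances, cut at
the final merge so exactly two clusters remain, followed by per-cluster
summary statistics: sizes and percentages, per-coordinate mean and
standard deviation, the within-cluster Pearson correlation between the
two coordinates, and the coefficient of variation C_V = sd/mean * 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy import stats as sps


def two_cluster_single_linkage(points: np.ndarray) -> np.ndarray:
    """Labels (0/1) from a single-linkage dendrogram cut at the last
    merge.  Deterministic given the point order; label 0 is the cluster
    containing the first point."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need an (n >= 2) x d point array")
    if not np.isfinite(pts).all():
        raise ValueError("non-finite coordinates")
    Z = linkage(pdist(pts, metric="euclidean"), method="single")
    labels = fcluster(Z, t=2, criterion="maxclust")
    if labels.max() == 1:  # all distances tied at the top merge: force a split
        labels = fcluster(Z, t=Z[-1, 2] - 1e-12, criterion="distance")
        labels = np.where(labels == labels[0], 1, 2)
    return (labels != labels[0]).astype(int)


@dataclass
class ClusterSummary:
    size: int
    percentage: float
    mean: tuple[float, float]
    sd: tuple[float, float]
    pearson_r: float | None
    pearson_alpha: float | None
    cv_percent: tuple[float, float]


@dataclass
class ClusterStats:
    clusters: list[ClusterSummary]

    @property
    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]


def _cv(values: np.ndarray) -> float:
    m = values.mean()
    if m == 0:
        return float("inf") if values.std(ddof=1) > 0 else 0.0
    return float(abs(values.std(ddof=1) / m) * 100.0)


def cluster_report(points: np.ndarray, labels: np.ndarray) -> ClusterStats:
    """Per-cluster summaries for a 2-cluster labelling of 2-D points.

    Within-cluster Pearson r is undefined (None) for clusters of fewer
    than 3 points or with a constant coordinate.
    """
    pts = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    present = sorted(set(labels.tolist()))
    if len(present) != 2:
        raise ValueError("expected exactly 2 cluster labels")
    n = len(pts)
    out = []
    for lab in present:
        sub = pts[labels == lab]
        size = len(sub)
        if size >= 2:
            sd = (float(sub[:, 0].std(ddof=1)), float(sub[:, 1].std(ddof=1)))
            cv = (_cv(sub[:, 0]), _cv(sub[:, 1]))
        else:
            sd = (0.0, 0.0)
            cv = (0.0, 0.0)
        r = alpha = None
        if size >= 3 and np.ptp(sub[:, 0]) > 0 and np.ptp(sub[:, 1]) > 0:
            r_, alpha_ = sps.pearsonr(sub[:, 0], sub[:, 1])
            r, alpha = float(r_), float(alpha_)
        out.append(
            ClusterSummary(
                size=size,
                percentage=round(100.0 * size / n),
                mean=(float(sub[:, 0].mean()), float(sub[:, 1].mean())),
                sd=sd,
                pearson_r=r,
                pearson_alpha=alpha,
                cv_percent=cv,
            )
        )
    return ClusterStats(clusters=out)
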