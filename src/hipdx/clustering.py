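"""Density-descending clustering of angle triplets.

Each hip contributes one point x = (θCE, θsharp, θTönnis) in degrees.  A
Gaussian-kernel local density is computed for every sample, samples are
processed in descending density order, and each sample either joins the
cluster of its nearest already-processed neighbor (if within the linking
radius) or founds a new cluster.  The cluster seeded by the global density
peak is taken to represent normal hip development; everything outside it is
treated as outlying (dysplastic or otherwise atypical).

The three axes are all degrees of comparable magnitude, so no
standardization is applied by default; ``standardize=True`` z-scales the
axes before density and distance computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InputError

__all__ = ["DensityClustering", "local_density", "density_descending_cluster",
           "select_normal_samples", "silverman_bandwidth"]


@dataclass
class DensityClustering:
    """Result of one clustering run.

    ``labels[i]`` is the cluster id of sample ``i`` (cluster 0 is founded by
    the global density peak, so ``peak_cluster == labels[order[0]] == 0``).
    """

    densities: np.ndarray
    order: np.ndarray
    labels: np.ndarray
    peak_cluster: int
    bandwidth: float
    linking_radius: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def _as_samples(samples) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2:
        raise InputError(f"samples must be a 2D array, got shape {x.shape}")
    if len(x) < 2:
        raise InputError(f"need at least 2 samples, got {len(x)}")
    if not np.isfinite(x).all():
        raise InputError("samples contain non-finite values")
    return x


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's multivariate rule of thumb, averaged over dimensions.

    h = (4 / (d + 2))^(1/(d+4)) * n^(-1/(d+4)) * mean_j(sd_j)
    """
    n, d = x.shape
    sd = x.std(axis=0, ddof=1).mean()
    if sd == 0.0:
        sd = 1.0  # all points coincide; any positive width works
    return float((4.0 / (d + 2.0)) ** (1.0 / (d + 4.0)) * n ** (-1.0 / (d + 4.0)) * sd)


def local_density(samples, bandwidth: float) -> np.ndarray:
    """Gaussian-kernel local density of each sample.

    rho_i = sum_{j != i} exp(-||x_i - x_j||^2 / (2 h^2))
    """
    x = _as_samples(samples)
    if not bandwidth > 0:
        raise InputError(f"bandwidth must be positive, got {bandwidth}")
    d2 = cdist(x, x, metric="sqeuclidean")
    k = np.exp(-d2 / (2.0 * bandwidth * bandwidth))
    np.fill_diagonal(k, 0.0)
    return k.sum(axis=1)


def density_descending_cluster(
    samples,
    bandwidth: float | None = None,
    linking_radius: float | None = None,
    standardize: bool = False,
) -> DensityClustering:
    """Cluster samples by descending local density.

    Samples are visited in order of decreasing density (ties broken by
    sample index, so the partition is invariant to input permutation up to
    label renaming).  The first sample founds cluster 0; each later sample
    joins its nearest already-processed sample's cluster when that distance
    is at most ``linking_radius``, else founds a new cluster.

    ``bandwidth`` defaults to Silverman's multivariate rule on the pooled
    samples; ``linking_radius`` defaults to three bandwidths.
    """
    x = _as_samples(samples)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0.0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    h = silverman_bandwidth(x) if bandwidth is None else float(bandwidth)
    r = 3.0 * h if linking_radius is None else float(linking_radius)
    if not r > 0:
        raise InputError(f"linking_radius must be positive, got {r}")

    rho = local_density(x, h)
    n = len(x)
    order = np.lexsort((np.arange(n), -rho))  # descending rho, ties by index
    labels = np.full(n, -1, dtype=int)
    labels[order[0]] = 0
    next_label = 1
    for k in range(1, n):
        i = order[k]
        prev = order[:k]
        dist = np.linalg.norm(x[prev] - x[i], axis=1)
        j = int(np.argmin(dist))
        if dist[j] <= r:
            labels[i] = labels[prev[j]]
        else:
            labels[i] = next_label
            next_label += 1
    return DensityClustering(
        densities=rho, order=order, labels=labels,
        peak_cluster=int(labels[order[0]]), bandwidth=h, linking_radius=r,
    )


def select_normal_samples(clustering: DensityClustering, samples=None) -> np.ndarray:
    """Indices of the samples in the highest-density-peak cluster.

    These are the samples taken to represent normal hip development and
    used to fit the diagnostic Gaussian model.
    """
    return np.flatnonzero(clustering.labels == clustering.peak_cluster)
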