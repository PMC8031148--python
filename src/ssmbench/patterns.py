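"""Robustness aggregation of resampled predictive patterns.

A benchmark run yields one variable-space pattern per resampling
iteration.  Robust variables are found by computing, per variable, the
mean and standard deviation of the loading across iterations and the
ratio Z = mean/std, thresholded at |Z| > 3.  Edge patterns are
additionally coarse-grained by average-pooling into within- and
between-network blocks of the node partition (14 networks for the
264-node taxonomy); voxel patterns are cleaned by removing small
connected clusters on their 3-D grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data_model import EdgeIndex

__all__ = [
    "ZPattern",
    "NetworkBlockPattern",
    "aggregate_patterns",
    "threshold_z",
    "coarse_grain",
    "cluster_filter",
    "cluster_filter_signed",
]

Z_THRESHOLD = 3.0
CLUSTER_MIN_SIZE = 100


@dataclass
class ZPattern:
    """Per-variable robustness summary over resampling iterations.

    ``z = mean/std`` (sample std, ddof 1).  Where the std is exactly
    zero, z is undefined: ``valid`` is False there and such variables
    never enter a thresholded mask.
    """

    mean: np.ndarray
    std: np.ndarray
    z: np.ndarray
    valid: np.ndarray
    n_iterations: int

    def mask(self, threshold: float = Z_THRESHOLD) -> np.ndarray:
        return threshold_z(self, threshold)


def aggregate_patterns(patterns) -> ZPattern:
    """Aggregate iteration patterns into a Z-pattern.

    Parameters
    ----------
    patterns : (iterations, variables) array or sequence of equal-length vectors
    """
    arr = np.asarray(patterns, dtype=float)
    if arr.ndim != 2:
        raise ValueError("patterns must form an (iterations, variables) array")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 iterations for a std")
    mean = arr.mean(axis=0)
    std = arr.std(axis=0, ddof=1)
    valid = std > 0
    z = np.full(mean.shape, np.nan)
    z[valid] = mean[valid] / std[valid]
    return ZPattern(mean=mean, std=std, z=z, valid=valid, n_iterations=arr.shape[0])


def threshold_z(zp: ZPattern, threshold: float = Z_THRESHOLD) -> np.ndarray:
    """Boolean mask of robust variables: strictly |Z| > threshold.

    Negative loadings pass on magnitude; variables with undefined Z are
    excluded.
    """
    with np.errstate(invalid="ignore"):
        return zp.valid & (np.abs(zp.z) > threshold)


@dataclass
class NetworkBlockPattern:
    """Edge pattern pooled into network-by-network blocks.

    ``values[a, b]`` is the mean loading over edges with one endpoint in
    network a and the other in network b (a == b pools the within-network
    edges).  ``sizes`` counts the contributing edges per block and sums
    to the total edge count.
    """

    values: np.ndarray
    sizes: np.ndarray
    networks: np.ndarray


def coarse_grain(edge_pattern: np.ndarray, edge_index: EdgeIndex, partition) -> NetworkBlockPattern:
    """Average-pool an edge pattern into network blocks.

    Parameters
    ----------
    edge_pattern : values over ``edge_index``'s edges; NaN entries
        (edges dropped by the conjunction mask) are excluded from the
        block means.
    partition : (n_nodes,) node -> network labels.
    """
    edge_pattern = np.asarray(edge_pattern, dtype=float)
    partition = np.asarray(partition)
    if partition.shape != (edge_index.n_nodes,):
        raise ValueError("partition must assign every node exactly one network")
    if edge_pattern.shape != (len(edge_index),):
        raise ValueError("edge pattern length must match the edge index")

    networks, node_net = np.unique(partition, return_inverse=True)
    k = networks.size
    a = node_net[edge_index.rows]
    b = node_net[edge_index.cols]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    block = lo * k + hi  # flat index of the (unordered) network pair

    finite = np.isfinite(edge_pattern)
    sums = np.bincount(block[finite], weights=edge_pattern[finite], minlength=k * k)
    counts = np.bincount(block[finite], minlength=k * k)
    sizes_all = np.bincount(block, minlength=k * k)

    values = np.full(k * k, np.nan)
    nonempty = counts > 0
    values[nonempty] = sums[nonempty] / counts[nonempty]
    if np.any((sizes_all > 0) & ~nonempty):
        warnings.warn("some network blocks have only missing edges; values set NaN")

    values = values.reshape(k, k)
    sizes = sizes_all.reshape(k, k)
    # mirror upper-triangle blocks so the output is symmetric
    iu = np.triu_indices(k, 1)
    values[(iu[1], iu[0])] = values[iu]
    sizes[(iu[1], iu[0])] = sizes[iu]
    return NetworkBlockPattern(values=values, sizes=sizes, networks=networks)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def cluster_filter(mask: np.ndarray, min_size: int = CLUSTER_MIN_SIZE,
                   connectivity: int = 26) -> np.ndarray:
    """Drop connected components of a 3-D boolean mask not exceeding min_size.

    Components survive only if strictly larger than ``min_size`` voxels.
    ``connectivity`` is the 3-D neighbourhood (6 faces, 18 +edges,
    26 +corners).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("cluster filtering expects a 3-D grid")
    try:
        structure = _STRUCTURES[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.zeros_like(mask)
    sizes = np.bincount(labels.ravel())
    keep = sizes > min_size
    keep[0] = False
    return keep[labels]


def cluster_filter_signed(z_grid: np.ndarray, threshold: float = Z_THRESHOLD,
                          min_size: int = CLUSTER_MIN_SIZE,
                          connectivity: int = 26) -> np.ndarray:
    """Threshold a signed 3-D Z-map and cluster-filter each sign separately.

    Positive (Z > threshold) and negative (Z < -threshold) voxels are
    clustered independently, so touching clusters of opposite sign are
    never merged; the surviving masks are combined.
    """
    z_grid = np.asarray(z_grid, dtype=float)
    with np.errstate(invalid="ignore"):
        pos = z_grid > threshold
        neg = z_grid < -threshold
    return (cluster_filter(pos, min_size, connectivity)
            | cluster_filter(neg, min_size, connectivity))
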