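"""From reconstructed densities to observable graphs.

Low-intensity voxels are removed with a quantile threshold, the surviving
voxels are grouped with DBSCAN, and each cluster's centroid becomes a graph
node; edges then follow the same distance-cutoff rule as control graphs,
with the cutoff measured in pixels.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from .contact import ProteinGraph, graph_from_points
from .tomosim import DensityVolume

#: Default contour level as a fraction of the map maximum. Calibrated once
#: on noise-free full-range reconstructions of the synthetic battery so
#: centroid counts track residue counts, then held fixed across defect
#: regimes (one threshold for the whole study, like an empirically chosen
#: isosurface level).
DEFAULT_FRACTION = 0.5
#: Default for the alternative quantile threshold (fraction of
#: positive-intensity voxels discarded).
DEFAULT_QUANTILE = 0.95
#: DBSCAN neighborhood radius in pixels (same calibration).
DEFAULT_EPS = 1.2
#: Minimum voxels per retained cluster.
DEFAULT_MIN_SAMPLES = 4


@dataclass
class CentroidSet:
    """Cluster centroids of the thresholded density, in pixel coordinates."""

    centroids: np.ndarray  # (k, 3) continuous pixel coordinates
    cluster_sizes: np.ndarray  # (k,) voxel counts
    params: dict

    def __len__(self) -> int:
        return len(self.centroids)


def threshold_volume(volume: DensityVolume, quantile: float) -> tuple[np.ndarray, np.ndarray]:
    """Voxels whose intensity strictly exceeds the q-quantile of positives.

    Returns integer voxel coordinates ``(m, 3)`` and their intensities. An
    all-zero volume yields an empty result.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    grid = np.asarray(volume.grid)
    positive = grid[grid > 0]
    if positive.size == 0:
        return np.empty((0, 3), dtype=int), np.empty(0)
    cut = float(np.quantile(positive, quantile))
    coords = np.argwhere(grid > cut)
    return coords, grid[grid > cut]


def threshold_volume_relative(volume: DensityVolume,
                              fraction: float = DEFAULT_FRACTION
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Voxels above a contour level set at ``fraction`` of the map maximum.

    Unlike the quantile rule, the retained count scales with the amount of
    strong density rather than with the footprint of reconstruction
    artifacts, so one calibrated level transfers across defect regimes.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    grid = np.asarray(volume.grid)
    peak = float(grid.max(initial=0.0))
    if peak <= 0.0:
        return np.empty((0, 3), dtype=int), np.empty(0)
    cut = fraction * peak
    coords = np.argwhere(grid > cut)
    return coords, grid[grid > cut]


def cluster_centroids(
    coords: np.ndarray,
    eps: float = DEFAULT_EPS,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    intensities: np.ndarray | None = None,
    intensity_weighted: bool = False,
) -> CentroidSet:
    """DBSCAN the retained voxels and reduce each cluster to its centroid.

    Noise-labelled voxels are discarded. By default the centroid is the
    unweighted mean of the cluster's voxel coordinates; pass
    ``intensity_weighted=True`` to weight by voxel intensity instead.
    """
    if not eps > 0:
        raise ValueError("eps must be positive")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    coords = np.asarray(coords, dtype=float)
    params = {"eps": eps, "min_samples": min_samples,
              "intensity_weighted": intensity_weighted}
    if len(coords) == 0:
        return CentroidSet(np.empty((0, 3)), np.empty(0, dtype=int), params)

    labels = DBSCAN(eps=eps, min_samples=min_samples).fit(coords).labels_
    cents, sizes = [], []
    for lab in np.unique(labels):
        if lab == -1:
            continue
        mask = labels == lab
        if intensity_weighted and intensities is not None:
            w = np.asarray(intensities, dtype=float)[mask]
            cents.append(np.average(coords[mask], axis=0, weights=w))
        else:
            cents.append(coords[mask].mean(axis=0))
        sizes.append(int(mask.sum()))
    if not cents:
        return CentroidSet(np.empty((0, 3)), np.empty(0, dtype=int), params)
    return CentroidSet(np.array(cents), np.array(sizes), params)


def build_observable_graph(
    volume: DensityVolume,
    d_cut_pixels: float,
    fraction: float = DEFAULT_FRACTION,
    quantile: float | None = None,
    eps: float = DEFAULT_EPS,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    source_id: str = "",
) -> ProteinGraph:
    """Threshold, cluster, and connect centroids closer than ``d_cut_pixels``.

    The threshold is the max-relative contour level ``fraction`` unless a
    ``quantile`` is given, which switches to the quantile-of-positives rule.
    """
    if quantile is not None:
        coords, intens = threshold_volume(volume, quantile)
    else:
        coords, intens = threshold_volume_relative(volume, fraction)
    cset = cluster_centroids(coords, eps=eps, min_samples=min_samples,
                             intensities=intens)
    if len(cset) < 2:
        warnings.warn(
            f"degenerate observable graph: {len(cset)} centroid(s) from "
            f"{len(coords)} thresholded voxels", stacklevel=2)
    if len(cset) == 0:
        raise ValueError("no clusters found; lower the threshold quantile")
    return graph_from_points(cset.centroids, cutoff=d_cut_pixels,
                             role="observable", source_id=source_id)
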