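"""Nuclear-pore spot detection and neighborhood-graph clustering.

Pore coordinates (2D from fluorescence spot detection, 3D from volume-EM
annotation) are clustered by building a neighborhood graph with an edge
between every pair of pores closer than a distance threshold; connected
components of that graph are the clusters.  In 3D the threshold is adjusted
with nucleus size (length scale ~ measure^(1/dim)) so that nuclei of
different sizes are compared fairly; the 2D fluorescence analysis uses a
fixed threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse
import scipy.sparse.csgraph
from scipy.spatial import cKDTree
from skimage.measure import regionprops

from .segmentation import detect_droplets_atrous

__all__ = ["PoreSet", "PoreClusters", "cluster_pores", "detect_pores_2d", "pore_density"]


@dataclass
class PoreSet:
    """Pore coordinates in micrometres plus the nucleus size context.

    ``nucleus_measure`` is a surface area (um^2) in 2D context or a volume
    (um^3) in 3D; it is only needed when the clustering threshold is
    nucleus-size adjusted.
    """

    coords: np.ndarray
    nucleus_measure: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 2)
        if self.coords.shape[1] not in (2, 3):
            raise ValueError("coordinates must be 2D or 3D")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    @property
    def n_pores(self) -> int:
        return self.coords.shape[0]


@dataclass
class PoreClusters:
    """Connected-component cluster labels over a :class:`PoreSet`."""

    labels: np.ndarray
    threshold_um: float

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size) if self.labels.size else 0

    @property
    def cluster_sizes(self) -> np.ndarray:
        if not self.labels.size:
            return np.array([], dtype=int)
        return np.bincount(self.labels)


def cluster_pores(
    pores: PoreSet,
    base_threshold_um: float,
    ref_measure: float | None = None,
    adjust_exponent: float | None = None,
) -> PoreClusters:
    """Cluster pores as connected components of a distance-threshold graph.

    Two pores are joined by an edge iff their distance is strictly below the
    effective threshold.  With ``ref_measure`` given, the threshold is
    rescaled by ``(nucleus_measure / ref_measure) ** adjust_exponent``
    (default exponent 1/dim, turning the measure ratio into a length-scale
    ratio); without it the fixed base threshold is used, as in the 2D
    fluorescence analysis.
    """
    if base_threshold_um <= 0:
        raise ValueError("base threshold must be > 0")
    threshold = float(base_threshold_um)
    if ref_measure is not None:
        if pores.nucleus_measure is None:
            raise ValueError("pore set has no nucleus_measure to adjust with")
        if ref_measure <= 0 or pores.nucleus_measure <= 0:
            raise ValueError("nucleus measures must be > 0")
        expo = 1.0 / pores.dim if adjust_exponent is None else adjust_exponent
        threshold *= (pores.nucleus_measure / ref_measure) ** expo
    n = pores.n_pores
    if n == 0:
        return PoreClusters(np.array([], dtype=int), threshold)
    tree = cKDTree(pores.coords)
    # query_pairs uses closed balls; shrink infinitesimally for strict "<"
    pairs = tree.query_pairs(np.nextafter(threshold, 0.0), output_type="ndarray")
    graph = scipy.sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = scipy.sparse.csgraph.connected_components(graph, directed=False)
    return PoreClusters(labels, threshold)


def detect_pores_2d(
    pore_channel: np.ndarray,
    pixel_size_um: float = 1.0,
    levels: int = 3,
    k_mad: float = 3.0,
    min_px: int = 2,
) -> np.ndarray:
    """Detect pore spots in a 2D image and return centroids in micrometres.

    Runs the shared a trous wavelet spot detector (the image may be a raw
    fluorescence channel or an externally produced pixel-classification
    probability image) and returns an ``(n, 2)`` array of ``(x, y)``
    centroids; two spots closer than the detector's resolution merge into
    one.
    """
    labels = detect_droplets_atrous(
        np.asarray(pore_channel, dtype=float), levels=levels, k_mad=k_mad, min_px=min_px
    )
    cents = [p.centroid for p in regionprops(labels)]
    if not cents:
        return np.empty((0, 2))
    cents = np.asarray(cents)  # (row, col)
    return np.column_stack([cents[:, 1], cents[:, 0]]) * pixel_size_um


def pore_density(n_pores: int, surface_area_um2: float) -> float:
    """Pore surface density in pores per square micrometre."""
    if surface_area_um2 <= 0:
        raise ValueError("surface area must be > 0")
    return n_pores / surface_area_um2
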