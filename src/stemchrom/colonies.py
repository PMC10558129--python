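"""Object detection in calibrated stacks and colony assignment.

Detection follows the published two-step recipe: a blob-enhancing Laplacian
convolution of neighbourhood size ``n`` (implemented as centre minus
neighbourhood mean, which removes any constant offset), then a threshold of
mean + f * std of the filtered image. Objects are connected components above
the threshold (8-connectivity per slice in 2D mode, 26-connectivity in 3D).
Centroids are unweighted voxel means scaled by the per-axis voxel size, and
cells whose centroids lie within 50 um of each other — transitively — form
one colony.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .simulate import ImageStack

DEFAULT_CUTOFF_UM = 50.0

# published parameter presets per staining type
PRESETS = {
    "dapi_2d": {"n": 2, "f": 1.0, "mode": "2D"},
    "fish_2d": {"n": 3, "f": 2.0, "mode": "2D"},
    "colony_3d": {"n": 3, "f": 1.5, "mode": "3D"},  # published 10x 3D preset
}


def enhance(image: ImageStack, n: int, mode: str = "3D") -> ImageStack:
    """Blob-enhancing Laplacian of neighbourhood radius ``n``.

    The kernel is centre minus the mean of a (2n+1)-voxel in-plane
    neighbourhood; in 3D mode the neighbourhood extends in z by the radius
    rescaled for voxel anisotropy (and stays in-plane when a z step covers
    more than the full in-plane neighbourhood).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    data = np.asarray(image.data, float)
    if 2 * n + 1 > min(data.shape[1], data.shape[2]):
        raise ValueError("n larger than image half-extent")
    vx, vy, vz = image.voxel_um
    nz = 0
    if mode == "3D":
        nz = int(round(n * min(vx, vy) / vz))
    size = (2 * nz + 1, 2 * n + 1, 2 * n + 1)
    filtered = data - ndimage.uniform_filter(data, size=size, mode="nearest")
    return ImageStack(data=filtered, voxel_um=image.voxel_um, channel=image.channel)


def segment(filtered: ImageStack, f: float, mode: str = "3D",
            min_size: int = 10) -> np.ndarray:
    """Label connected components above the threshold mean + f * std.

    2D mode labels each z-slice independently with 8-connectivity; 3D mode
    uses 26-connectivity. Components smaller than ``min_size`` voxels are
    discarded. Returns an integer label volume (0 = background).
    """
    if f <= 0:
        raise ValueError("f must be positive")
    data = np.asarray(filtered.data, float)
    threshold = data.mean() + f * data.std()
    mask = data > threshold
    if mode == "3D":
        labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
    elif mode == "2D":
        labels = np.zeros(data.shape, int)
        offset = 0
        for z in range(data.shape[0]):
            lab, k = ndimage.label(mask[z], structure=np.ones((3, 3), int))
            lab[lab > 0] += offset
            labels[z] = lab
            offset += k
    else:
        raise ValueError("mode must be '2D' or '3D'")
    if min_size > 1 and labels.max():
        sizes = np.bincount(labels.ravel())
        small = np.nonzero(sizes < min_size)[0]
        labels[np.isin(labels, small)] = 0
    # relabel consecutively
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(labels.max() + 1, int)
    remap[ids] = np.arange(1, len(ids) + 1)
    return remap[labels]


def centroids(labels: np.ndarray, voxel_um: tuple) -> pd.DataFrame:
    """Physical centroids (um): unweighted voxel centroid times voxel size.

    ``voxel_um`` is (x, y, z); label volumes are (z, y, x).
    """
    vx, vy, vz = voxel_um
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if not len(ids):
        return pd.DataFrame(columns=["object_id", "x_um", "y_um", "z_um", "voxels"])
    coms = ndimage.center_of_mass(np.ones_like(labels), labels, ids)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, ids).astype(int)
    coms = np.asarray(coms, float)
    return pd.DataFrame({
        "object_id": ids,
        "x_um": coms[:, 2] * vx,
        "y_um": coms[:, 1] * vy,
        "z_um": coms[:, 0] * vz,
        "voxels": sizes,
    })


def cluster_colonies(points_um: np.ndarray, cutoff: float = DEFAULT_CUTOFF_UM) -> np.ndarray:
    """Colony ids: connected components of the graph with edges between
    centroids at Euclidean distance strictly less than ``cutoff``.

    Transitive: chains of sub-cutoff links merge into one colony.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pts = np.asarray(points_um, float).reshape(-1, 3)
    n = len(pts)
    if n == 0:
        return np.zeros(0, int)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        # strict inequality: discard pairs at exactly the cutoff
        d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff]
    graph = csr_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, comp = connected_components(graph, directed=False)
    # renumber in order of first appearance for determinism
    remap = {c: k for k, c in enumerate(dict.fromkeys(comp))}
    return np.array([remap[c] for c in comp], dtype=int)


def detect_objects(image: ImageStack, n: int, f: float, mode: str = "3D",
                   min_size: int = 10) -> pd.DataFrame:
    """Enhance, segment and measure in one call."""
    labels = segment(enhance(image, n, mode=mode), f, mode=mode, min_size=min_size)
    return centroids(labels, image.voxel_um)


@dataclass
class ColonySet:
    objects: pd.DataFrame      # object_id, centroid um, voxels, colony_id

    def colony_sizes(self) -> pd.Series:
        return self.objects.groupby("colony_id").size().rename("cells")

    def write(self, path) -> None:
        self.objects.to_csv(path, index=False)


def assign_colonies(objects: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF_UM) -> ColonySet:
    objects = objects.copy()
    pts = objects[["x_um", "y_um", "z_um"]].to_numpy()
    objects["colony_id"] = cluster_colonies(pts, cutoff)
    return ColonySet(objects=objects)


def density_and_counts(marker_objects: pd.DataFrame, dapi_objects: pd.DataFrame,
                       cutoff: float = DEFAULT_CUTOFF_UM):
    """Marker abundance normalised to nuclei count, plus the colony size table.

    Returns (abundance, colony size table). Zero DAPI objects leave the
    abundance undefined (NaN) with a warning.
    """
    import warnings

    n_marker = len(marker_objects)
    n_dapi = len(dapi_objects)
    if n_dapi == 0:
        warnings.warn("no DAPI-positive nuclei detected; abundance undefined")
        abundance = float("nan")
    else:
        abundance = n_marker / n_dapi
    sizes = assign_colonies(marker_objects, cutoff).colony_sizes() if n_marker else \
        pd.Series(dtype=int, name="cells")
    return abundance, sizes
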