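"""PCA denoising of voxel time courses and ward clustering with selection.

Voxel time courses (percent signal change) are arranged as a voxels x frames
matrix. Group-average matrices are reconstructed from the leading principal
components (the three largest typically explain >99% of the variability for
contrast-injected cohorts), then partitioned by agglomerative ward clustering
cut at a fixed number of clusters. Clusters are kept for kinetic analysis when
they are large enough and show a real intensity excursion — small or flat
clusters reflect noise-level signal variability, as seen in non-injected
control cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .preprocess import NormalizedSeries

__all__ = [
    "VoxelTimeCourseMatrix",
    "PCAReconstruction",
    "ClusterMap",
    "matrix_from_series",
    "group_average_matrix",
    "pca_reconstruct",
    "ward_cluster",
    "select_clusters",
    "extract_cluster_timecourses",
]


@dataclass
class VoxelTimeCourseMatrix:
    """Masked voxels x frames matrix — the common currency of the analysis.

    ``voxel_index_map`` holds the (i, j, k) coordinate of each row, so cluster
    labelings can be painted back onto the image grid.
    """

    values: np.ndarray  # (n_voxels, n_frames)
    voxel_index_map: np.ndarray  # (n_voxels, 3) int
    frame_times_min: np.ndarray
    level: str = "subject"  # "subject" | "group-average"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_index_map = np.asarray(self.voxel_index_map)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (voxels x frames)")
        if self.values.shape[0] != self.voxel_index_map.shape[0]:
            raise ValueError("row count must equal voxel_index_map length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time-course matrix contains non-finite entries")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def same_voxel_map(self, other: "VoxelTimeCourseMatrix") -> bool:
        return (
            self.voxel_index_map.shape == other.voxel_index_map.shape
            and np.array_equal(self.voxel_index_map, other.voxel_index_map)
        )


def matrix_from_series(series: NormalizedSeries, mask: np.ndarray) -> VoxelTimeCourseMatrix:
    """Extract the in-mask voxel time courses of a normalized series."""
    mask = np.asarray(mask, bool)
    if mask.shape != series.grid_shape:
        raise ValueError("mask grid does not match series grid")
    coords = np.argwhere(mask)
    return VoxelTimeCourseMatrix(
        values=series.data[mask],
        voxel_index_map=coords,
        frame_times_min=series.frame_times_min.copy(),
        level="subject",
    )


def group_average_matrix(matrices: list[VoxelTimeCourseMatrix]) -> VoxelTimeCourseMatrix:
    """Element-wise mean over subjects sharing one voxel map."""
    if not matrices:
        raise ValueError("need at least one matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if not first.same_voxel_map(m):
            raise ValueError("voxel maps differ across subjects; no implicit alignment")
        if m.values.shape != first.values.shape:
            raise ValueError("matrix shapes differ across subjects")
    mean = np.mean([m.values for m in matrices], axis=0)
    return VoxelTimeCourseMatrix(
        values=mean,
        voxel_index_map=first.voxel_index_map.copy(),
        frame_times_min=first.frame_times_min.copy(),
        level="group-average",
    )


@dataclass
class PCAReconstruction:
    """Low-rank reconstruction of a time-course matrix."""

    n_components: int
    explained_variance_fractions: np.ndarray
    reconstructed: np.ndarray
    mean_timecourse: np.ndarray = field(default_factory=lambda: np.empty(0))


def pca_reconstruct(
    matrix: VoxelTimeCourseMatrix,
    variance_threshold: float = 0.99,
    max_components: int | None = 3,
) -> PCAReconstruction:
    """Denoise by projecting onto the leading principal components.

    The voxel-mean time course is removed before the eigendecomposition and
    restored on reconstruction (uncentered PCA would confound the global
    uptake curve with component 1). The smallest number of components whose
    cumulative explained variance reaches ``variance_threshold`` is retained,
    capped at ``max_components``.
    """
    if not (0.0 < variance_threshold <= 1.0):
        raise ValueError("variance_threshold must be in (0, 1]")
    X = matrix.values
    if X.shape[1] < 2:
        raise ValueError("need at least 2 frames for PCA")
    if X.shape[0] < X.shape[1]:
        warnings.warn(
            f"fewer voxels ({X.shape[0]}) than frames ({X.shape[1]}); "
            "components may be poorly determined",
            stacklevel=2,
        )
    mean_tc = X.mean(axis=0)
    Xc = X - mean_tc
    # thin SVD over the frame dimension; rows are observations
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= np.finfo(float).eps * X.size:
        warnings.warn("constant matrix: nothing to reconstruct, 0 components", stacklevel=2)
        return PCAReconstruction(
            n_components=0,
            explained_variance_fractions=np.zeros(0),
            reconstructed=X.copy(),
            mean_timecourse=mean_tc,
        )
    fractions = var / total
    cumulative = np.cumsum(fractions)
    k = int(np.searchsorted(cumulative, variance_threshold - 1e-12) + 1)
    if max_components is not None:
        k = min(k, max_components)
    k = min(k, s.size)
    recon = (U[:, :k] * s[:k]) @ Vt[:k] + mean_tc
    return PCAReconstruction(
        n_components=k,
        explained_variance_fractions=fractions[:k],
        reconstructed=recon,
        mean_timecourse=mean_tc,
    )


@dataclass
class ClusterMap:
    """Voxel-to-cluster labeling with per-cluster summaries and selection flags.

    Cluster ids are 1..K sorted by voxel count smallest to largest (id 1 is
    the smallest cluster).
    """

    labels: np.ndarray  # (n_voxels,) int, 1..K
    voxel_index_map: np.ndarray
    frame_times_min: np.ndarray
    cluster_sizes: np.ndarray  # (K,)
    cluster_mean_tc: np.ndarray  # (K, n_frames)
    cluster_sd_tc: np.ndarray  # (K, n_frames)
    selected: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    def __post_init__(self) -> None:
        if self.cluster_sizes.sum() != self.labels.size:
            raise ValueError("cluster sizes must sum to the number of voxels")

    @property
    def n_clusters(self) -> int:
        return self.cluster_sizes.size

    def cluster_range(self, k: int) -> float:
        """Max - min of cluster k's mean time course (percent points)."""
        tc = self.cluster_mean_tc[k - 1]
        return float(tc.max() - tc.min())

    def selected_ids(self) -> list[int]:
        return [k + 1 for k in range(self.n_clusters) if self.selected[k]]

    def paint(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        """Render the labeling as a 3D volume (0 outside the voxel map)."""
        vol = np.zeros(grid_shape, dtype=np.int32)
        idx = self.voxel_index_map
        vol[idx[:, 0], idx[:, 1], idx[:, 2]] = self.labels
        return vol


def ward_cluster(matrix: VoxelTimeCourseMatrix, max_clusters: int = 15) -> ClusterMap:
    """Agglomerative ward clustering of voxel time courses, flat cut at
    ``max_clusters``.

    Euclidean distance (ward's canonical metric) on the full time courses;
    ids are relabeled so that cluster 1 is the smallest by voxel count. The
    result is deterministic for a given input ordering.
    """
    if max_clusters <= 0:
        raise ValueError("max_clusters must be positive")
    if matrix.n_voxels < max_clusters:
        raise ValueError(
            f"{matrix.n_voxels} voxels cannot form {max_clusters} clusters"
        )
    Z = linkage(matrix.values, method="ward")
    raw = fcluster(Z, t=max_clusters, criterion="maxclust")
    # relabel by size, smallest -> 1; ties broken by original cluster id
    ids, counts = np.unique(raw, return_counts=True)
    order = np.lexsort((ids, counts))
    remap = np.zeros(ids.max() + 1, dtype=int)
    for new, old in enumerate(ids[order], start=1):
        remap[old] = new
    labels = remap[raw]
    K = ids.size
    sizes = np.zeros(K, dtype=int)
    mean_tc = np.zeros((K, matrix.n_frames))
    sd_tc = np.zeros((K, matrix.n_frames))
    for k in range(1, K + 1):
        rows = matrix.values[labels == k]
        sizes[k - 1] = rows.shape[0]
        mean_tc[k - 1] = rows.mean(axis=0)
        sd_tc[k - 1] = rows.std(axis=0)
    return ClusterMap(
        labels=labels,
        voxel_index_map=matrix.voxel_index_map.copy(),
        frame_times_min=matrix.frame_times_min.copy(),
        cluster_sizes=sizes,
        cluster_mean_tc=mean_tc,
        cluster_sd_tc=sd_tc,
        selected=np.zeros(K, dtype=bool),
    )


def select_clusters(
    cmap: ClusterMap, min_voxels: int = 100, min_range_percent: float = 10.0
) -> ClusterMap:
    """Flag clusters worth modelling: at least ``min_voxels`` voxels and a
    mean-time-course excursion strictly greater than ``min_range_percent``.

    The range criterion is evaluated on the group-level cluster-mean trace;
    its default reflects the noise-level variability of non-injected cohorts.
    Idempotent; nothing but the flags is altered.
    """
    ranges = cmap.cluster_mean_tc.max(axis=1) - cmap.cluster_mean_tc.min(axis=1)
    selected = (cmap.cluster_sizes >= min_voxels) & (ranges > min_range_percent)
    return replace(cmap, selected=selected)


def extract_cluster_timecourses(
    cmap: ClusterMap, subject_matrix: VoxelTimeCourseMatrix
) -> np.ndarray:
    """Per-cluster mean time courses of one subject, using a reference map.

    The reference clusters may come from either group's map, so the same
    voxel sets are compared across groups. Returns a (K, n_frames) array.
    """
    if cmap.voxel_index_map.shape != subject_matrix.voxel_index_map.shape or not np.array_equal(
        cmap.voxel_index_map, subject_matrix.voxel_index_map
    ):
        raise ValueError("subject matrix voxel map does not match the cluster map")
    K = cmap.n_clusters
    out = np.zeros((K, subject_matrix.n_frames))
    for k in range(1, K + 1):
        out[k - 1] = subject_matrix.values[cmap.labels == k].mean(axis=0)
    return out
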