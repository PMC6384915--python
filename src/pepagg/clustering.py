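"""Peptide contact-graph clustering and mean cluster size.

Two peptides are in contact when any two of their atoms are closer than the
sum of their van der Waals radii (minimum image).  A cluster is a connected
component of the contact graph; the cluster size CS of a peptide is the
size of its component, and the mean cluster size

    MCS(t) = sum_i CS_i(t) / N

averages CS over the N peptides (so each cluster is weighted by its size:
MCS = sum_clusters size^2 / N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import Frame, Topology, Trajectory
from .geometry import periodic_pairs


@dataclass
class ClusterAssignment:
    """Per-frame clustering: labels and cluster sizes per peptide."""

    frame_time: float
    labels: np.ndarray  # (n_peptides,) component id
    cluster_sizes: np.ndarray  # (n_peptides,) CS_{i,t}

    @property
    def mcs(self) -> float:
        return float(np.mean(self.cluster_sizes))

    def size_histogram(self, n_peptides: int) -> np.ndarray:
        """Number of clusters of each size 1..N (index s-1 = count of s-mers)."""
        hist = np.zeros(n_peptides, dtype=int)
        for label in np.unique(self.labels):
            size = int(np.sum(self.labels == label))
            hist[size - 1] += 1
        return hist


@dataclass
class ClusterSeries:
    """Time-ordered cluster assignments with the MCS series."""

    assignments: list[ClusterAssignment]
    n_peptides: int

    @property
    def times(self) -> np.ndarray:
        return np.array([a.frame_time for a in self.assignments])

    @property
    def mcs(self) -> np.ndarray:
        return np.array([a.mcs for a in self.assignments])

    @property
    def cluster_sizes(self) -> np.ndarray:
        """(n_frames, n_peptides) array of CS_{i,t}."""
        return np.stack([a.cluster_sizes for a in self.assignments])


def contact_adjacency(
    frame: Frame, topology: Topology, heavy_only: bool = False
) -> np.ndarray:
    """Symmetric boolean peptide-pair contact matrix for one frame.

    Pair (i, j) is adjacent iff some atom pair (a in i, b in j) has
    minimum-image distance strictly below r_vdw(a) + r_vdw(b).  With
    ``heavy_only`` hydrogens are ignored (for H-less inputs).
    """
    if frame.coordinates.shape[0] != topology.n_atoms:
        raise ValueError("frame atom count does not match topology")
    coords = frame.coordinates
    radii = topology.vdw_radii
    pep = topology.atom_peptide
    if heavy_only:
        keep = topology.elements != "H"
        coords, radii, pep = coords[keep], radii[keep], pep[keep]
    cutoff = 2.0 * float(radii.max())
    pairs = periodic_pairs(coords, cutoff, frame.box_edge)
    n = topology.n_peptides
    adj = np.zeros((n, n), dtype=bool)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        d = np.sqrt(
            np.sum(
                (
                    (coords[i] - coords[j])
                    - frame.box_edge
                    * np.round((coords[i] - coords[j]) / frame.box_edge)
                )
                ** 2,
                axis=1,
            )
        )
        hit = (d < radii[i] + radii[j]) & (pep[i] != pep[j])
        pi, pj = pep[i[hit]], pep[j[hit]]
        adj[pi, pj] = True
        adj[pj, pi] = True
    return adj


def find_clusters(adjacency: np.ndarray) -> np.ndarray:
    """Connected-component label per peptide (labels ordered by first member)."""
    adjacency = np.asarray(adjacency)
    if not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    _, labels = connected_components(csr_matrix(adjacency), directed=False)
    return labels


def cluster_sizes_from_labels(labels: np.ndarray) -> np.ndarray:
    """CS per peptide from component labels."""
    counts = np.bincount(labels)
    return counts[labels]


def mean_cluster_size(cluster_sizes: np.ndarray) -> float:
    """Mean cluster size: the per-peptide average of CS."""
    cs = np.asarray(cluster_sizes)
    n = len(cs)
    if np.any(cs < 1) or np.any(cs > n):
        raise ValueError("cluster sizes must lie in 1..N")
    return float(np.mean(cs))


def assign_frame(
    frame: Frame, topology: Topology, heavy_only: bool = False
) -> ClusterAssignment:
    adj = contact_adjacency(frame, topology, heavy_only=heavy_only)
    labels = find_clusters(adj)
    return ClusterAssignment(
        frame_time=frame.time,
        labels=labels,
        cluster_sizes=cluster_sizes_from_labels(labels),
    )


def mcs_time_series(
    trajectory: Trajectory, heavy_only: bool = False
) -> ClusterSeries:
    """Cluster every frame and collect the MCS time series."""
    assignments = [
        assign_frame(fr, trajectory.topology, heavy_only=heavy_only)
        for fr in trajectory.frames
    ]
    return ClusterSeries(assignments, trajectory.topology.n_peptides)


def window_average_mcs(
    series: ClusterSeries, t_start: float, t_end: float
) -> float:
    """Unweighted mean of per-frame MCS over frames with t in [t_start, t_end]."""
    times = series.times
    mask = (times >= t_start) & (times <= t_end)
    if not np.any(mask):
        raise ValueError(
            f"no frames in window [{t_start}, {t_end}] ps"
        )
    return float(np.mean(series.mcs[mask]))
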