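"""Inter-element distances, spatial clusters and patch construction.

Patches define the design "area": the set of segments (or individual
residues) gathered within a radius of a reference G point.  Three patch
modes exist: fixed 10 A, fixed 15 A, and a varying 15-20 A radius chosen by
a mean-count rule over the six integer radii.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

__all__ = [
    "DistanceMatrix",
    "Patch",
    "Cluster",
    "element_points",
    "distance_matrix",
    "build_patch",
    "varying_patch_radius",
    "build_varying_patch",
    "choose_varying_radius",
    "cluster_segments",
]

VARYING_RADIUS_GRID = (15, 16, 17, 18, 19, 20)
DEFAULT_CLUSTER_THRESHOLD = 10.0


def element_points(elements: Sequence) -> np.ndarray:
    """Representative point per element: segment G point or residue C-alpha."""
    points = []
    for el in elements:
        if hasattr(el, "g_point"):
            points.append(el.g_point)
        elif hasattr(el, "ca"):
            points.append(el.ca)
        else:
            raise TypeError(f"element {el!r} has neither a G point nor a CA atom")
    return np.asarray(points, dtype=float)


def element_id(el) -> Hashable:
    """Public id of an element: segment id or residue key."""
    if hasattr(el, "g_point"):
        return el.id
    return el.key


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric Euclidean distances between element representative points."""

    ids: tuple[Hashable, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "_pos", {eid: i for i, eid in enumerate(self.ids)})

    def distance(self, a: Hashable, b: Hashable) -> float:
        return float(self.matrix[self._pos[a], self._pos[b]])


@dataclass(frozen=True)
class Patch:
    """Elements within ``radius`` of the reference G point (boundary inclusive)."""

    reference: Hashable
    mode: str               # "fixed10" | "fixed15" | "varying" | "custom"
    radius: float
    members: tuple[Hashable, ...]

    def __contains__(self, eid: Hashable) -> bool:
        return eid in self.members


@dataclass(frozen=True)
class Cluster:
    """A group of segments from single-linkage clustering at a threshold."""

    members: tuple[Hashable, ...]
    threshold: float


def distance_matrix(elements: Sequence) -> DistanceMatrix:
    """Pairwise Euclidean distances between segment G points or residue CAs."""
    if len(elements) == 0:
        raise ValueError("need at least one element")
    points = element_points(elements)
    ids = tuple(element_id(el) for el in elements)
    return DistanceMatrix(ids=ids, matrix=cdist(points, points))


def build_patch(
    reference,
    elements: Sequence,
    radius: float,
    mode: str = "custom",
) -> Patch:
    """Gather the elements inside ``radius`` of the reference's G point.

    The reference is always a member; the boundary is inclusive (<= radius).
    """
    ref_id = element_id(reference)
    ids = [element_id(el) for el in elements]
    if ref_id not in ids:
        raise KeyError(f"reference {ref_id} not among the candidate elements")
    points = element_points(elements)
    ref_point = element_points([reference])[0]
    dists = np.linalg.norm(points - ref_point, axis=1)
    members = tuple(
        eid for eid, d in zip(ids, dists) if d <= radius or eid == ref_id
    )
    return Patch(reference=ref_id, mode=mode, radius=radius, members=members)


def choose_varying_radius(counts: Mapping[int, int]) -> int:
    """Pick the radius whose count is closest to the mean count.

    ``counts`` maps each radius of the 15-20 A grid to the number of residues
    it collects; the target is the arithmetic mean of the six counts and ties
    resolve to the smaller radius.
    """
    missing = [r for r in VARYING_RADIUS_GRID if r not in counts]
    if missing:
        raise KeyError(f"counts missing radii {missing}")
    target = np.mean([counts[r] for r in VARYING_RADIUS_GRID])
    return min(VARYING_RADIUS_GRID, key=lambda r: (abs(counts[r] - target), r))


def varying_patch_radius(reference, residues: Sequence) -> int:
    """Varying-patch radius (15-20 A) for a reference over surface residues."""
    ref_point = element_points([reference])[0]
    points = element_points(residues)
    dists = np.linalg.norm(points - ref_point, axis=1)
    counts = {r: int(np.sum(dists <= r)) for r in VARYING_RADIUS_GRID}
    return choose_varying_radius(counts)


def build_varying_patch(reference, residues: Sequence) -> Patch:
    """The varying-mode patch: residues within the mean-count radius."""
    radius = varying_patch_radius(reference, residues)
    patch = build_patch(reference, residues, radius=float(radius), mode="varying")
    return patch


def cluster_segments(
    matrix: DistanceMatrix,
    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
) -> list[Cluster]:
    """Single-linkage agglomerative clustering cut at ``threshold`` (A).

    Clusters partition the segment set; elements whose minimum inter-cluster
    distance exceeds the threshold end up in different clusters.
    """
    n = len(matrix.ids)
    if n == 1:
        return [Cluster(members=(matrix.ids[0],), threshold=threshold)]
    condensed = squareform(matrix.matrix, checks=False)
    labels = fcluster(linkage(condensed, method="single"), t=threshold, criterion="distance")
    clusters: dict[int, list[Hashable]] = {}
    for eid, label in zip(matrix.ids, labels):
        clusters.setdefault(label, []).append(eid)
    return [
        Cluster(members=tuple(members), threshold=threshold)
        for _, members in sorted(clusters.items())
    ]
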