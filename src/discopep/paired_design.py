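"""Paired peptide design: anchoring peptides at distant surface residues.

To raise antibody pairs able to capture an antigen simultaneously (sandwich
format), up to five pairs of mutually distant surface residues are
constructed geometrically:

1. the two most distant surface-accessible residues of the protein;
2. the two most distant residues within 5 A of the plane orthogonal to the
   first pair's axis through its midpoint;
3. the two most distant residues inside the 10 A-thick perpendicular
   bisector of both pairs (within +/- 5 A of each pair's bisector plane);
4./5. alternatives to pairs 2/3: one endpoint of the source pair combined
   with the farthest surface residue (the source pair's other endpoint is
   excluded so the alternative is distinct).

Each endpoint then seeds one peptide: the containing segment (or the residue
itself for residue-level methods) becomes the design reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .design_methods import DesignContext, DesignedPeptide, design, get_method
from .structure_io import Residue

__all__ = [
    "DistantPair",
    "PairedPeptideSet",
    "DegeneratePairError",
    "most_distant_pair",
    "second_pair",
    "third_pair",
    "alternate_pairs",
    "design_paired",
    "pair_table",
]

PLANE_TOLERANCE = 5.0
SLAB_THICKNESS = 10.0


class DegeneratePairError(ValueError):
    """Raised when a pair construction has fewer than two candidates."""


@dataclass(frozen=True)
class DistantPair:
    """Two mutually distant surface residues with construction provenance."""

    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    distance: float
    rank: int
    rule: str   # primary | orthogonal_plane | bisector | alternate_of_2 | alternate_of_3

    def __post_init__(self) -> None:
        if self.residue_a == self.residue_b:
            raise ValueError("a distant pair needs two distinct residues")

    @property
    def keys(self) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
        return (self.residue_a, self.residue_b)


@dataclass(frozen=True)
class PairedPeptideSet:
    """The constructed pairs and the peptide designed from each endpoint."""

    pairs: tuple[DistantPair, ...]
    peptides: tuple[tuple[DesignedPeptide, DesignedPeptide], ...]


def _points_and_keys(residues: list[Residue]) -> tuple[np.ndarray, list]:
    ordered = sorted(residues, key=lambda r: r.key)
    return np.array([r.ca for r in ordered]), [r.key for r in ordered]


def _max_pair(points: np.ndarray, keys: list, mask=None) -> tuple[int, int, float]:
    """Indices and distance of the most distant pair; ties -> smallest keys.

    ``mask`` restricts candidates to a boolean subset.  Keys are pre-sorted,
    so the (i, j) scan order realises the ascending-key tie-break.
    """
    idx = np.arange(len(keys)) if mask is None else np.flatnonzero(mask)
    if len(idx) < 2:
        raise DegeneratePairError("fewer than two candidate residues")
    sub = points[idx]
    d = cdist(sub, sub)
    np.fill_diagonal(d, -1.0)
    best = float(d.max())
    ii, jj = np.argwhere(np.isclose(d, best, rtol=0.0, atol=1e-9))[0]
    if ii > jj:
        ii, jj = jj, ii
    return int(idx[ii]), int(idx[jj]), best


def most_distant_pair(
    residues: list[Residue],
    anchor: tuple[str, int, str] | None = None,
) -> DistantPair:
    """The two most distant surface residues (exhaustive O(n^2) scan).

    With ``anchor`` given, the pair is the anchor and its farthest surface
    residue, letting the user orientate the whole paired design.
    """
    points, keys = _points_and_keys(residues)
    if len(keys) < 2:
        raise DegeneratePairError("need at least two surface residues")
    if anchor is not None:
        if anchor not in keys:
            raise KeyError(f"anchor residue {anchor} is not surface-accessible")
        ai = keys.index(anchor)
        d = np.linalg.norm(points - points[ai], axis=1)
        d[ai] = -1.0
        bi = int(np.flatnonzero(np.isclose(d, d.max(), atol=1e-9))[0])
        a, b = sorted((ai, bi))
        return DistantPair(keys[a], keys[b], float(np.linalg.norm(points[a] - points[b])),
                           rank=1, rule="primary")
    i, j, dist = _max_pair(points, keys)
    return DistantPair(keys[i], keys[j], dist, rank=1, rule="primary")


def _axis(points: np.ndarray, keys: list, pair: DistantPair) -> np.ndarray:
    a = points[keys.index(pair.residue_a)]
    b = points[keys.index(pair.residue_b)]
    v = b - a
    norm = np.linalg.norm(v)
    if norm == 0.0:
        raise DegeneratePairError("pair axis has zero length")
    return v / norm


def second_pair(
    residues: list[Residue],
    pair1: DistantPair,
    plane_tolerance: float = PLANE_TOLERANCE,
) -> DistantPair:
    """Most distant pair within ``plane_tolerance`` of the orthogonal plane.

    The plane is orthogonal to the pair-1 axis and passes through the pair-1
    midpoint; the band is inclusive (|signed distance| <= tolerance).
    """
    points, keys = _points_and_keys(residues)
    u = _axis(points, keys, pair1)
    mid = 0.5 * (
        points[keys.index(pair1.residue_a)] + points[keys.index(pair1.residue_b)]
    )
    signed = (points - mid) @ u
    mask = np.abs(signed) <= plane_tolerance
    try:
        i, j, dist = _max_pair(points, keys, mask)
    except DegeneratePairError:
        raise DegeneratePairError(
            f"fewer than two residues within {plane_tolerance:g} A of the "
            "plane orthogonal to pair 1"
        ) from None
    return DistantPair(keys[i], keys[j], dist, rank=2, rule="orthogonal_plane")


def third_pair(
    residues: list[Residue],
    pair1: DistantPair,
    pair2: DistantPair,
    slab_thickness: float = SLAB_THICKNESS,
) -> DistantPair:
    """Most distant pair inside the perpendicular bisector of both pairs.

    Each pair defines a perpendicular-bisector plane (orthogonal to its axis,
    through its midpoint); a candidate must lie within ``slab_thickness/2``
    of *both* planes, i.e. in the intersection of the two thick bisectors.
    This keeps pair 3 roughly orthogonal to, and distinct from, pairs 1-2.
    """
    points, keys = _points_and_keys(residues)
    mask = np.ones(len(keys), dtype=bool)
    for pair in (pair1, pair2):
        u = _axis(points, keys, pair)
        mid = 0.5 * (
            points[keys.index(pair.residue_a)] + points[keys.index(pair.residue_b)]
        )
        signed = (points - mid) @ u
        mask &= np.abs(signed) <= slab_thickness / 2.0
    try:
        i, j, dist = _max_pair(points, keys, mask)
    except DegeneratePairError:
        raise DegeneratePairError(
            f"fewer than two residues inside the {slab_thickness:g} A bisector slab"
        ) from None
    return DistantPair(keys[i], keys[j], dist, rank=3, rule="bisector")


def _alternate(
    points: np.ndarray,
    keys: list,
    source: DistantPair,
    rank: int,
    rule: str,
) -> DistantPair:
    """Alternative pair: a source endpoint with the farthest surface residue,
    excluding the source pair's other endpoint (keeps it distinct)."""
    best = None
    for endpoint, excluded in (
        (source.residue_a, source.residue_b),
        (source.residue_b, source.residue_a),
    ):
        ei = keys.index(endpoint)
        d = np.linalg.norm(points - points[ei], axis=1)
        d[ei] = -1.0
        d[keys.index(excluded)] = -1.0
        if np.all(d < 0):
            continue
        pi = int(np.flatnonzero(np.isclose(d, d.max(), atol=1e-9))[0])
        cand = (float(d[pi]), tuple(sorted((keys[ei], keys[pi]))))
        if best is None or cand[0] > best[0] + 1e-9 or (
            abs(cand[0] - best[0]) <= 1e-9 and cand[1] < best[1]
        ):
            best = cand
    if best is None:
        raise DegeneratePairError(f"no partner available for alternative pair {rank}")
    a, b = best[1]
    return DistantPair(a, b, best[0], rank=rank, rule=rule)


def alternate_pairs(
    residues: list[Residue],
    pair2: DistantPair | None,
    pair3: DistantPair | None,
) -> tuple[DistantPair | None, DistantPair | None]:
    """Pairs 4 and 5: alternatives derived from pairs 2 and 3."""
    points, keys = _points_and_keys(residues)
    pair4 = pair5 = None
    if pair2 is not None:
        pair4 = _alternate(points, keys, pair2, rank=4, rule="alternate_of_2")
    if pair3 is not None:
        pair5 = _alternate(points, keys, pair3, rank=5, rule="alternate_of_3")
    return pair4, pair5


def build_pairs(
    residues: list[Residue],
    anchor: tuple[str, int, str] | None = None,
    plane_tolerance: float = PLANE_TOLERANCE,
    slab_thickness: float = SLAB_THICKNESS,
) -> list[DistantPair]:
    """All constructible pairs in rank order; degenerate ones are omitted."""
    pairs: list[DistantPair] = []
    pair1 = most_distant_pair(residues, anchor=anchor)
    pairs.append(pair1)
    pair2 = pair3 = None
    try:
        pair2 = second_pair(residues, pair1, plane_tolerance)
        pairs.append(pair2)
    except DegeneratePairError:
        pass
    if pair2 is not None:
        try:
            pair3 = third_pair(residues, pair1, pair2, slab_thickness)
            pairs.append(pair3)
        except DegeneratePairError:
            pass
    try:
        pair4, pair5 = alternate_pairs(residues, pair2, pair3)
    except DegeneratePairError:
        pair4 = pair5 = None
    if pair4 is not None:
        pairs.append(pair4)
    if pair5 is not None:
        pairs.append(pair5)
    return pairs


def design_paired(
    ctx: DesignContext,
    method_name: str = "NN",
    target_length: int = 10,
    anchor: tuple[str, int, str] | None = None,
    options=None,
) -> PairedPeptideSet:
    """Construct the distant pairs and design one peptide per endpoint.

    Segment-level methods use each endpoint's containing segment as the
    design reference; residue-level methods use the endpoint itself.
    """
    surface = ctx.accessible_residues()
    if len(surface) < 2:
        raise DegeneratePairError("need at least two surface residues")
    desc = get_method(method_name)
    pairs = build_pairs(surface, anchor=anchor)
    peptides = []
    for pair in pairs:
        endpoint_peps = []
        for key in pair.keys:
            ref = key if desc.element_kind == "aa" else ctx.segment_containing(key)
            endpoint_peps.append(
                design(desc.name, ctx, ref, target_length, options)
            )
        peptides.append(tuple(endpoint_peps))
    return PairedPeptideSet(pairs=tuple(pairs), peptides=tuple(peptides))


def pair_table(result: PairedPeptideSet) -> pd.DataFrame:
    """TSV-exportable report: rank, rule, residues, distance, sequences."""
    rows = []
    for pair, (pep_a, pep_b) in zip(result.pairs, result.peptides):
        rows.append(
            {
                "rank": pair.rank,
                "rule": pair.rule,
                "residue_a": f"{pair.residue_a[0]}:{pair.residue_a[1]}{pair.residue_a[2]}",
                "residue_b": f"{pair.residue_b[0]}:{pair.residue_b[1]}{pair.residue_b[2]}",
                "distance_A": round(pair.distance, 3),
                "peptide_a": pep_a.sequence,
                "peptide_b": pep_b.sequence,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["rank", "rule", "residue_a", "residue_b",
                 "distance_A", "peptide_a", "peptide_b"],
    )
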