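"""The 35 design methods and the dispatcher turning a reference into a peptide.

Method families
---------------
- sequential (1): FPS extends a segment along the native chain sequence — the
  only continuous-epitope method.
- prime (6): NN, uNN, FNN, ONN, OFN, OPP concatenate nearest-neighbour
  segments without linkers; O-variants re-order the selected segments by
  shortest through-space path.
- prime + linkers (16): the ALA (6), SA (5) and SAS (5) variants insert
  computed linkers at the junctions of their base prime method.
- graph theory (12): SHP methods route segments (or residues) with Dijkstra
  through a proximity graph; TSP methods solve an exact shortest open tour.

Whole elements only: a segment is never split; assembly stops at the first
size >= the requested peptide length (FPS trims to the exact length).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Hashable, Mapping, Sequence

import numpy as np

from .linkers import DEFAULT_SPAN, LinkerSpec, make_linker
from .pathing import (
    NATURAL,
    OrientedElement,
    PathNode,
    PathSolution,
    _chain_orientations,
    _id_key,
    _solution,
    dijkstra_route,
    greedy_nn_order,
    shortest_path_order,
)
from .segmentation import Segment, build_segments
from .structure_io import ProteinStructure, Residue
from .surface import AccessibilityProfile, surface_profile
from .topology import (
    DEFAULT_CLUSTER_THRESHOLD,
    build_patch,
    cluster_segments,
    distance_matrix,
    varying_patch_radius,
)

__all__ = [
    "MethodDescriptor",
    "Part",
    "DesignedPeptide",
    "DesignContext",
    "registry",
    "get_method",
    "method_names",
    "expand_method_selection",
    "fps",
    "design",
    "assemble",
]


# ---------------------------------------------------------------------------
# Method registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethodDescriptor:
    """Static description of one design method."""

    name: str
    family: str            # sequential | prime | prime_ala | prime_sa | prime_sas | shp | tsp
    element_kind: str      # segment | aa
    orientation: str       # natural_only | reversible
    linker_policy: str     # none | ALA | SA | SAS
    ordering: str          # fps | greedy_c | flanking | opt_nn | opt_flanking |
                           # opt_patch | dijkstra | tsp1..tsp4 | tsp_aa
    epitope_type: str      # continuous | discontinuous
    base: str | None = None  # prime method a linker variant decorates


def _descriptors() -> tuple[MethodDescriptor, ...]:
    out: list[MethodDescriptor] = [
        MethodDescriptor("FPS", "sequential", "segment", "natural_only",
                         "none", "fps", "continuous"),
        MethodDescriptor("NN", "prime", "segment", "natural_only",
                         "none", "greedy_c", "discontinuous"),
        MethodDescriptor("uNN", "prime", "segment", "reversible",
                         "none", "greedy_c", "discontinuous"),
        MethodDescriptor("FNN", "prime", "segment", "natural_only",
                         "none", "flanking", "discontinuous"),
        MethodDescriptor("ONN", "prime", "segment", "natural_only",
                         "none", "opt_nn", "discontinuous"),
        MethodDescriptor("OFN", "prime", "segment", "natural_only",
                         "none", "opt_flanking", "discontinuous"),
        MethodDescriptor("OPP", "prime", "segment", "natural_only",
                         "none", "opt_patch", "discontinuous"),
    ]
    ala_bases = {"NNala": "NN", "uNNala": "uNN", "ONNala": "ONN",
                 "FNala": "FNN", "OFNala": "OFN", "OPPala": "OPP"}
    sa_bases = {"NNsa": "NN", "ONNsa": "ONN", "FNsa": "FNN",
                "OFNsa": "OFN", "OPPsa": "OPP"}
    sas_bases = {"NNsas": "NN", "ONNsas": "ONN", "FNsas": "FNN",
                 "OFNsas": "OFN", "OPPsas": "OPP"}
    for names, family, policy in (
        (ala_bases, "prime_ala", "ALA"),
        (sa_bases, "prime_sa", "SA"),
        (sas_bases, "prime_sas", "SAS"),
    ):
        for name, base_name in names.items():
            base = next(d for d in out if d.name == base_name)
            out.append(
                MethodDescriptor(name, family, "segment", base.orientation,
                                 policy, base.ordering, "discontinuous", base=base_name)
            )
    out += [
        MethodDescriptor("SHPnat", "shp", "segment", "natural_only",
                         "none", "dijkstra", "discontinuous"),
        MethodDescriptor("SHPrev", "shp", "segment", "reversible",
                         "none", "dijkstra", "discontinuous"),
        MethodDescriptor("SHPaa", "shp", "aa", "natural_only",
                         "none", "dijkstra", "discontinuous"),
        MethodDescriptor("TSPnat1", "tsp", "segment", "natural_only",
                         "none", "tsp1", "discontinuous"),
        MethodDescriptor("TSPnat2", "tsp", "segment", "natural_only",
                         "none", "tsp2", "discontinuous"),
        MethodDescriptor("TSPnat3", "tsp", "segment", "natural_only",
                         "none", "tsp3", "discontinuous"),
        MethodDescriptor("TSPnat4", "tsp", "segment", "natural_only",
                         "none", "tsp4", "discontinuous"),
        MethodDescriptor("TSPrev1", "tsp", "segment", "reversible",
                         "none", "tsp1", "discontinuous"),
        MethodDescriptor("TSPrev2", "tsp", "segment", "reversible",
                         "none", "tsp2", "discontinuous"),
        MethodDescriptor("TSPrev3", "tsp", "segment", "reversible",
                         "none", "tsp3", "discontinuous"),
        MethodDescriptor("TSPrev4", "tsp", "segment", "reversible",
                         "none", "tsp4", "discontinuous"),
        MethodDescriptor("TSPaa", "tsp", "aa", "natural_only",
                         "none", "tsp_aa", "discontinuous"),
    ]
    return tuple(out)


@lru_cache(maxsize=1)
def _registry_map() -> Mapping[str, MethodDescriptor]:
    return {d.name.lower(): d for d in _descriptors()}


def registry() -> list[MethodDescriptor]:
    """All 35 method descriptors, in registry order."""
    return list(_descriptors())


def get_method(name: str) -> MethodDescriptor:
    """Look a method up by its (case-insensitive) short name."""
    try:
        return _registry_map()[name.lower()]
    except KeyError:
        raise KeyError(f"unknown design method {name!r}") from None


def method_names() -> list[str]:
    return [d.name for d in _descriptors()]


#: family aliases accepted where a method list is expected
FAMILY_ALIASES: dict[str, tuple[str, ...]] = {
    "sequential": ("FPS",),
    "prime": ("NN", "uNN", "FNN", "ONN", "OFN", "OPP"),
    "ala": ("NNala", "uNNala", "ONNala", "FNala", "OFNala", "OPPala"),
    "sa": ("NNsa", "ONNsa", "FNsa", "OFNsa", "OPPsa"),
    "sas": ("NNsas", "ONNsas", "FNsas", "OFNsas", "OPPsas"),
    "shp": ("SHPnat", "SHPrev", "SHPaa"),
    "tsp": ("TSPnat1", "TSPnat2", "TSPnat3", "TSPnat4",
            "TSPrev1", "TSPrev2", "TSPrev3", "TSPrev4", "TSPaa"),
}


def expand_method_selection(names: Sequence[str]) -> list[str]:
    """Expand family aliases to canonical method names, preserving order."""
    out: list[str] = []
    for name in names:
        if name.lower() in FAMILY_ALIASES:
            expanded = FAMILY_ALIASES[name.lower()]
        else:
            expanded = (get_method(name).name,)
        for m in expanded:
            if m not in out:
                out.append(m)
    return out


# ---------------------------------------------------------------------------
# Designed peptides
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Part:
    """One assembled piece: a segment, a single residue or a linker."""

    kind: str                               # segment | residue | linker | fps_run
    element_id: Hashable | None
    orientation: str
    sequence: str
    residue_keys: tuple[tuple[str, int, str], ...]  # empty for linkers


@dataclass(frozen=True)
class DesignedPeptide:
    """A designed peptide with full per-residue provenance."""

    sequence: str
    method: str
    reference: Hashable
    parts: tuple[Part, ...]
    provenance: tuple          # per residue: (chain, number, icode) or "linker"
    area: str
    exact_solver: bool
    total_junction_length: float
    notes: dict = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.sequence)


def assemble(parts: Sequence[Part]) -> tuple[str, tuple]:
    """Concatenate part sequences and build per-residue provenance."""
    if not parts:
        raise ValueError("cannot assemble zero parts")
    sequence = []
    provenance: list = []
    for part in parts:
        sequence.append(part.sequence)
        if part.kind == "linker":
            provenance.extend(["linker"] * len(part.sequence))
        else:
            if len(part.residue_keys) != len(part.sequence):
                raise ValueError(f"part {part.element_id}: sequence/provenance mismatch")
            provenance.extend(part.residue_keys)
    return "".join(sequence), tuple(provenance)


# ---------------------------------------------------------------------------
# Design context
# ---------------------------------------------------------------------------

@dataclass
class DesignContext:
    """Everything the dispatcher needs: structure, accessibility, segments."""

    structure: ProteinStructure
    profile: AccessibilityProfile
    segments: list[Segment]
    cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD

    @classmethod
    def prepare(
        cls,
        structure: ProteinStructure,
        threshold: float = 0.25,
        probe_radius: float = 1.4,
        n_sphere_points: int = 960,
        cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
    ) -> "DesignContext":
        """Run the surface/segmentation pipeline on a structure."""
        profile = surface_profile(
            structure,
            probe_radius=probe_radius,
            n_sphere_points=n_sphere_points,
            threshold=threshold,
        )
        segments = build_segments(structure, profile)
        return cls(structure=structure, profile=profile, segments=segments,
                   cluster_threshold=cluster_threshold)

    def segment(self, seg_id: int) -> Segment:
        for seg in self.segments:
            if seg.id == seg_id:
                return seg
        raise KeyError(f"no segment with id {seg_id}")

    def accessible_residues(self) -> list[Residue]:
        return [
            r for r in self.structure.residues() if self.profile[r.key].accessible
        ]

    def segment_containing(self, residue_key: tuple[str, int, str]) -> Segment:
        for seg in self.segments:
            if residue_key in seg.residue_keys:
                return seg
        raise KeyError(f"residue {residue_key} is not part of any surface segment")

    def resolve_segment(self, reference) -> Segment:
        """Accept a Segment, a segment id, a Residue or a residue key."""
        if isinstance(reference, Segment):
            return reference  # user-supplied segments (e.g. FPS sub-runs) pass through
        if isinstance(reference, (int, np.integer)):
            return self.segment(int(reference))
        if isinstance(reference, Residue):
            return self.segment_containing(reference.key)
        if isinstance(reference, tuple):
            return self.segment_containing(reference)
        raise TypeError(f"cannot interpret {reference!r} as a segment reference")

    def resolve_residue(self, reference) -> Residue:
        """Accept a Residue, a residue key, or a Segment (-> residue nearest G)."""
        if isinstance(reference, Residue):
            return reference
        if isinstance(reference, tuple):
            return self.structure.residue(reference)
        seg = self.resolve_segment(reference)
        return min(
            seg.residues,
            key=lambda r: (float(np.linalg.norm(r.ca - seg.g_point)), r.key),
        )

    def resolve_area(self, ref: Segment, area: str) -> tuple[list[Segment], str]:
        """The segments of the named design area (always includes the ref)."""
        if area == "all":
            return list(self.segments), "all"
        if area == "cluster":
            clusters = cluster_segments(
                distance_matrix(self.segments), self.cluster_threshold
            )
            for cluster in clusters:
                if ref.id in cluster.members:
                    members = [self.segment(sid) for sid in cluster.members]
                    return members, f"cluster({self.cluster_threshold:g}A)"
            raise ValueError(f"segment {ref.id} missing from its own clustering")
        if area in ("patch10", "patch15"):
            radius = 10.0 if area == "patch10" else 15.0
            patch = build_patch(ref, self.segments, radius, mode=f"fixed{radius:g}")
            members = [self.segment(sid) for sid in patch.members]
            return members, f"patch({radius:g}A)"
        raise ValueError(f"unknown design area {area!r}")


# ---------------------------------------------------------------------------
# Part construction
# ---------------------------------------------------------------------------

def _element_part(ctx: DesignContext, el: OrientedElement) -> Part:
    if isinstance(el.id, tuple):  # single residue
        res = ctx.structure.residue(el.id)
        return Part("residue", el.id, NATURAL, res.name1, (res.key,))
    seg = ctx.segment(el.id)
    seq, keys = seg.sequence, seg.residue_keys
    if el.orientation != NATURAL:
        seq, keys = seq[::-1], tuple(reversed(keys))
    return Part("segment", el.id, el.orientation, seq, keys)


def _linker_part(spec: LinkerSpec) -> Part:
    return Part("linker", spec.policy, NATURAL, spec.residues, ())


def _parts_from_layout(
    ctx: DesignContext,
    layout: Sequence[OrientedElement],
    linker_policy: str,
    span: float,
) -> tuple[Part, ...]:
    parts: list[Part] = []
    for i, el in enumerate(layout):
        if i > 0 and linker_policy != "none":
            prev = layout[i - 1]
            spec = make_linker(linker_policy, prev.outgoing_ca, el.incoming_ca, span)
            if spec.residues:
                parts.append(_linker_part(spec))
        parts.append(_element_part(ctx, el))
    return tuple(parts)


def _truncate(sol: PathSolution, target_length: int, must_include) -> PathSolution:
    """Shortest layout prefix with size >= target that keeps the reference."""
    total = 0
    seen_ref = False
    for i, el in enumerate(sol.elements):
        total += el.node.length
        seen_ref = seen_ref or el.id == must_include
        if total >= target_length and seen_ref:
            if i + 1 == len(sol.elements):
                return sol
            return _solution(sol.elements[: i + 1], sol.exact)
    return sol


# ---------------------------------------------------------------------------
# FPS (the one continuous method)
# ---------------------------------------------------------------------------

def fps(
    ctx: DesignContext,
    reference: Segment,
    target_length: int,
) -> DesignedPeptide:
    """Extend a segment along the native chain to the requested length.

    One residue is added C-terminally, then one N-terminally, repeating
    (C first) and clamping at chain ends, until the peptide reaches
    ``target_length`` or the whole chain is consumed.  A reference already
    at or above the target length is returned unchanged.
    """
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    chain = ctx.structure.chain(reference.chain_id)
    keys = [r.key for r in chain]
    try:
        lo = keys.index(reference.residue_keys[0])
        hi = keys.index(reference.residue_keys[-1])
    except ValueError:
        raise KeyError(
            f"reference segment {reference.id} not found in chain {reference.chain_id}"
        ) from None

    side = "C"
    while hi - lo + 1 < target_length and (lo > 0 or hi < len(chain) - 1):
        if side == "C":
            if hi < len(chain) - 1:
                hi += 1
            elif lo > 0:
                lo -= 1
        else:
            if lo > 0:
                lo -= 1
            elif hi < len(chain) - 1:
                hi += 1
        side = "N" if side == "C" else "C"

    run = chain[lo : hi + 1]
    part = Part(
        kind="fps_run",
        element_id=reference.id,
        orientation=NATURAL,
        sequence="".join(r.name1 for r in run),
        residue_keys=tuple(r.key for r in run),
    )
    sequence, provenance = assemble([part])
    return DesignedPeptide(
        sequence=sequence,
        method="FPS",
        reference=reference.id,
        parts=(part,),
        provenance=provenance,
        area=f"chain {reference.chain_id}",
        exact_solver=True,
        total_junction_length=0.0,
        notes={},
    )


# ---------------------------------------------------------------------------
# Segment-based methods
# ---------------------------------------------------------------------------

def _favourability(seg: Segment) -> float:
    """Composite of the five scores: accessible, turn-prone, WRYP-rich,
    hydrophilic segments score higher (hydropathy normalised by its 4.5
    scale maximum, turn propensity by a typical 1.5 peak)."""
    p = seg.properties
    return (
        p.accessibility + p.wryp + p.beta_turn / 1.5 - p.hydrophobicity / 4.5
    )


def _reorder_fixed_position(
    nodes: list[PathNode],
    ref_id: Hashable,
    position: int,
    allow_reverse: bool,
) -> PathSolution:
    """Minimal-cost order with the reference pinned at a layout position.

    Exhaustive over the other elements' placements (selection sizes are
    length-limited, so n stays small); ties resolve to the lexicographically
    smallest id sequence.
    """
    import itertools as it

    ref_node = next(n for n in nodes if n.id == ref_id)
    others = sorted((n for n in nodes if n.id != ref_id), key=lambda n: _id_key(n.id))
    if not others:
        return shortest_path_order([ref_node], allow_reverse)
    if len(others) > 8:
        # too many for exhaustive placement: fall back to the unconstrained
        # exact/heuristic solver
        return shortest_path_order(nodes, allow_reverse)
    best: tuple[float, tuple, list] | None = None
    for perm in it.permutations(others):
        order = list(perm[:position]) + [ref_node] + list(perm[position:])
        layout = _chain_orientations(order, allow_reverse)
        cost = sum(
            float(np.linalg.norm(a.outgoing_ca - b.incoming_ca))
            for a, b in zip(layout, layout[1:])
        )
        key = tuple(_id_key(n.id) for n in order)
        if best is None or cost < best[0] - 1e-9 or (
            abs(cost - best[0]) <= 1e-9 and key < best[1]
        ):
            best = (cost, key, layout)
    return _solution(best[2], exact=True)


def _tsp_select(
    variant: str,
    ref: Segment,
    area_segs: list[Segment],
    target_length: int,
) -> list[Segment]:
    """Candidate selection for the four TSP variants (config-pinned readings).

    1: reference plus the most favourable segments (composite of the five
       property scores) until the target length is covered;
    2: every segment of the area;
    3: the k nearest segments whose combined length best matches the target;
    4: the 2 closest segments always included, then nearest until covered.
    """
    others = [s for s in area_segs if s.id != ref.id]
    if variant == "tsp2" or not others:
        return list(area_segs)
    by_dist = sorted(
        others,
        key=lambda s: (float(np.linalg.norm(s.g_point - ref.g_point)), s.id),
    )
    if variant == "tsp1":
        ranked = sorted(others, key=lambda s: (-_favourability(s), s.id))
        chosen = [ref]
        total = len(ref)
        for seg in ranked:
            if total >= target_length:
                break
            chosen.append(seg)
            total += len(seg)
        return chosen
    if variant == "tsp3":
        best_k, best_gap = 0, abs(len(ref) - target_length)
        total = len(ref)
        for k, seg in enumerate(by_dist, start=1):
            total += len(seg)
            gap = abs(total - target_length)
            if gap < best_gap:
                best_k, best_gap = k, gap
        return [ref] + by_dist[:best_k]
    if variant == "tsp4":
        chosen = [ref] + by_dist[:2]
        total = sum(len(s) for s in chosen)
        for seg in by_dist[2:]:
            if total >= target_length:
                break
            chosen.append(seg)
            total += len(seg)
        return chosen
    raise ValueError(f"unknown TSP variant {variant!r}")


_DEFAULT_AREAS = {
    "greedy_c": "all",
    "flanking": "all",
    "opt_nn": "all",
    "opt_flanking": "all",
    "opt_patch": "patch10",
    "dijkstra": "cluster",
    "tsp1": "cluster",
    "tsp2": "cluster",
    "tsp3": "cluster",
    "tsp4": "cluster",
}


def _design_segment_method(
    desc: MethodDescriptor,
    ctx: DesignContext,
    ref: Segment,
    target_length: int,
    options: Mapping,
) -> DesignedPeptide:
    allow_reverse = desc.orientation == "reversible"
    area_name = options.get("area", _DEFAULT_AREAS[desc.ordering])
    area_segs, area_label = ctx.resolve_area(ref, area_name)
    if not area_segs:
        raise ValueError(f"empty design area {area_label} for segment {ref.id}")
    if all(s.id != ref.id for s in area_segs):
        area_segs = [ref] + area_segs  # ad-hoc reference segments join their area
    nodes = {s.id: PathNode.from_segment(s) for s in area_segs}
    ref_node = nodes[ref.id]
    cand_nodes = [nodes[s.id] for s in area_segs if s.id != ref.id]

    def stop(total: int) -> bool:
        return total >= target_length

    notes: dict = {}
    ordering = desc.ordering
    if ordering == "greedy_c":
        sol = greedy_nn_order(ref_node, cand_nodes, "c_append", allow_reverse, stop)
    elif ordering == "flanking":
        sol = greedy_nn_order(ref_node, cand_nodes, "flanking", allow_reverse, stop)
    elif ordering in ("opt_nn", "opt_patch"):
        pre = greedy_nn_order(ref_node, cand_nodes, "c_append", allow_reverse, stop)
        notes["nn_order"] = pre.ids
        sol = shortest_path_order([el.node for el in pre.elements], allow_reverse)
    elif ordering == "opt_flanking":
        pre = greedy_nn_order(ref_node, cand_nodes, "flanking", allow_reverse, stop)
        notes["flanking_order"] = pre.ids
        position = pre.ids.index(ref.id)
        sol = _reorder_fixed_position(
            [el.node for el in pre.elements], ref.id, position, allow_reverse
        )
        notes["reordered"] = sol.ids
    elif ordering == "dijkstra":
        cutoff = options.get("proximity_cutoff", 10.0)
        sol = dijkstra_route(ref_node, list(nodes.values()), cutoff, allow_reverse)
        sol = _truncate(sol, target_length, ref.id)
    elif ordering in ("tsp1", "tsp2", "tsp3", "tsp4"):
        chosen = _tsp_select(ordering, ref, area_segs, target_length)
        sol = shortest_path_order([nodes[s.id] for s in chosen], allow_reverse)
        if ordering == "tsp2":
            sol = _truncate(sol, target_length, ref.id)
    else:
        raise ValueError(f"method {desc.name} has no segment ordering engine")

    span = options.get("per_residue_span", DEFAULT_SPAN)
    parts = _parts_from_layout(ctx, sol.elements, desc.linker_policy, span)
    sequence, provenance = assemble(parts)
    if desc.linker_policy in ("SA", "SAS"):
        notes["linker_model"] = (
            f"{desc.linker_policy} linkers use a distance-model stand-in "
            f"(span {span:g} A per residue)"
        )
    return DesignedPeptide(
        sequence=sequence,
        method=desc.name,
        reference=ref.id,
        parts=parts,
        provenance=provenance,
        area=area_label,
        exact_solver=sol.exact,
        total_junction_length=sol.total_junction_length,
        notes=notes,
    )


def _design_aa_method(
    desc: MethodDescriptor,
    ctx: DesignContext,
    reference,
    target_length: int,
    options: Mapping,
) -> DesignedPeptide:
    ref_res = ctx.resolve_residue(reference)
    if ref_res.key not in ctx.profile or not ctx.profile[ref_res.key].accessible:
        raise ValueError(
            f"reference residue {ref_res.key} is not surface-accessible"
        )
    surface = ctx.accessible_residues()
    radius = varying_patch_radius(ref_res, surface)
    ref_ca = ref_res.ca
    members = [
        r for r in surface if float(np.linalg.norm(r.ca - ref_ca)) <= radius
    ]
    nodes = {r.key: PathNode.from_residue(r) for r in members}
    ref_node = nodes[ref_res.key]

    if desc.ordering == "dijkstra":
        cutoff = options.get("proximity_cutoff", 10.0)
        sol = dijkstra_route(ref_node, list(nodes.values()), cutoff)
        sol = _truncate(sol, target_length, ref_res.key)
    elif desc.ordering == "tsp_aa":
        by_dist = sorted(
            members,
            key=lambda r: (float(np.linalg.norm(r.ca - ref_ca)), r.key),
        )
        chosen = by_dist[: max(1, min(target_length, len(by_dist)))]
        if not any(r.key == ref_res.key for r in chosen):
            chosen[-1] = ref_res
        sol = shortest_path_order([nodes[r.key] for r in chosen])
    else:
        raise ValueError(f"method {desc.name} has no residue ordering engine")

    parts = _parts_from_layout(ctx, sol.elements, "none", DEFAULT_SPAN)
    sequence, provenance = assemble(parts)
    return DesignedPeptide(
        sequence=sequence,
        method=desc.name,
        reference=ref_res.key,
        parts=parts,
        provenance=provenance,
        area=f"varying patch({radius:g}A)",
        exact_solver=sol.exact,
        total_junction_length=sol.total_junction_length,
        notes={},
    )


def design(
    method_name: str,
    ctx: DesignContext,
    reference,
    target_length: int = 10,
    options: Mapping | None = None,
) -> DesignedPeptide:
    """Design one peptide with the named method.

    ``reference`` may be a Segment, a segment id, a Residue or a residue key
    (chain, number, icode); segment methods resolve residues to their
    containing segment, residue methods resolve segments to the member
    residue nearest the G point.
    """
    desc = get_method(method_name)
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    opts = dict(options or {})
    if "cluster_threshold" in opts:
        ctx = DesignContext(
            structure=ctx.structure,
            profile=ctx.profile,
            segments=ctx.segments,
            cluster_threshold=float(opts["cluster_threshold"]),
        )
    if desc.name == "FPS":
        return fps(ctx, ctx.resolve_segment(reference), target_length)
    if desc.element_kind == "aa":
        return _design_aa_method(desc, ctx, reference, target_length, opts)
    return _design_segment_method(
        desc, ctx, ctx.resolve_segment(reference), target_length, opts
    )
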