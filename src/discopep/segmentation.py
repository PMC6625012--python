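"""Continuous surface segments and their descriptive scores.

A segment is a maximal run of consecutive surface-accessible residues on one
chain — the atomic building block of every design method.  Each segment
carries its G point (C-alpha centroid) and five scores: mean hydropathy,
mean relative accessibility, length, mean beta-turn propensity and WRYP
content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._tables import CHOU_FASMAN_TURN, KYTE_DOOLITTLE, WRYP
from .structure_io import ProteinStructure, Residue
from .surface import AccessibilityProfile

__all__ = [
    "PropertyVector",
    "Segment",
    "build_segments",
    "g_point",
    "segment_properties",
    "segment_table",
]


@dataclass(frozen=True)
class PropertyVector:
    """The five physicochemical/structural segment scores."""

    hydrophobicity: float   # mean Kyte-Doolittle hydropathy
    accessibility: float    # mean relative SASA, in [0, 1]
    length: int             # residue count
    beta_turn: float        # mean Chou-Fasman turn propensity
    wryp: float             # fraction of residues in {W, R, Y, P}

    def __post_init__(self) -> None:
        if not 0.0 <= self.wryp <= 1.0:
            raise ValueError(f"wryp {self.wryp} outside [0, 1]")
        if not 0.0 <= self.accessibility <= 1.0:
            raise ValueError(f"accessibility {self.accessibility} outside [0, 1]")
        if self.length < 1:
            raise ValueError("segment length must be positive")


@dataclass(frozen=True)
class Segment:
    """A maximal run of consecutive accessible residues on one chain."""

    id: int
    chain_id: str
    residues: tuple[Residue, ...]
    sequence: str
    g_point: np.ndarray
    properties: PropertyVector

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def start(self) -> int:
        return self.residues[0].author_number

    @property
    def end(self) -> int:
        return self.residues[-1].author_number

    @property
    def residue_keys(self) -> tuple[tuple[str, int, str], ...]:
        return tuple(r.key for r in self.residues)


def g_point(residues: tuple[Residue, ...] | list[Residue]) -> np.ndarray:
    """Arithmetic mean of the member C-alpha coordinates (the G point)."""
    if not residues:
        raise ValueError("cannot compute a G point of zero residues")
    return np.mean([r.ca for r in residues], axis=0)


def segment_properties(
    residues: tuple[Residue, ...] | list[Residue],
    profile: AccessibilityProfile,
) -> PropertyVector:
    """Score a residue run on the five segment criteria.

    Residues without a table entry (nonstandard, mapped to 'X') contribute 0
    to hydropathy and turn propensity.
    """
    if not residues:
        raise ValueError("cannot score an empty segment")
    seq = [r.name1 for r in residues]
    return PropertyVector(
        hydrophobicity=float(np.mean([KYTE_DOOLITTLE.get(c, 0.0) for c in seq])),
        accessibility=float(np.mean([profile[r.key].relative_sasa for r in residues])),
        length=len(residues),
        beta_turn=float(np.mean([CHOU_FASMAN_TURN.get(c, 0.0) for c in seq])),
        wryp=sum(c in WRYP for c in seq) / len(seq),
    )


def _consecutive(prev: Residue, curr: Residue) -> bool:
    """Author-numbering adjacency; a numbering gap breaks a run even when both
    flanking residues are accessible (missing density)."""
    if curr.author_number == prev.author_number + 1 and not curr.insertion_code:
        return True
    # insertion codes: same number, successive codes (e.g. 52 -> 52A -> 52B)
    return curr.author_number == prev.author_number and curr.insertion_code > prev.insertion_code


def build_segments(
    structure: ProteinStructure,
    profile: AccessibilityProfile,
) -> list[Segment]:
    """Deduce the continuous surface segments of a structure.

    Segments partition the accessible residue set into maximal runs; ids are
    assigned 0..n-1 in chain order then sequence order and are stable across
    runs on identical input.
    """
    segments: list[Segment] = []
    next_id = 0
    for chain_id, residues in structure.chains:
        run: list[Residue] = []
        for res in residues:
            if profile[res.key].accessible:
                if run and not _consecutive(run[-1], res):
                    segments.append(_make_segment(next_id, chain_id, run, profile))
                    next_id += 1
                    run = []
                run.append(res)
            elif run:
                segments.append(_make_segment(next_id, chain_id, run, profile))
                next_id += 1
                run = []
        if run:
            segments.append(_make_segment(next_id, chain_id, run, profile))
            next_id += 1
    return segments


def _make_segment(
    seg_id: int, chain_id: str, run: list[Residue], profile: AccessibilityProfile
) -> Segment:
    return Segment(
        id=seg_id,
        chain_id=chain_id,
        residues=tuple(run),
        sequence="".join(r.name1 for r in run),
        g_point=g_point(run),
        properties=segment_properties(run, profile),
    )


def segment_table(segments: list[Segment]) -> pd.DataFrame:
    """Segment summary as a DataFrame (TSV-exportable)."""
    rows = []
    for seg in segments:
        rows.append(
            {
                "id": seg.id,
                "chain": seg.chain_id,
                "start": seg.start,
                "end": seg.end,
                "sequence": seg.sequence,
                "hydrophobicity": seg.properties.hydrophobicity,
                "accessibility": seg.properties.accessibility,
                "length": seg.properties.length,
                "beta_turn": seg.properties.beta_turn,
                "wryp": seg.properties.wryp,
                "g_x": seg.g_point[0],
                "g_y": seg.g_point[1],
                "g_z": seg.g_point[2],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id", "chain", "start", "end", "sequence",
            "hydrophobicity", "accessibility", "length", "beta_turn", "wryp",
            "g_x", "g_y", "g_z",
        ],
    )
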