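"""Synthetic PDB structures with analytically known geometry.

Every generator emits standard fixed-column PDB text (one C-alpha atom per
residue) that parses cleanly through :func:`discopep.structure_io.read_structure`.
Residues are placed sparsely so all are surface-accessible by construction,
which decouples geometry tests from the SASA threshold.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._tables import ONE_TO_THREE

__all__ = [
    "FixtureSpec",
    "synth_structure",
    "octahedron_spec",
    "cube_spec",
    "collinear_spec",
    "cloud_spec",
    "segmented_cloud_spec",
    "paired_scaffold_spec",
    "flanking_demo_spec",
    "two_region_toy",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Blueprint for one synthetic structure."""

    name: str
    ca_coordinates: np.ndarray          # (n, 3) in Angstrom
    sequence: str
    chain_ids: tuple[str, ...] | None = None     # per residue; default all "A"
    author_numbers: tuple[int, ...] | None = None  # default 1..n
    seed: int | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.ca_coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("ca_coordinates must be an (n, 3) array")
        if coords.shape[0] != len(self.sequence):
            raise ValueError(
                f"{coords.shape[0]} coordinates but {len(self.sequence)} sequence letters"
            )
        object.__setattr__(self, "ca_coordinates", coords)
        if self.chain_ids is not None and len(self.chain_ids) != len(self.sequence):
            raise ValueError("chain_ids length must match the sequence")
        if self.author_numbers is not None and len(self.author_numbers) != len(self.sequence):
            raise ValueError("author_numbers length must match the sequence")


def synth_structure(spec: FixtureSpec) -> str:
    """Render a spec as PDB text (CA-only residues, occupancy 1.00)."""
    chains = spec.chain_ids or tuple("A" for _ in spec.sequence)
    numbers = spec.author_numbers or tuple(range(1, len(spec.sequence) + 1))
    lines = [f"HEADER    SYNTHETIC FIXTURE {spec.name.upper()[:40]}"]
    serial = 1
    prev_chain = chains[0]
    for code, chain, number, (x, y, z) in zip(
        spec.sequence, chains, numbers, spec.ca_coordinates
    ):
        if chain != prev_chain:
            lines.append("TER")
            prev_chain = chain
        res3 = ONE_TO_THREE.get(code.upper())
        if res3 is None:
            raise ValueError(f"unknown one-letter residue code {code!r}")
        lines.append(
            f"ATOM  {serial:5d} {'CA':^4s} {res3:>3s} {chain:1s}{number:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f" C"
        )
        serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def octahedron_spec(radius: float = 10.0) -> FixtureSpec:
    """Six residues at (+/-r,0,0), (0,+/-r,0), (0,0,+/-r)."""
    coords = np.array(
        [
            [radius, 0, 0], [-radius, 0, 0],
            [0, radius, 0], [0, -radius, 0],
            [0, 0, radius], [0, 0, -radius],
        ],
        dtype=float,
    )
    return FixtureSpec(
        name="octahedron",
        ca_coordinates=coords,
        sequence="ACDEFG",
        author_numbers=tuple(range(10, 70, 10)),  # gaps: one segment per residue
    )


def cube_spec(side: float = 10.0) -> FixtureSpec:
    """Eight residues at the corners of a cube; diagonal side*sqrt(3)."""
    corners = np.array(
        [[x, y, z] for x in (0, side) for y in (0, side) for z in (0, side)],
        dtype=float,
    )
    return FixtureSpec(
        name="cube",
        ca_coordinates=corners,
        sequence="ACDEFGHI",
        author_numbers=tuple(range(10, 90, 10)),
    )


def collinear_spec(
    sequence: str = "AAA",
    spacing: float = 5.0,
    author_numbers: Sequence[int] | None = None,
) -> FixtureSpec:
    """Residues evenly spaced along the x axis."""
    coords = np.array([[i * spacing, 0.0, 0.0] for i in range(len(sequence))])
    return FixtureSpec(
        name="collinear",
        ca_coordinates=coords,
        sequence=sequence,
        author_numbers=tuple(author_numbers) if author_numbers is not None else None,
    )


def cloud_spec(
    n: int = 20,
    seed: int = 0,
    box: float = 40.0,
    min_separation: float = 6.0,
    sequence: str | None = None,
) -> FixtureSpec:
    """n residues scattered in a box with a minimum pairwise separation."""
    rng = np.random.default_rng(seed)
    points: list[np.ndarray] = []
    while len(points) < n:
        cand = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(cand - p) >= min_separation for p in points):
            points.append(cand)
    letters = "ACDEFGHIKLMNPQRSTVWY"
    seq = sequence or "".join(
        letters[i % len(letters)] for i in range(n)
    )
    return FixtureSpec(
        name=f"cloud{n}-seed{seed}",
        ca_coordinates=np.array(points),
        sequence=seq,
        author_numbers=tuple(range(10, 10 * (n + 1), 10)),
        seed=seed,
    )


def segmented_cloud_spec(
    n_segments: int = 5,
    seed: int = 0,
    box: float = 50.0,
    min_separation: float = 12.0,
    step: float = 3.8,
) -> FixtureSpec:
    """Multi-residue segments (2-4 residues) scattered with known geometry.

    Each segment runs along a random direction at ``step`` A per residue;
    segment origins keep ``min_separation`` so segments stay distinct and
    every residue stays surface-accessible.
    """
    rng = np.random.default_rng(seed)
    origins: list[np.ndarray] = []
    while len(origins) < n_segments:
        cand = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(cand - o) >= min_separation for o in origins):
            origins.append(cand)
    letters = "ACDEFGHIKLMNPQRSTV"
    coords, seq, numbers = [], [], []
    for s, origin in enumerate(origins):
        length = int(rng.integers(2, 5))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        for i in range(length):
            coords.append(origin + i * step * direction)
            seq.append(letters[(3 * s + i) % len(letters)])
            numbers.append(100 * s + 10 + i)
    return FixtureSpec(
        name=f"segmented-cloud{n_segments}-seed{seed}",
        ca_coordinates=np.array(coords),
        sequence="".join(seq),
        author_numbers=tuple(numbers),
        seed=seed,
    )


def paired_scaffold_spec(seed: int = 0, jitter: float = 1.5) -> FixtureSpec:
    """Twelve surface residues in general position for paired design.

    Six octahedron vertices at 15 A plus six equatorial points at 8 A
    offsets, each jittered by a seeded uniform offset: every pair
    construction (primary axis, orthogonal band, double-bisector slab,
    alternates) has candidates by construction, while the jitter removes
    exact ties.
    """
    scaffold = np.array(
        [
            [15, 0, 0], [-15, 0, 0], [0, 15, 0], [0, -15, 0],
            [0, 0, 15], [0, 0, -15],
            [8, 8, 0], [-8, 8, 0], [8, -8, 0], [-8, -8, 0],
            [0, 8, 8], [0, -8, -8],
        ],
        dtype=float,
    )
    rng = np.random.default_rng(seed)
    coords = scaffold + rng.uniform(-jitter, jitter, size=scaffold.shape)
    return FixtureSpec(
        name=f"paired-scaffold-seed{seed}",
        ca_coordinates=coords,
        sequence="ACDEFGHIKLMN",
        author_numbers=tuple(range(10, 130, 10)),
        seed=seed,
    )


def flanking_demo_spec() -> FixtureSpec:
    """Four segments laid out for flanking assembly into a 17-mer.

    A 12-residue reference (author numbers 80-91) flanked by a lysine
    segment N-side and a valine plus a three-residue segment C-side, with
    junction distances arranged so flanking selection picks V first (C),
    then K (N), then ETR (C), and the shortest-path reorder keeps the
    layout K | reference | V | ETR.
    """
    ref_seq = "YGDGDHNGLYAD"
    coords: list[list[float]] = [[-5.0, 0.0, 0.0]]
    seq = ["K"]
    numbers = [70]
    for i, code in enumerate(ref_seq):
        coords.append([i * 3.8, 0.0, 0.0])
        seq.append(code)
        numbers.append(80 + i)
    coords.append([45.6, 0.0, 0.0])
    seq.append("V")
    numbers.append(93)
    for j, code in enumerate("ETR"):
        coords.append([49.4 + j * 3.8, 0.0, 0.0])
        seq.append(code)
        numbers.append(95 + j)
    return FixtureSpec(
        name="flanking-demo",
        ca_coordinates=np.array(coords),
        sequence="".join(seq),
        author_numbers=tuple(numbers),
    )


def two_region_toy(seed: int = 0) -> str:
    """PDB text with two residue clusters >= 50 A apart, two segments each.

    Each region holds two 3-residue segments (consecutive author numbers,
    5 A spacing, segment G points ~6 A apart), regions offset by 60 A, plus
    a seeded sub-Angstrom jitter.  Clustering the segments at a 10 A
    threshold yields exactly two clusters.
    """
    rng = np.random.default_rng(seed)

    def region(origin: np.ndarray) -> np.ndarray:
        rows = []
        for s in range(2):  # two segments, offset in y
            base = origin + np.array([0.0, s * 6.0, 0.0])
            for i in range(3):
                rows.append(base + np.array([i * 5.0, 0.0, 0.0]))
        return np.array(rows)

    coords = np.vstack([region(np.zeros(3)), region(np.array([60.0, 0.0, 0.0]))])
    coords = coords + rng.uniform(-0.4, 0.4, size=coords.shape)
    numbers = []
    for r in range(2):
        for s in range(2):
            start = 100 * r + 10 * s + 1
            numbers.extend([start, start + 1, start + 2])
    spec = FixtureSpec(
        name=f"two-region-seed{seed}",
        ca_coordinates=coords,
        sequence="ACDEFGHIKLMN",
        author_numbers=tuple(numbers),
        seed=seed,
    )
    return synth_structure(spec)
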