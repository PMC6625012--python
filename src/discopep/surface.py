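"""Per-residue solvent accessibility and surface classification.

Absolute SASA is computed with the Shrake-Rupley rolling-probe algorithm over
the package's coordinate model, then normalised by a per-residue-type
theoretical maximum to a relative SASA in [0, 1]; residues at or above the
relative threshold are classified surface-accessible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._tables import DEFAULT_VDW_RADIUS, MAX_SASA_TIEN, VDW_RADII
from .structure_io import ProteinStructure

__all__ = [
    "ResidueAccessibility",
    "AccessibilityProfile",
    "compute_sasa",
    "classify_accessible",
    "surface_profile",
    "parse_dssp_acc",
]

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_SPHERE_POINTS = 960
DEFAULT_THRESHOLD = 0.25


@dataclass(frozen=True)
class ResidueAccessibility:
    """Accessibility record for one residue."""

    key: tuple[str, int, str]
    absolute_sasa: float
    relative_sasa: float
    accessible: bool


@dataclass(frozen=True)
class AccessibilityProfile:
    """Per-residue accessibility, keyed by (chain, author_number, icode)."""

    records: tuple[ResidueAccessibility, ...]
    threshold: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "_by_key", {r.key: r for r in self.records})

    def __getitem__(self, key: tuple[str, int, str]) -> ResidueAccessibility:
        try:
            return self._by_key[key]
        except KeyError:
            raise KeyError(f"no accessibility record for residue {key}") from None

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        return key in self._by_key

    def accessible_keys(self) -> tuple[tuple[str, int, str], ...]:
        return tuple(r.key for r in self.records if r.accessible)


def _sphere_points(n: int) -> np.ndarray:
    """n approximately uniform unit-sphere points (golden-spiral lattice)."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k          # golden angle increments
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((r * np.cos(phi), r * np.sin(phi), z))


def compute_sasa(
    structure: ProteinStructure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> dict[tuple[str, int, str], float]:
    """Absolute solvent-accessible surface area per residue, in A^2.

    Shrake-Rupley: each atom is covered with a test-point sphere of radius
    vdW + probe; points buried inside any neighbouring atom's probe-expanded
    sphere are removed and the surviving fraction scaled to the sphere area.
    Per-atom areas are summed per residue.
    """
    residues = structure.residues()
    atoms: list[tuple[int, np.ndarray, float]] = []  # (residue idx, pos, radius)
    for ridx, res in enumerate(residues):
        if not res.atoms:
            raise ValueError(f"residue {res.key} has no atoms")
        for atom in res.atoms:
            radius = VDW_RADII.get(atom.element, DEFAULT_VDW_RADIUS)
            atoms.append((ridx, atom.position, radius))

    coords = np.array([a[1] for a in atoms])
    radii = np.array([a[2] for a in atoms]) + probe_radius
    owners = np.array([a[0] for a in atoms])
    unit_sphere = _sphere_points(n_sphere_points)

    tree = cKDTree(coords)
    max_reach = 2.0 * radii.max()
    sasa = np.zeros(len(residues))
    for i in range(len(atoms)):
        points = coords[i] + radii[i] * unit_sphere
        neighbour_idx = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        exposed = np.ones(n_sphere_points, dtype=bool)
        if neighbour_idx:
            nb = np.asarray(neighbour_idx)
            # only neighbours whose expanded sphere can actually intersect ours
            close = np.linalg.norm(coords[nb] - coords[i], axis=1) < radii[nb] + radii[i]
            for j in nb[close]:
                d2 = np.einsum("ij,ij->i", points - coords[j], points - coords[j])
                exposed &= d2 > radii[j] ** 2
                if not exposed.any():
                    break
        area = 4.0 * np.pi * radii[i] ** 2 * exposed.sum() / n_sphere_points
        sasa[owners[i]] += area
    return {res.key: float(sasa[ridx]) for ridx, res in enumerate(residues)}


def classify_accessible(
    structure: ProteinStructure,
    raw_sasa: dict[tuple[str, int, str], float],
    reference_max: dict[str, float] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> AccessibilityProfile:
    """Normalise absolute SASA and flag surface residues.

    relative = min(1, absolute / reference_max[type]); accessible iff
    relative >= threshold.
    """
    table = MAX_SASA_TIEN if reference_max is None else reference_max
    records = []
    for res in structure.residues():
        code = res.name1
        if code not in table:
            raise KeyError(
                f"residue type {res.name3} ({code}) missing from reference-max SASA table"
            )
        absolute = raw_sasa[res.key]
        relative = min(1.0, max(0.0, absolute / table[code]))
        records.append(
            ResidueAccessibility(
                key=res.key,
                absolute_sasa=absolute,
                relative_sasa=relative,
                accessible=relative >= threshold,
            )
        )
    return AccessibilityProfile(records=tuple(records), threshold=threshold)


def surface_profile(
    structure: ProteinStructure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
    threshold: float = DEFAULT_THRESHOLD,
    reference_max: dict[str, float] | None = None,
) -> AccessibilityProfile:
    """Convenience: compute_sasa followed by classify_accessible."""
    raw = compute_sasa(structure, probe_radius, n_sphere_points)
    return classify_accessible(structure, raw, reference_max, threshold)


def parse_dssp_acc(dssp_text: str) -> dict[tuple[str, int, str], float]:
    """Extract the ACC column from classic DSSP output.

    Provided for parity experiments against an external DSSP run; returns
    absolute accessibility per (chain, number, insertion code).
    """
    acc: dict[tuple[str, int, str], float] = {}
    in_table = False
    for line in dssp_text.splitlines():
        if line.startswith("  #  RESIDUE"):
            in_table = True
            continue
        if not in_table or len(line) < 38:
            continue
        if line[13] == "!":  # chain break marker
            continue
        try:
            number = int(line[5:10])
        except ValueError:
            continue
        icode = line[10].strip()
        chain = line[11].strip()
        acc[(chain, number, icode)] = float(line[34:38])
    return acc
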