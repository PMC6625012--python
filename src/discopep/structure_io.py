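"""Reading PDB structures into an immutable coordinate model.

The model keeps only ATOM records of standard amino acids (plus configurable
extras), resolves alternate locations to the highest-occupancy conformer and
exposes residues in author numbering (number + insertion code), which is the
public coordinate convention throughout the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

from ._tables import STANDARD_AA3, THREE_TO_ONE, WATER_NAMES

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "PDBParseError",
    "read_structure",
    "one_letter_sequence",
]


class PDBParseError(ValueError):
    """Raised when PDB text cannot be parsed into a structure."""


@dataclass(frozen=True)
class Atom:
    """A single atom with coordinates in Angstrom."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass(frozen=True)
class Residue:
    """One residue in author numbering, with its atoms."""

    chain_id: str
    author_number: int
    insertion_code: str
    name3: str
    atoms: tuple[Atom, ...]
    is_standard_aa: bool = True

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.key} has no atoms")

    @property
    def key(self) -> tuple[str, int, str]:
        """(chain_id, author_number, insertion_code) — the public residue id."""
        return (self.chain_id, self.author_number, self.insertion_code)

    @property
    def name1(self) -> str:
        return THREE_TO_ONE.get(self.name3, "X")

    @property
    def ca(self) -> np.ndarray:
        """C-alpha coordinates; raises if the residue has none."""
        for atom in self.atoms:
            if atom.name == "CA":
                return atom.position
        raise ValueError(f"residue {self.key} ({self.name3}) has no CA atom")

    @property
    def has_ca(self) -> bool:
        return any(atom.name == "CA" for atom in self.atoms)


@dataclass(frozen=True)
class ProteinStructure:
    """Ordered chains of ordered residues; the geometric substrate."""

    source_id: str
    model_index: int
    chains: tuple[tuple[str, tuple[Residue, ...]], ...]
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        index = {}
        for chain_id, residues in self.chains:
            for res in residues:
                index[res.key] = res
        object.__setattr__(self, "_index", index)

    @property
    def chain_ids(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.chains)

    def chain(self, chain_id: str) -> tuple[Residue, ...]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(f"no chain {chain_id!r} in structure {self.source_id}")

    def residues(self) -> tuple[Residue, ...]:
        """All residues, chain by chain, in author order."""
        return tuple(r for _, chain in self.chains for r in chain)

    def residue(self, key: tuple[str, int, str]) -> Residue:
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"no residue {key} in structure {self.source_id}") from None

    def __len__(self) -> int:
        return sum(len(chain) for _, chain in self.chains)


def _check_coordinate_fields(pdb_text: str) -> None:
    """Pre-scan ATOM/HETATM lines so coordinate errors report a line number."""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        for start, stop, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            raw = line[start:stop]
            try:
                float(raw)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed {what} coordinate field {raw!r}"
                ) from None


def _resolve_altloc(bio_atom):
    """Pick the highest-occupancy conformer; ties by lexicographic altloc."""
    if not bio_atom.is_disordered():
        return bio_atom
    children = sorted(
        bio_atom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def read_structure(
    pdb_text: str,
    model_index: int = 0,
    chains: set[str] | None = None,
    source_id: str = "structure",
    extra_residues: set[str] | None = None,
) -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    Only ATOM records of the 20 standard amino acids (plus ``extra_residues``)
    are retained; waters and other heteroatoms are dropped.  Alternate
    locations resolve to the highest-occupancy conformer.

    Parameters
    ----------
    pdb_text:
        The structure as PDB fixed-column text.
    model_index:
        Which MODEL to read (0-based); single-model files have index 0.
    chains:
        Optional chain-id whitelist.
    extra_residues:
        Additional three-letter residue names treated as standard
        (e.g. ``{"MSE"}``).
    """
    _check_coordinate_fields(pdb_text)
    accepted = STANDARD_AA3 | (set(extra_residues or ()))

    parser = PDBParser(QUIET=True)
    try:
        bio_structure = parser.get_structure(source_id, io.StringIO(pdb_text))
    except Exception as exc:  # Biopython raises several exception types
        raise PDBParseError(f"could not parse PDB text: {exc}") from exc

    models = list(bio_structure)
    if not models:
        raise PDBParseError("no models found in PDB text")
    if not 0 <= model_index < len(models):
        raise PDBParseError(
            f"model_index {model_index} out of range (file has {len(models)} model(s))"
        )
    model = models[model_index]

    out_chains: list[tuple[str, tuple[Residue, ...]]] = []
    for bio_chain in model:
        chain_id = bio_chain.id
        if chains is not None and chain_id not in chains:
            continue
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetfield, resseq, icode = bio_res.id
            name3 = bio_res.get_resname().strip()
            if name3 in WATER_NAMES:
                continue
            if hetfield.strip() and name3 not in accepted:
                continue
            if name3 not in accepted:
                continue
            atoms = []
            for bio_atom in bio_res:
                chosen = _resolve_altloc(bio_atom)
                atoms.append(
                    Atom(
                        name=chosen.get_name(),
                        element=(chosen.element or "").upper(),
                        position=np.array(chosen.get_coord(), dtype=float),
                        occupancy=min(1.0, max(0.0, chosen.get_occupancy() or 1.0)),
                        altloc=chosen.get_altloc().strip(),
                    )
                )
            if not atoms:
                continue
            residues.append(
                Residue(
                    chain_id=chain_id,
                    author_number=resseq,
                    insertion_code=icode.strip(),
                    name3=name3,
                    atoms=tuple(atoms),
                    is_standard_aa=name3 in STANDARD_AA3,
                )
            )
        if residues:
            residues.sort(key=lambda r: (r.author_number, r.insertion_code))
            out_chains.append((chain_id, tuple(residues)))

    if not out_chains:
        raise PDBParseError(
            "no residues after filtering (empty selection or no standard amino acids)"
        )
    return ProteinStructure(
        source_id=source_id, model_index=model_index, chains=tuple(out_chains)
    )


def one_letter_sequence(structure: ProteinStructure, chain_id: str) -> str:
    """One-letter sequence of a chain; nonstandard residues map to 'X'."""
    return "".join(res.name1 for res in structure.chain(chain_id))
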