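"""Inter-segment linkers for the ALA, SA and SAS method families.

Linker length is quantised from the C-alpha gap between the two termini at a
per-residue span (default 3.8 A, the canonical C-alpha - C-alpha step of an
extended chain): k = max(0, round_half_up(gap / span) - 1) residues, so
adjacent termini (one span apart) need no linker.

ALA linkers are alanine spacers.  The SA ("structural alphabet") and SAS
("superposed structural alphabet") policies are distance-model stand-ins for
backbone-fragment linker computations that are not fully specifiable here:
SA applies the same span model, SAS first superposes the termini onto
canonical fragment geometry, which shortens the effective gap by one
terminal span on each side.  SA/SAS linkers are emitted as glycine so their
residues remain distinguishable from ALA spacers in provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["LinkerSpec", "make_linker", "LINKER_POLICIES", "DEFAULT_SPAN"]

LINKER_POLICIES = ("ALA", "SA", "SAS")
DEFAULT_SPAN = 3.8


@dataclass(frozen=True)
class LinkerSpec:
    """A computed linker: policy, residues and the gap it spans."""

    policy: str
    residues: str
    spanned_gap: float

    def __post_init__(self) -> None:
        if self.policy == "ALA" and set(self.residues) - {"A"}:
            raise ValueError("ALA linkers must consist of alanine only")

    def __len__(self) -> int:
        return len(self.residues)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _ca_of(terminus) -> np.ndarray:
    if hasattr(terminus, "ca"):
        return np.asarray(terminus.ca, dtype=float)
    pos = np.asarray(terminus, dtype=float)
    if pos.shape != (3,):
        raise ValueError("terminus must be a residue with a CA atom or a 3-vector")
    return pos


def make_linker(
    policy: str,
    terminus_a,
    terminus_b,
    per_residue_span: float = DEFAULT_SPAN,
) -> LinkerSpec:
    """Compute the linker spanning the gap between two termini.

    ``terminus_a``/``terminus_b`` are residues with C-alpha coordinates (or
    bare 3-vectors).  The residue count is deterministic given the gap and
    policy; a zero gap yields an empty linker for every policy.
    """
    if policy not in LINKER_POLICIES:
        raise ValueError(f"unknown linker policy {policy!r}; expected one of {LINKER_POLICIES}")
    if per_residue_span <= 0:
        raise ValueError("per_residue_span must be positive")
    gap = float(np.linalg.norm(_ca_of(terminus_a) - _ca_of(terminus_b)))

    if policy == "SAS":
        effective = max(0.0, gap - 2.0 * per_residue_span)
    else:
        effective = gap
    count = max(0, _round_half_up(effective / per_residue_span) - 1)
    residue = "A" if policy == "ALA" else "G"
    return LinkerSpec(policy=policy, residues=residue * count, spanned_gap=gap)
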