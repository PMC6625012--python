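"""Peptide-bank enumeration, length filtering and export.

A bank takes every segment of the structure in turn as the reference for
every chosen method, so the entire protein surface is explored: the record
count before filtering is exactly |methods| x |segments|.  Records outside
the synthesis-friendly length window (7-24 residues by default, bounds
inclusive) are flagged "eliminated" rather than discarded, so pre- and
post-filter counts both stay reportable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .design_methods import (
    DesignContext,
    DesignedPeptide,
    design,
    expand_method_selection,
)

__all__ = [
    "BankConfig",
    "BankRecord",
    "PeptideBank",
    "generate_bank",
    "filter_length",
    "export",
    "load_bank_json",
]

DEFAULT_METHODS = ("prime", "ala", "sa")


@dataclass(frozen=True)
class BankConfig:
    """Bank parameters; the default method set is prime + ALA + SA."""

    methods: tuple[str, ...] = DEFAULT_METHODS
    target_length: int = 10
    min_length: int = 7
    max_length: int = 24
    dedupe: bool = False

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("the bank needs at least one method")
        if not 1 <= self.min_length <= self.max_length:
            raise ValueError("need 1 <= min_length <= max_length")


@dataclass(frozen=True)
class BankRecord:
    """One designed peptide plus its filter status."""

    peptide: DesignedPeptide
    status: str = "ok"          # ok | eliminated
    also_from: tuple[str, ...] = field(default_factory=tuple)  # dedupe provenance

    @property
    def length(self) -> int:
        return len(self.peptide.sequence)


@dataclass(frozen=True)
class PeptideBank:
    """All records of one bank run."""

    records: tuple[BankRecord, ...]
    config: BankConfig

    def kept(self) -> tuple[BankRecord, ...]:
        return tuple(r for r in self.records if r.status == "ok")

    def eliminated(self) -> tuple[BankRecord, ...]:
        return tuple(r for r in self.records if r.status == "eliminated")

    def __len__(self) -> int:
        return len(self.records)


def generate_bank(ctx: DesignContext, config: BankConfig) -> PeptideBank:
    """Design one peptide per method x segment-as-reference (pre-filter).

    With ``dedupe`` set, records sharing an identical sequence collapse to
    the first one, whose ``also_from`` lists the other producing methods.
    """
    if not ctx.segments:
        raise ValueError("the structure has no surface segments")
    methods = expand_method_selection(config.methods)
    records: list[BankRecord] = []
    for method in methods:
        for seg in ctx.segments:
            peptide = design(method, ctx, seg, config.target_length)
            records.append(BankRecord(peptide=peptide))
    if config.dedupe:
        by_seq: dict[str, int] = {}
        merged: list[BankRecord] = []
        for rec in records:
            seq = rec.peptide.sequence
            if seq in by_seq:
                i = by_seq[seq]
                merged[i] = replace(
                    merged[i],
                    also_from=merged[i].also_from + (rec.peptide.method,),
                )
            else:
                by_seq[seq] = len(merged)
                merged.append(rec)
        records = merged
    return PeptideBank(records=tuple(records), config=config)


def filter_length(
    bank: PeptideBank,
    min_length: int | None = None,
    max_length: int | None = None,
) -> PeptideBank:
    """Flag records outside [min_length, max_length] (bounds inclusive).

    Peptides shorter than the minimum are too short to mimic a
    discontinuous epitope; ones longer than the maximum exceed synthesis
    limits.  Filtering is idempotent.
    """
    lo = bank.config.min_length if min_length is None else min_length
    hi = bank.config.max_length if max_length is None else max_length
    records = tuple(
        replace(rec, status="ok" if lo <= rec.length <= hi else "eliminated")
        for rec in bank.records
    )
    return PeptideBank(records=records, config=bank.config)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def _key_str(key) -> str:
    if key == "linker":
        return "linker"
    chain, number, icode = key
    return f"{chain}:{number}{icode}"


def _ref_str(ref) -> str:
    return _key_str(ref) if isinstance(ref, tuple) else str(ref)


def _parts_str(peptide: DesignedPeptide) -> str:
    bits = []
    for part in peptide.parts:
        if part.kind == "linker":
            bits.append(f"linker[{part.element_id}:{part.sequence}]")
        else:
            tag = "-" if part.orientation == "natural" else "~"
            bits.append(f"{_ref_str(part.element_id)}{tag}")
    return "+".join(bits)


def _records_of(source) -> list[BankRecord]:
    if isinstance(source, PeptideBank):
        return list(source.records)
    if isinstance(source, DesignedPeptide):
        return [BankRecord(peptide=source)]
    out = []
    for item in source:
        out.append(item if isinstance(item, BankRecord) else BankRecord(peptide=item))
    return out


def _to_fasta(records: list[BankRecord]) -> str:
    lines = []
    for i, rec in enumerate(records):
        pep = rec.peptide
        lines.append(f">{pep.method}|ref={_ref_str(pep.reference)}|{i}|{_parts_str(pep)}")
        lines.append(pep.sequence)
    return "\n".join(lines) + "\n"


def _to_frame(records: list[BankRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        pep = rec.peptide
        rows.append(
            {
                "method": pep.method,
                "reference": _ref_str(pep.reference),
                "sequence": pep.sequence,
                "length": len(pep.sequence),
                "area": pep.area,
                "parts": _parts_str(pep),
                "junction_length_A": round(pep.total_junction_length, 3),
                "exact_solver": pep.exact_solver,
                "status": rec.status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["method", "reference", "sequence", "length", "area",
                 "parts", "junction_length_A", "exact_solver", "status"],
    )


def _to_json_obj(records: list[BankRecord]) -> list[dict]:
    out = []
    for rec in records:
        pep = rec.peptide
        out.append(
            {
                "method": pep.method,
                "reference": _ref_str(pep.reference),
                "sequence": pep.sequence,
                "area": pep.area,
                "exact_solver": pep.exact_solver,
                "junction_length_A": round(pep.total_junction_length, 6),
                "status": rec.status,
                "also_from": list(rec.also_from),
                "parts": [
                    {
                        "kind": part.kind,
                        "element": _ref_str(part.element_id),
                        "orientation": part.orientation,
                        "sequence": part.sequence,
                    }
                    for part in pep.parts
                ],
                "provenance": [_key_str(k) for k in pep.provenance],
            }
        )
    return out


def _to_viz_script(records: list[BankRecord]) -> str:
    """PyMOL selection/colour commands for the provenance residues."""
    lines = ["# PyMOL script: highlight designed-peptide residues on the antigen"]
    palette = ["red", "orange", "yellow", "green", "cyan", "blue", "purple"]
    for i, rec in enumerate(records):
        pep = rec.peptide
        by_chain: dict[str, list[str]] = {}
        for key in pep.provenance:
            if key == "linker":
                continue
            chain, number, icode = key
            by_chain.setdefault(chain, []).append(f"{number}{icode}")
        sel = " or ".join(
            f"(chain {chain} and resi {'+'.join(resis)})"
            for chain, resis in sorted(by_chain.items())
        )
        name = f"pep_{i}_{pep.method}"
        lines.append(f"select {name}, {sel}")
        lines.append(f"color {palette[i % len(palette)]}, {name}")
    return "\n".join(lines) + "\n"


def export(source, fmt: str, path: str | Path) -> Path:
    """Write a bank, a record list or a single peptide to ``path``.

    Formats: ``fasta`` (headers encode method|reference|parts), ``tsv``
    (one row per record), ``json`` (full provenance; round-trips through
    :func:`load_bank_json`), ``viz_script`` (PyMOL selections colouring the
    provenance residues on the source structure).
    """
    records = _records_of(source)
    if not records:
        raise ValueError("nothing to export")
    path = Path(path)
    if fmt == "fasta":
        path.write_text(_to_fasta(records))
    elif fmt == "tsv":
        _to_frame(records).to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        path.write_text(json.dumps(_to_json_obj(records), indent=2) + "\n")
    elif fmt == "viz_script":
        path.write_text(_to_viz_script(records))
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


def load_bank_json(path: str | Path) -> list[dict]:
    """Read a JSON export back into record dictionaries."""
    return json.loads(Path(path).read_text())
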