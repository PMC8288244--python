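"""Reading, canonicalizing and filtering compound tables.

Input is a delimited text table (CSV or TSV, header required) with an
identifier column and a SMILES column, or a headerless SMILES-only file
(one structure per line, identifiers auto-assigned ``C000001`` ...).

Each record is canonicalized (largest organic fragment, canonical SMILES)
and annotated with its heavy-atom count and molecular weight; a supplied
molecular-weight column overrides the computed value.  Downstream analysis
retains only compounds up to a molecular-weight ceiling (1000 Da by
default).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chem import ChemError, canonical_compound, heavy_atom_count, mol_weight, parse_smiles

log = logging.getLogger(__name__)

DEFAULT_MW_MAX = 1000.0


@dataclass(frozen=True, order=True)
class CompoundRecord:
    """One input molecule after standardization.

    Attributes
    ----------
    compound_id:
        Opaque unique identifier.
    smiles:
        Canonical SMILES of the (largest-fragment) structure.
    heavy_atoms:
        Number of non-hydrogen atoms.
    mol_weight:
        Molecular weight in Daltons.
    """

    compound_id: str
    smiles: str
    heavy_atoms: int
    mol_weight: float


class InputTableError(ValueError):
    """Fatal problem with an input compound table (missing file/column, no records)."""


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def make_record(compound_id: str, smiles: str, mw: float | None = None,
                strip_stereo: bool = False) -> CompoundRecord:
    """Build a canonicalized :class:`CompoundRecord` from raw fields."""
    canonical = canonical_compound(smiles, strip_stereo=strip_stereo)
    mol = parse_smiles(canonical)
    heavy = heavy_atom_count(mol)
    if heavy < 1:
        raise ChemError(f"no heavy atoms in {smiles!r}")
    weight = float(mw) if mw is not None else mol_weight(mol)
    if not weight > 0:
        raise ChemError(f"non-positive molecular weight for {compound_id}")
    return CompoundRecord(compound_id, canonical, heavy, weight)


def read_compound_table(
    path: str | Path,
    id_column: str = "compound_id",
    smiles_column: str = "smiles",
    mw_column: str | None = None,
    delimiter: str | None = None,
    strip_stereo: bool = False,
) -> list[CompoundRecord]:
    """Read a delimited compound table into canonicalized records.

    Unparseable SMILES are logged and skipped (a summary count is logged);
    a missing file or column, a duplicated identifier, or zero parseable
    records raise :class:`InputTableError`.
    """
    path = Path(path)
    if not path.exists():
        raise InputTableError(f"input file not found: {path}")
    sep = delimiter or _sniff_delimiter(path)
    table = pd.read_csv(path, sep=sep, dtype=str)
    for col in [id_column, smiles_column] + ([mw_column] if mw_column else []):
        if col not in table.columns:
            raise InputTableError(
                f"column {col!r} not found in {path} (columns: {list(table.columns)})"
            )
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    skipped = 0
    for _, row in table.iterrows():
        cid = str(row[id_column]).strip()
        smi = str(row[smiles_column]).strip()
        mw = None
        if mw_column is not None and not pd.isna(row[mw_column]):
            mw = float(row[mw_column])
        try:
            rec = make_record(cid, smi, mw, strip_stereo=strip_stereo)
        except ChemError as exc:
            log.warning("skipping %s: %s", cid, exc)
            skipped += 1
            continue
        if cid in seen:
            raise InputTableError(f"duplicate compound_id {cid!r}")
        seen.add(cid)
        records.append(rec)
    if skipped:
        log.info("skipped %d unparseable record(s) of %d", skipped, len(table))
    if not records:
        raise InputTableError(f"no parseable compound records in {path}")
    return records


def read_smiles_file(path: str | Path, strip_stereo: bool = False) -> list[CompoundRecord]:
    """Read a headerless SMILES-only file; ids are auto-assigned C000001..."""
    path = Path(path)
    if not path.exists():
        raise InputTableError(f"input file not found: {path}")
    records: list[CompoundRecord] = []
    skipped = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            smi = line.strip()
            if not smi:
                continue
            try:
                records.append(make_record(f"C{i:06d}", smi, strip_stereo=strip_stereo))
            except ChemError as exc:
                log.warning("skipping line %d: %s", i, exc)
                skipped += 1
    if skipped:
        log.info("skipped %d unparseable line(s)", skipped)
    if not records:
        raise InputTableError(f"no parseable SMILES in {path}")
    return records


def filter_compounds(
    records: Iterable[CompoundRecord], mw_max: float = DEFAULT_MW_MAX
) -> list[CompoundRecord]:
    """Retain compounds with molecular weight <= ``mw_max`` (inclusive).

    Ordering is preserved; the number of removed records is logged and an
    empty result is legal (logged as a warning).
    """
    if not mw_max > 0:
        raise ValueError("mw_max must be positive")
    records = list(records)
    kept = [r for r in records if r.mol_weight <= mw_max]
    removed = len(records) - len(kept)
    if removed:
        log.info("molecular-weight filter removed %d of %d compounds", removed, len(records))
    if not kept:
        log.warning("molecular-weight filter removed every compound")
    return kept


def write_compound_table(records: Sequence[CompoundRecord], path: str | Path) -> None:
    """Write canonicalized records as CSV (compound_id, smiles, heavy_atoms, mol_weight)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_id", "smiles", "heavy_atoms", "mol_weight"])
        for r in records:
            writer.writerow([r.compound_id, r.smiles, r.heavy_atoms, f"{r.mol_weight:.3f}"])
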