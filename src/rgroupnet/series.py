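"""Assembling analogue series from decompositions.

An analogue series is a set of at least three compounds sharing one core and
differing only in the R-groups at the core's indexed substitution sites.
Compounds are grouped by canonical core; the fully unsubstituted analogue
(the core with hydrogen at every site) is matched into a candidate group by
direct structure lookup, since it has no cuttable bond of its own yet carries
the hydrogen R-group at each site.

Two assignment modes are supported.  In ``overlapping`` mode every core with
enough candidates becomes a series and compounds may appear in several.  In
``unique`` mode (default) each compound belongs to at most one series: cores
claim compounds greedily, largest candidate set first, ties broken by larger
core, then fewer sites, then core string, and a claiming core keeps its
series only if enough unclaimed candidates remain.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from .chem import saturate_core
from .compound_io import CompoundRecord
from .fragmentation import HYDROGEN, CoreKey, Decomposition, RGroup

log = logging.getLogger(__name__)

DEFAULT_MIN_MEMBERS = 3


@dataclass(frozen=True)
class AnalogueSeries:
    """A core shared by >= 3 compounds with per-member site assignments."""

    series_id: str
    core: CoreKey
    members: tuple[str, ...]  # sorted compound ids
    member_assignments: Mapping[str, tuple[RGroup, ...]]

    def site_table(self) -> dict[int, frozenset[RGroup]]:
        """Distinct R-groups observed at each site across members."""
        table: dict[int, set[RGroup]] = {s: set() for s in range(1, self.core.n_sites + 1)}
        for assignment in self.member_assignments.values():
            for i, rg in enumerate(assignment):
                table[i + 1].add(rg)
        return {s: frozenset(v) for s, v in table.items()}


@dataclass(frozen=True)
class SubstitutionSite:
    """One indexed substitution site of a series and its distinct R-groups."""

    series_id: str
    site_index: int
    rgroups: frozenset[RGroup]


def group_by_core(
    decompositions: Iterable[Decomposition],
    records: Sequence[CompoundRecord] | None = None,
) -> dict[CoreKey, dict[str, tuple[RGroup, ...]]]:
    """Group compounds by canonical core.

    For each core the candidate set maps compound id to one site assignment;
    a compound with several distinct assignments on the same core keeps the
    canonically smallest.  When ``records`` is given, any compound whose
    whole structure equals a core saturated with hydrogens joins that core's
    candidates with the all-hydrogen assignment (the unsubstituted analogue).
    """
    groups: dict[CoreKey, dict[str, tuple[RGroup, ...]]] = {}
    for dec in decompositions:
        cands = groups.setdefault(dec.core, {})
        prev = cands.get(dec.compound_id)
        if prev is None or tuple(r.smiles for r in dec.assignments) < tuple(
            r.smiles for r in prev
        ):
            cands[dec.compound_id] = dec.assignments
    if records is not None:
        by_structure: dict[str, list[str]] = {}
        for rec in records:
            by_structure.setdefault(rec.smiles, []).append(rec.compound_id)
        for core, cands in groups.items():
            for cid in by_structure.get(saturate_core(core.smiles), []):
                cands.setdefault(cid, (HYDROGEN,) * core.n_sites)
    return groups


def build_series(
    core_groups: Mapping[CoreKey, Mapping[str, tuple[RGroup, ...]]],
    min_members: int = DEFAULT_MIN_MEMBERS,
    assignment_mode: Literal["unique", "overlapping"] = "unique",
) -> list[AnalogueSeries]:
    """Turn core groups into analogue series of at least ``min_members``.

    In unique mode cores are processed greedily (candidate count descending,
    core heavy atoms descending, site count ascending, core string
    ascending); each core claims its still-unassigned candidates and the
    series is kept only if enough remain.
    """
    if min_members < 2:
        raise ValueError("min_members must be >= 2")
    order = sorted(
        core_groups,
        key=lambda c: (-len(core_groups[c]), -c.heavy_atoms, c.n_sites, c.smiles),
    )
    series: list[AnalogueSeries] = []
    claimed: set[str] = set()
    for core in order:
        cands = core_groups[core]
        if assignment_mode == "unique":
            taken = {cid: a for cid, a in cands.items() if cid not in claimed}
        else:
            taken = dict(cands)
        if len(taken) < min_members:
            continue
        if assignment_mode == "unique":
            claimed.update(taken)
        members = tuple(sorted(taken))
        series.append(
            AnalogueSeries(f"S{len(series) + 1:05d}", core, members,
                           {cid: taken[cid] for cid in members})
        )
    return series


def build_site_tables(series: Iterable[AnalogueSeries]) -> list[SubstitutionSite]:
    """One :class:`SubstitutionSite` per core site of every series."""
    sites: list[SubstitutionSite] = []
    for s in series:
        for idx, rgroups in sorted(s.site_table().items()):
            sites.append(SubstitutionSite(s.series_id, idx, rgroups))
    return sites


# ---------------------------------------------------------------------------
# delimited exports


def write_series_table(series: Sequence[AnalogueSeries], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["series_id", "core_smiles", "n_sites", "n_members", "members"])
        for s in series:
            w.writerow([s.series_id, s.core.smiles, s.core.n_sites, len(s.members),
                        ";".join(s.members)])


def write_site_tables(sites: Sequence[SubstitutionSite], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["series_id", "site_index", "rgroup_smiles"])
        for site in sites:
            for rg in sorted(site.rgroups):
                w.writerow([site.series_id, site.site_index, rg.smiles])


def read_site_tables(path: str | Path) -> list[SubstitutionSite]:
    """Read a site-table CSV back into :class:`SubstitutionSite` rows."""
    from .chem import rgroup_heavy_atoms

    acc: dict[tuple[str, int], set[RGroup]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            key = (row["series_id"], int(row["site_index"]))
            smi = row["rgroup_smiles"]
            acc.setdefault(key, set()).add(RGroup(smi, rgroup_heavy_atoms(smi)))
    return [
        SubstitutionSite(sid, idx, frozenset(rgs))
        for (sid, idx), rgs in sorted(acc.items())
    ]


def write_decomposition_audit(
    decompositions: Iterable[Decomposition], path: str | Path
) -> None:
    """Optional audit trail: one row per (decomposition, site)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "core_smiles", "n_sites", "site_index",
                    "rgroup_smiles", "rgroup_heavy"])
        for d in decompositions:
            for i, rg in enumerate(d.assignments):
                w.writerow([d.compound_id, d.core.smiles, d.core.n_sites, i + 1,
                            rg.smiles, rg.heavy_atoms])
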