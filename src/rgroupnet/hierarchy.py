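"""Replacement hierarchies and the searchable XML database.

For a frequently used R-group (the root), the first layer lists its top
replacements ranked by edge weight and the second layer the top onward
replacements of each first-layer group.  At the defaults (5 first-layer,
2 second-layer) a hierarchy defines at most ten root-first-second
replacement sequences.  Hierarchies for the top-ranked R-groups of the
final network form a database searchable by canonical R-group SMILES,
serialized as XML:

.. code-block:: xml

    <rgroup_database>
      <rgroup smiles="*O" rank="1" nd="12">
        <first smiles="*OC" ew="7">
          <second smiles="*N" ew="5"/>
        </first>
      </rgroup>
    </rgroup_database>

Document order is rank order; ties in edge weight are broken by ascending
SMILES so the selection is deterministic.  Because the final network omits
hydrogen, methyl and phenyl, methyl and phenyl can be read as additional
generic replacements applicable to every hierarchy.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence
from xml.etree import ElementTree as ET
from xml.sax.saxutils import quoteattr

import networkx as nx

from .chem import ChemError, canonical_rgroup
from .network import rank_nodes

log = logging.getLogger(__name__)

DEFAULT_N_FIRST = 5
DEFAULT_N_SECOND = 2

#: Informational note surfaced with every search result.
GENERIC_REPLACEMENTS_NOTE = (
    "methyl (*C) and phenyl (*c1ccccc1) were removed from the final network "
    "and can be considered additional generic replacements in all hierarchies"
)


@dataclass(frozen=True)
class SecondLayerEntry:
    rgroup: str
    ew: int


@dataclass(frozen=True)
class FirstLayerEntry:
    rgroup: str
    ew: int
    second_layer: tuple[SecondLayerEntry, ...]


@dataclass(frozen=True)
class ReplacementHierarchy:
    """A root R-group with ranked first- and second-layer replacements."""

    root: str
    root_nd: int
    rank: int
    first_layer: tuple[FirstLayerEntry, ...]

    def n_sequences(self) -> int:
        """Number of root-first-second replacement sequences."""
        return sum(len(f.second_layer) for f in self.first_layer)


class RootNotFoundError(KeyError):
    """Query R-group absent from the database; carries nearby roots by string."""

    def __init__(self, query: str, suggestions: Sequence[str]):
        super().__init__(query)
        self.query = query
        self.suggestions = tuple(suggestions)

    def __str__(self) -> str:
        hint = f" (nearest roots: {', '.join(self.suggestions)})" if self.suggestions else ""
        return f"R-group {self.query!r} not in database{hint}"


class DatabaseFormatError(ValueError):
    """Malformed or schema-violating XML database file."""


def _ranked_neighbors(net: nx.Graph, node: str, exclude: set[str]) -> list[tuple[str, int]]:
    pairs = [
        (nbr, int(net[node][nbr]["weight"]))
        for nbr in net.neighbors(node)
        if nbr not in exclude
    ]
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return pairs


def build_hierarchy(
    net: nx.Graph,
    root: str,
    n_first: int = DEFAULT_N_FIRST,
    n_second: int = DEFAULT_N_SECOND,
    rank: int = 0,
) -> ReplacementHierarchy:
    """Derive one root's replacement hierarchy from a weighted network.

    First layer: the root's neighbors ranked by edge weight, truncated to
    ``n_first``.  Second layer per first-layer group: its neighbors ranked
    by edge weight, excluding the root and the group itself, truncated to
    ``n_second``.  Layers come up short when neighbors run out.
    """
    if n_first < 1 or n_second < 1:
        raise ValueError("n_first and n_second must be >= 1")
    if root not in net:
        raise RootNotFoundError(root, _nearest(sorted(net.nodes), root))
    first_entries = []
    for f, ew in _ranked_neighbors(net, root, exclude=set())[:n_first]:
        second = tuple(
            SecondLayerEntry(s, sew)
            for s, sew in _ranked_neighbors(net, f, exclude={root, f})[:n_second]
        )
        first_entries.append(FirstLayerEntry(f, ew, second))
    return ReplacementHierarchy(root, int(net.degree(root)), rank, tuple(first_entries))


def build_database(
    net: nx.Graph,
    top_k: int = 500,
    n_first: int = DEFAULT_N_FIRST,
    n_second: int = DEFAULT_N_SECOND,
) -> list[ReplacementHierarchy]:
    """Hierarchies for the ``top_k`` highest-ranked R-groups, in rank order."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ranked = rank_nodes(net)
    if top_k > len(ranked):
        log.info("top_k=%d exceeds node count %d; building all", top_k, len(ranked))
    return [
        build_hierarchy(net, root, n_first, n_second, rank=i + 1)
        for i, root in enumerate(ranked[:top_k])
    ]


def _nearest(sorted_roots: Sequence[str], query: str, n: int = 4) -> list[str]:
    i = bisect.bisect_left(sorted_roots, query)
    lo, hi = max(0, i - n // 2), min(len(sorted_roots), i + n - n // 2)
    return list(sorted_roots[lo:hi])


def search(database: Sequence[ReplacementHierarchy], query: str) -> ReplacementHierarchy:
    """Exact-match a query R-group (canonicalized first) against the roots.

    Non-canonical forms of a root (e.g. the attachment point written at the
    other end) find the same hierarchy.  An unparseable query raises
    :class:`~rgroupnet.chem.ChemError`; an absent one raises
    :class:`RootNotFoundError` listing the nearest roots by string.
    """
    try:
        canonical = canonical_rgroup(query)
    except ChemError as exc:
        raise ChemError(f"invalid query R-group {query!r}: {exc}") from exc
    by_root = {h.root: h for h in database}
    if canonical in by_root:
        return by_root[canonical]
    raise RootNotFoundError(canonical, _nearest(sorted(by_root), canonical))


def format_hierarchy(h: ReplacementHierarchy) -> str:
    """Indented text tree of one hierarchy (for terminal display)."""
    lines = [f"{h.root}  (rank {h.rank}, ND {h.root_nd})"]
    for f in h.first_layer:
        lines.append(f"  {f.rgroup}  (EW {f.ew})")
        for s in f.second_layer:
            lines.append(f"    {s.rgroup}  (EW {s.ew})")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# XML serialization (deterministic writer, validating reader)


def write_xml(database: Sequence[ReplacementHierarchy], path: str | Path) -> None:
    """Serialize the database; write -> read -> write is byte-identical."""
    if not database:
        raise ValueError("refusing to write an empty database")
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', "<rgroup_database>"]
    for h in database:
        lines.append(
            f"  <rgroup smiles={quoteattr(h.root)} rank=\"{h.rank}\" nd=\"{h.root_nd}\">"
        )
        for f in h.first_layer:
            if f.second_layer:
                lines.append(f"    <first smiles={quoteattr(f.rgroup)} ew=\"{f.ew}\">")
                for s in f.second_layer:
                    lines.append(
                        f"      <second smiles={quoteattr(s.rgroup)} ew=\"{s.ew}\"/>"
                    )
                lines.append("    </first>")
            else:
                lines.append(f"    <first smiles={quoteattr(f.rgroup)} ew=\"{f.ew}\"/>")
        lines.append("  </rgroup>")
    lines.append("</rgroup_database>")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _require(condition: bool, path: str, message: str) -> None:
    if not condition:
        raise DatabaseFormatError(f"{path}: {message}")


def read_xml(path: str | Path) -> list[ReplacementHierarchy]:
    """Parse and validate a database file written by :func:`write_xml`."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise DatabaseFormatError(f"{path}: not well-formed XML: {exc}") from exc
    root = tree.getroot()
    _require(root.tag == "rgroup_database", "/", f"root element is {root.tag!r}")
    for child in root:
        _require(child.tag == "rgroup", f"/rgroup_database/{child.tag}",
                 "only <rgroup> elements allowed at top level")
    database: list[ReplacementHierarchy] = []
    seen_roots: set[str] = set()
    for i, el in enumerate(root, start=1):
        where = f"/rgroup_database/rgroup[{i}]"
        for attr in ("smiles", "rank", "nd"):
            _require(attr in el.attrib, where, f"missing attribute {attr!r}")
        smiles = el.attrib["smiles"]
        _require(smiles not in seen_roots, where, f"duplicate root {smiles!r}")
        seen_roots.add(smiles)
        firsts = []
        for j, fel in enumerate(el, start=1):
            fwhere = f"{where}/{fel.tag}[{j}]"
            _require(fel.tag == "first", fwhere,
                     "only <first> elements allowed inside <rgroup>")
            _require("smiles" in fel.attrib and "ew" in fel.attrib, fwhere,
                     "missing smiles/ew attribute")
            seconds = []
            for k, sel in enumerate(fel, start=1):
                swhere = f"{fwhere}/{sel.tag}[{k}]"
                _require(sel.tag == "second", swhere,
                         "only <second> elements allowed inside <first>")
                _require("smiles" in sel.attrib and "ew" in sel.attrib, swhere,
                         "missing smiles/ew attribute")
                seconds.append(SecondLayerEntry(sel.attrib["smiles"], int(sel.attrib["ew"])))
            _require(
                all(
                    a.ew > b.ew or (a.ew == b.ew and a.rgroup <= b.rgroup)
                    for a, b in zip(seconds, seconds[1:])
                ),
                fwhere, "second layer not sorted by ew desc / smiles asc",
            )
            firsts.append(FirstLayerEntry(fel.attrib["smiles"], int(fel.attrib["ew"]),
                                          tuple(seconds)))
        ews = [f.ew for f in firsts]
        _require(all(a >= b for a, b in zip(ews, ews[1:])), where,
                 "first layer not sorted by ew descending")
        database.append(
            ReplacementHierarchy(smiles, int(el.attrib["nd"]), int(el.attrib["rank"]),
                                 tuple(firsts))
        )
    return database
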