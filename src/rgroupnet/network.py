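"""The weighted R-group replacement network.

Nodes are unique R-groups (canonical fragment SMILES); an undirected edge
connects two R-groups that interchange at a substitution site, and its
weight (EW) counts the number of sites — over all analogue series — at which
the pair co-occurs.  Each site contributes at most one to any pair, however
many series members carry the two groups.  Node degree (ND, number of
distinct replacement partners) ranks R-groups by breadth of use.

Refinement removes the three generic R-groups that would otherwise dominate
every replacement ranking — hydrogen, methyl and phenyl — together with any
nodes left isolated.
"""

from __future__ import annotations

import csv
import itertools
import logging
from pathlib import Path
from typing import Iterable

import networkx as nx

from .chem import HYDROGEN_SMILES
from .fragmentation import RGroup
from .series import SubstitutionSite

log = logging.getLogger(__name__)

METHYL_SMILES = "*C"
PHENYL_SMILES = "*c1ccccc1"

#: R-groups removed when deriving the final network from the global one.
DEFAULT_REMOVE = frozenset({HYDROGEN_SMILES, METHYL_SMILES, PHENYL_SMILES})

DEFAULT_TOP_K = 500


def site_pairs(site: SubstitutionSite | Iterable[RGroup]) -> list[tuple[str, str]]:
    """All unordered pairs of distinct R-groups at one site.

    ``k`` distinct R-groups yield ``C(k, 2)`` bidirectional replacements
    (four R-groups give six).  Pairs are returned with endpoints in
    ascending canonical-SMILES order.
    """
    rgroups = site.rgroups if isinstance(site, SubstitutionSite) else site
    smis = sorted({r.smiles for r in rgroups})
    return list(itertools.combinations(smis, 2))


def build_network(sites: Iterable[SubstitutionSite]) -> nx.Graph:
    """Combine site-specific replacements into the global weighted network.

    Nodes are all distinct R-groups over all sites (including R-groups from
    single-R-group sites, which stay isolated); the weight of edge (a, b) is
    the number of sites whose R-group set contains both.
    """
    g = nx.Graph()
    for site in sites:
        for r in site.rgroups:
            if r.smiles not in g:
                g.add_node(r.smiles)
        for a, b in site_pairs(site):
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return g


def refine_network(
    net: nx.Graph,
    remove: Iterable[str] = DEFAULT_REMOVE,
    drop_isolated: bool = True,
) -> nx.Graph:
    """Remove generic R-groups (and their edges) from a network.

    Surviving edge weights are unchanged; with ``drop_isolated`` nodes left
    without any edge are removed as well.  Removing an absent node is a
    logged no-op.
    """
    out = net.copy()
    for smi in sorted(set(remove)):
        if smi in out:
            out.remove_node(smi)
        else:
            log.info("refine: node %s not in network (no-op)", smi)
    if drop_isolated:
        out.remove_nodes_from(list(nx.isolates(out)))
    return out


def rank_nodes(net: nx.Graph) -> list[str]:
    """Nodes by descending degree, ties by ascending canonical SMILES."""
    return sorted(net.nodes, key=lambda n: (-net.degree(n), n))


def top_k_subnetwork(net: nx.Graph, k: int = DEFAULT_TOP_K) -> nx.Graph:
    """Induced subgraph on the ``k`` highest-ranked nodes.

    Edges survive only when both endpoints rank in the top ``k``; a ``k``
    beyond the node count returns the whole network (logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > net.number_of_nodes():
        log.info("top_k=%d exceeds node count %d; returning full network",
                 k, net.number_of_nodes())
    keep = rank_nodes(net)[:k]
    return net.subgraph(keep).copy()


def total_weight(net: nx.Graph) -> int:
    return sum(d["weight"] for _, _, d in net.edges(data=True))


# ---------------------------------------------------------------------------
# CSV edge list (Cytoscape-ready)

EDGE_HEADER = "source,target,weight"


def write_edge_list(net: nx.Graph, path: str | Path, min_weight: int | None = None) -> None:
    """Write the weighted edge list as CSV.

    Header is exactly ``source,target,weight``; rows are sorted by weight
    descending, then source and target ascending; an optional minimum-weight
    filter keeps the file tractable for display tools.
    """
    rows = [
        (a, b, d["weight"]) if a < b else (b, a, d["weight"])
        for a, b, d in net.edges(data=True)
        if min_weight is None or d["weight"] >= min_weight
    ]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w", newline="") as fh:
        fh.write(EDGE_HEADER + "\n")
        w = csv.writer(fh, lineterminator="\n")
        for a, b, weight in rows:
            w.writerow([a, b, weight])


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a ``source,target,weight`` CSV back into a weighted graph.

    Validates the header, positive integer weights, absence of self-edges
    and of duplicate pairs.
    """
    g = nx.Graph()
    with open(path, newline="") as fh:
        header = fh.readline().strip()
        if header != EDGE_HEADER:
            raise ValueError(f"bad edge-list header {header!r}, expected {EDGE_HEADER!r}")
        for ln, row in enumerate(csv.reader(fh), start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ValueError(f"line {ln}: expected 3 columns, got {len(row)}")
            a, b, wtxt = row
            weight = int(wtxt)
            if weight < 1:
                raise ValueError(f"line {ln}: weight must be >= 1")
            if a == b:
                raise ValueError(f"line {ln}: self-edge {a!r}")
            if g.has_edge(a, b):
                raise ValueError(f"line {ln}: duplicate edge {a!r}-{b!r}")
            g.add_edge(a, b, weight=weight)
    return g


def unique_rgroups(sites: Iterable[SubstitutionSite]) -> set[str]:
    """All distinct R-group SMILES over the given sites."""
    out: set[str] = set()
    for site in sites:
        out.update(r.smiles for r in site.rgroups)
    return out
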