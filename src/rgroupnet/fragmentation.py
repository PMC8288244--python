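"""Compound-core decomposition by exocyclic single-bond cutting.

A compound is split into a **core** with indexed substitution sites plus one
**R-group** per cut, by deleting a set of acyclic single bonds between heavy
atoms ("heavy cuts").  In addition, any heavy atom carrying at least one
hydrogen can be marked as a virtual "hydrogen cut" site: the core gains an
attachment point there and the site carries the hydrogen R-group.  This is
the generalized (non-retrosynthetic) compound-core-relationship scheme: every
single exocyclic bond is a legal cut, so all substituents a molecule can
formally donate are enumerated, not only those defined by reaction rules.

A candidate decomposition is accepted only if

* exactly one fragment (the core) is incident to every heavy cut and each
  remaining fragment is incident to exactly one (peripheral-substituent
  condition);
* the core contains at least half of the compound's heavy atoms
  (``2 * core_heavy >= compound_heavy``, integer comparison);
* no R-group exceeds ``rgroup_max_heavy`` heavy atoms (13 by default);
* at least one heavy cut is present (pure-hydrogen cores are not
  enumerated) and the total number of sites does not exceed ``max_sites``.

Rejections are typed outcomes carrying the violated rule, not exceptions.

Enumeration is exhaustive over all cut subsets up to ``max_sites`` — a
deterministic superset of random bond sampling — with a per-compound attempt
budget guarding against hyper-flexible molecules.
"""

from __future__ import annotations

import functools
import itertools
import logging
from dataclasses import dataclass
from math import comb
from typing import Iterable, Literal, Sequence

import networkx as nx
from networkx.algorithms.isomorphism import (
    GraphMatcher,
    categorical_edge_match,
    categorical_node_match,
)
from rdkit import Chem

from .chem import HYDROGEN_SMILES, parse_smiles
from .compound_io import CompoundRecord

log = logging.getLogger(__name__)

DEFAULT_RGROUP_MAX_HEAVY = 13
DEFAULT_MAX_SITES = 4


@dataclass(frozen=True, order=True)
class RGroup:
    """A substituent fragment with one attachment point.

    ``heavy_atoms`` is 0 exactly for the hydrogen R-group.
    """

    smiles: str
    heavy_atoms: int


HYDROGEN = RGroup(HYDROGEN_SMILES, 0)


@dataclass(frozen=True, order=True)
class CoreKey:
    """A canonical core: SMILES with numbered attachment points [1*]..[k*]."""

    smiles: str
    n_sites: int
    heavy_atoms: int


@dataclass(frozen=True)
class Decomposition:
    """One accepted split of a compound into core + per-site R-groups.

    ``assignments[i]`` is the R-group at site ``i + 1``; assignments on
    symmetric cores are collapsed to a canonical orbit representative.
    """

    compound_id: str
    core: CoreKey
    assignments: tuple[RGroup, ...]

    @property
    def sort_key(self) -> tuple:
        return (self.core.smiles, tuple(r.smiles for r in self.assignments))


@dataclass(frozen=True)
class Rejection:
    """A typed refusal of a candidate decomposition, carrying the violated rule."""

    compound_id: str
    rule: Literal[
        "no_heavy_cut",
        "too_many_sites",
        "not_peripheral",
        "half_rule",
        "rgroup_size",
        "hydrogen_site_outside_core",
        "invalid_hydrogen_site",
    ]


@dataclass(frozen=True)
class CutSite:
    """A cuttable position: a heavy bond index or a virtual hydrogen-cut atom index."""

    kind: Literal["bond", "hydrogen"]
    index: int


@dataclass
class FragmentationConfig:
    max_sites: int = DEFAULT_MAX_SITES
    rgroup_max_heavy: int = DEFAULT_RGROUP_MAX_HEAVY
    hydrogen_cuts: bool = True
    # per-compound ceiling on evaluated cut combinations; beyond it the
    # compound is skipped with a warning
    cut_budget: int = 500_000


def eligible_cut_bonds(compound: CompoundRecord | str) -> list[CutSite]:
    """All legal cut positions of a compound.

    Returns every acyclic single bond between two heavy atoms as a
    ``bond`` cut, and every heavy atom bearing at least one hydrogen as a
    virtual ``hydrogen`` cut.  Ring bonds and double/triple/aromatic bonds
    are never cut.
    """
    smiles = compound.smiles if isinstance(compound, CompoundRecord) else compound
    mol = parse_smiles(smiles)
    cuts: list[CutSite] = []
    for bond in mol.GetBonds():
        if (
            bond.GetBondType() == Chem.BondType.SINGLE
            and not bond.IsInRing()
            and bond.GetBeginAtom().GetAtomicNum() > 1
            and bond.GetEndAtom().GetAtomicNum() > 1
        ):
            cuts.append(CutSite("bond", bond.GetIdx()))
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() > 1 and atom.GetTotalNumHs() >= 1:
            cuts.append(CutSite("hydrogen", atom.GetIdx()))
    return cuts


# ---------------------------------------------------------------------------
# internal machinery


@dataclass
class _CorePrep:
    """A core candidate after heavy cutting, before hydrogen sites are added."""

    core_mol: Chem.Mol                     # dummies labeled with provisional cut ids
    core_atoms: frozenset[int]             # original atom indices inside the core
    atom_to_local: dict[int, int]          # original atom index -> core-local index
    rgroup_by_label: dict[int, RGroup]     # provisional cut id -> R-group
    core_heavy: int


def _fragment_on_heavy(
    mol: Chem.Mol, compound_id: str, heavy_bonds: Sequence[int], compound_heavy: int,
    cfg: FragmentationConfig,
) -> list[_CorePrep | Rejection]:
    """Cut the heavy bonds and evaluate each legal core orientation.

    For a single cut both fragments are incident to all cuts, so both
    orientations are evaluated; for two or more cuts at most one fragment
    can be.
    """
    m = len(heavy_bonds)
    frag_mol = Chem.FragmentOnBonds(
        mol, list(heavy_bonds), addDummies=True,
        dummyLabels=[(i + 1, i + 1) for i in range(m)],
    )
    frag_atom_idx = Chem.GetMolFrags(frag_mol)
    try:
        frag_mols = Chem.GetMolFrags(frag_mol, asMols=True, sanitizeFrags=True)
    except Chem.MolSanitizeException:
        return [Rejection(compound_id, "not_peripheral")]
    n_orig = mol.GetNumAtoms()
    labels: list[list[int]] = []
    for idx_tuple, fmol in zip(frag_atom_idx, frag_mols):
        labels.append(sorted(
            a.GetIsotope() for a in fmol.GetAtoms() if a.GetAtomicNum() == 0
        ))
    all_labels = list(range(1, m + 1))
    candidates = [i for i, ls in enumerate(labels) if ls == all_labels]
    if not candidates:
        return [Rejection(compound_id, "not_peripheral")]
    out: list[_CorePrep | Rejection] = []
    for ci in candidates:
        ok = True
        rgroup_by_label: dict[int, RGroup] = {}
        for oi, (idx_tuple, fmol) in enumerate(zip(frag_atom_idx, frag_mols)):
            if oi == ci:
                continue
            if len(labels[oi]) != 1:
                out.append(Rejection(compound_id, "not_peripheral"))
                ok = False
                break
            heavy = sum(1 for a in fmol.GetAtoms() if a.GetAtomicNum() > 1)
            if heavy > cfg.rgroup_max_heavy:
                out.append(Rejection(compound_id, "rgroup_size"))
                ok = False
                break
            rw = Chem.RWMol(fmol)
            for a in rw.GetAtoms():
                if a.GetAtomicNum() == 0:
                    a.SetIsotope(0)
            rgroup_by_label[labels[oi][0]] = RGroup(Chem.MolToSmiles(rw.GetMol()), heavy)
        if not ok:
            continue
        core_fmol = frag_mols[ci]
        core_heavy = sum(1 for a in core_fmol.GetAtoms() if a.GetAtomicNum() > 1)
        if 2 * core_heavy < compound_heavy:
            out.append(Rejection(compound_id, "half_rule"))
            continue
        orig_atoms = [i for i in frag_atom_idx[ci] if i < n_orig]
        # FragmentOnBonds preserves original atom order and appends dummies,
        # so fragment atom tuples list original indices in core-local order
        # (dummies interleave only at the end of the tuple).
        atom_to_local: dict[int, int] = {}
        for local, orig in enumerate(frag_atom_idx[ci]):
            if orig < n_orig:
                atom_to_local[orig] = local
        out.append(_CorePrep(core_fmol, frozenset(orig_atoms), atom_to_local,
                             rgroup_by_label, core_heavy))
    return out


def _finalize(
    prep: _CorePrep, compound_id: str, h_atoms_local: Sequence[int], n_heavy_sites: int,
) -> Decomposition | Rejection:
    """Attach hydrogen-site dummies and canonicalize core numbering."""
    rw = Chem.RWMol(prep.core_mol)
    label = n_heavy_sites
    for local in h_atoms_local:
        label += 1
        dummy = Chem.Atom(0)
        dummy.SetIsotope(label)
        di = rw.AddAtom(dummy)
        rw.AddBond(local, di, Chem.BondType.SINGLE)
        tgt = rw.GetAtomWithIdx(local)
        if tgt.GetNumExplicitHs() > 0:
            tgt.SetNumExplicitHs(tgt.GetNumExplicitHs() - 1)
    core = rw.GetMol()
    try:
        Chem.SanitizeMol(core)
    except Chem.MolSanitizeException:
        return Rejection(compound_id, "invalid_hydrogen_site")
    # canonical site numbering: rank atoms of the label-free core and number
    # the attachment points 1..k along canonical ranks
    plain = Chem.RWMol(core)
    for a in plain.GetAtoms():
        if a.GetAtomicNum() == 0:
            a.SetIsotope(0)
    ranks = list(Chem.CanonicalRankAtoms(plain.GetMol(), breakTies=True))
    dummies = [a.GetIdx() for a in core.GetAtoms() if a.GetAtomicNum() == 0]
    dummies.sort(key=lambda i: ranks[i])
    site_of_atom = {ai: s + 1 for s, ai in enumerate(dummies)}
    provisional = {ai: core.GetAtomWithIdx(ai).GetIsotope() for ai in dummies}
    for ai, site in site_of_atom.items():
        core.GetAtomWithIdx(ai).SetIsotope(site)
    core_smiles = Chem.MolToSmiles(core)
    k = len(dummies)
    assignments: list[RGroup | None] = [None] * k
    for ai, site in site_of_atom.items():
        lab = provisional[ai]
        assignments[site - 1] = prep.rgroup_by_label.get(lab, HYDROGEN)
    key = CoreKey(core_smiles, k, prep.core_heavy)
    assigned = canonical_assignment(key, tuple(assignments))  # type: ignore[arg-type]
    return Decomposition(compound_id, key, assigned)


def _graph_of(core_smiles: str) -> tuple[nx.Graph, dict[int, int]]:
    params = Chem.SmilesParserParams()
    params.removeHs = False
    mol = Chem.MolFromSmiles(core_smiles, params)
    g = nx.Graph()
    site_of: dict[int, int] = {}
    for a in mol.GetAtoms():
        iso = a.GetIsotope() if a.GetAtomicNum() > 0 else 0
        g.add_node(a.GetIdx(), z=a.GetAtomicNum(), q=a.GetFormalCharge(),
                   ar=a.GetIsAromatic(), h=a.GetTotalNumHs(), iso=iso)
        if a.GetAtomicNum() == 0:
            site_of[a.GetIdx()] = a.GetIsotope()
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), t=str(b.GetBondType()))
    return g, site_of


@functools.lru_cache(maxsize=50_000)
def site_permutations(core_smiles: str, max_isomorphisms: int = 5000) -> tuple[tuple[int, ...], ...]:
    """Site-index permutations induced by graph automorphisms of a core.

    The returned tuples map site ``i + 1`` to ``perm[i]``.  Site labels are
    ignored during matching so that symmetry-equivalent attachment points may
    interchange.  Enumeration is capped; the cap only ever shrinks the
    collapse group, never differently for the same core string.
    """
    g, site_of = _graph_of(core_smiles)
    matcher = GraphMatcher(
        g, g,
        node_match=categorical_node_match(["z", "q", "ar", "h"], [0, 0, False, 0]),
        edge_match=categorical_edge_match("t", ""),
    )
    sites_sorted = sorted(site_of, key=lambda ai: site_of[ai])
    perms: set[tuple[int, ...]] = set()
    for n, iso in enumerate(matcher.isomorphisms_iter()):
        perms.add(tuple(site_of[iso[ai]] for ai in sites_sorted))
        if n + 1 >= max_isomorphisms:
            log.warning("automorphism cap reached for core %s", core_smiles)
            break
    perms.add(tuple(range(1, len(sites_sorted) + 1)))
    return tuple(sorted(perms))


def canonical_assignment(core: CoreKey, assignments: tuple[RGroup, ...]) -> tuple[RGroup, ...]:
    """Collapse symmetry-equivalent site assignments to one orbit representative.

    Among all images of ``assignments`` under the core's site permutations,
    the lexicographically smallest (by per-site R-group SMILES) is returned;
    asymmetric cores return the input unchanged.
    """
    if len(assignments) != core.n_sites:
        raise ValueError("assignments must cover every core site")
    perms = site_permutations(core.smiles)
    if len(perms) == 1:
        return assignments
    best: tuple[RGroup, ...] | None = None
    for perm in perms:
        image: list[RGroup | None] = [None] * core.n_sites
        for i, site in enumerate(perm):
            image[site - 1] = assignments[i]
        cand = tuple(image)  # type: ignore[assignment]
        if best is None or tuple(r.smiles for r in cand) < tuple(r.smiles for r in best):
            best = cand
    return best  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# public decomposition API


def decompose(
    compound: CompoundRecord,
    cut_set: Iterable[CutSite],
    config: FragmentationConfig | None = None,
) -> list[Decomposition | Rejection]:
    """Evaluate one explicit cut set against a compound.

    Returns one outcome per legal core orientation (two only for a single
    heavy cut that splits the molecule into two half-rule-compatible parts);
    each outcome is either an accepted :class:`Decomposition` or a
    :class:`Rejection` naming the violated rule.
    """
    cfg = config or FragmentationConfig()
    cuts = list(cut_set)
    heavy = [c.index for c in cuts if c.kind == "bond"]
    hydros = sorted(c.index for c in cuts if c.kind == "hydrogen")
    if not heavy:
        return [Rejection(compound.compound_id, "no_heavy_cut")]
    if len(heavy) + len(hydros) > cfg.max_sites:
        return [Rejection(compound.compound_id, "too_many_sites")]
    mol = parse_smiles(compound.smiles)
    for ai in hydros:
        if mol.GetAtomWithIdx(ai).GetTotalNumHs() < 1:
            return [Rejection(compound.compound_id, "invalid_hydrogen_site")]
    outcomes: list[Decomposition | Rejection] = []
    for prep in _fragment_on_heavy(mol, compound.compound_id, heavy,
                                   compound.heavy_atoms, cfg):
        if isinstance(prep, Rejection):
            outcomes.append(prep)
            continue
        if any(ai not in prep.core_atoms for ai in hydros):
            outcomes.append(Rejection(compound.compound_id, "hydrogen_site_outside_core"))
            continue
        locals_ = [prep.atom_to_local[ai] for ai in hydros]
        outcomes.append(_finalize(prep, compound.compound_id, locals_, len(heavy)))
    return outcomes


def enumerate_decompositions(
    compound: CompoundRecord,
    config: FragmentationConfig | None = None,
) -> list[Decomposition]:
    """All accepted decompositions of a compound, deduplicated and sorted.

    Exhaustively enumerates heavy-cut subsets of size 1..``max_sites`` and,
    for each accepted core, every subset of hydrogen-bearing core positions
    filling the remaining sites.  Results are deduplicated on
    (core, canonical assignment) and sorted by core SMILES then assignment.
    Compounds whose cut-combination count exceeds the budget are skipped
    with a warning.
    """
    cfg = config or FragmentationConfig()
    mol = parse_smiles(compound.smiles)
    cuts = eligible_cut_bonds(compound)
    heavy_bonds = [c.index for c in cuts if c.kind == "bond"]
    h_atoms = set(c.index for c in cuts if c.kind == "hydrogen") if cfg.hydrogen_cuts else set()
    b = len(heavy_bonds)
    n_heavy_subsets = sum(comb(b, m) for m in range(1, cfg.max_sites + 1))
    if n_heavy_subsets > cfg.cut_budget:
        log.warning(
            "skipping %s: %d heavy-cut combinations exceed budget %d",
            compound.compound_id, n_heavy_subsets, cfg.cut_budget,
        )
        return []
    attempts = 0
    found: dict[tuple, Decomposition] = {}
    for m in range(1, cfg.max_sites + 1):
        for heavy_subset in itertools.combinations(heavy_bonds, m):
            attempts += 1
            if attempts > cfg.cut_budget:
                log.warning("skipping %s: cut budget %d exhausted",
                            compound.compound_id, cfg.cut_budget)
                return []
            for prep in _fragment_on_heavy(mol, compound.compound_id, heavy_subset,
                                           compound.heavy_atoms, cfg):
                if isinstance(prep, Rejection):
                    continue
                h_candidates = sorted(prep.core_atoms & h_atoms)
                for hn in range(0, cfg.max_sites - m + 1):
                    for h_subset in itertools.combinations(h_candidates, hn):
                        attempts += 1
                        if attempts > cfg.cut_budget:
                            log.warning("skipping %s: cut budget %d exhausted",
                                        compound.compound_id, cfg.cut_budget)
                            return []
                        locals_ = [prep.atom_to_local[ai] for ai in h_subset]
                        res = _finalize(prep, compound.compound_id, locals_, m)
                        if isinstance(res, Decomposition):
                            found.setdefault(res.sort_key, res)
    return sorted(found.values(), key=lambda d: d.sort_key)
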