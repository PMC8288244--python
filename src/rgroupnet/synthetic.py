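"""Seeded combinatorial analogue libraries with known ground truth.

The generator enumerates substituent combinations on rigid ring scaffolds
with numbered attachment points, producing a compound table together with
the series membership, per-site R-group tables and replacement edge list
that the pipeline is expected to recover.  It emulates the structural
regularities the pipeline assumes about curated bioactive compounds —
shared cores, enumerated substituents at indexed sites, hydrogen as a
substituent state — and nothing else (no activity data, no property
distributions).

Ground truth is exact only under the generator's recoverability
conditions, validated by default:

* scaffolds are rigid ring systems (no cuttable internal bond) with at
  most four designed sites, each on a hydrogen-bearing atom;
* every substituent fits the 13-heavy-atom cap and the per-compound sum of
  largest pool substituents never violates the half rule;
* for any scaffold reaching series size, every designed site varies
  (>= 2 distinct substituents among members) and no pool can be absorbed
  into an enlarged core (hydrogen present, or a one-atom substituent
  present, or at least two distinct attachment elements).

``validate=False`` ("violator" mode) skips these checks to exercise
rejection paths; its ground truth is not meaningful for equality checks.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
from rdkit import Chem

from .chem import HYDROGEN_SMILES, canonical_rgroup, heavy_atom_count, parse_smiles
from .compound_io import CompoundRecord, make_record
from .fragmentation import eligible_cut_bonds

log = logging.getLogger(__name__)

#: Rigid, symmetry-free scaffold templates (sites on hydrogen-bearing ring atoms).
SCAFFOLD_VOCABULARY: tuple[str, ...] = (
    "[*:1]c1ccc2ncc([*:2])cc2c1",        # quinoline, 2 sites
    "[*:1]c1cc2ccccc2[nH]1",             # 2-substituted indole
    "[*:1]c1cc2ccccc2o1",                # 2-substituted benzofuran
    "[*:1]c1nc2ccc([*:2])cc2[nH]1",      # benzimidazole, 2 sites
    "O=C1C=C([*:1])Oc2ccc([*:2])cc21",   # chromone, 2 sites
    "[*:1]c1ccc2ccccc2c1",               # 2-substituted naphthalene
)

#: Small substituents with diverse attachment elements (all <= 4 heavy atoms).
SUBSTITUENT_VOCABULARY: tuple[str, ...] = (
    "*F", "*Cl", "*Br", "*C", "*CC", "*C(C)C", "*O", "*OC", "*OCC",
    "*N", "*NC", "*C#N", "*C(F)(F)F", "*S", "*SC", "*C=C", "*C(=O)O",
)

#: Rigid singleton molecules structurally unrelated to the scaffolds.
DECOY_VOCABULARY: tuple[str, ...] = (
    "c1ccc2sccc2c1",                # benzothiophene
    "c1ccc2cc3ccccc3cc2c1",         # anthracene
    "c1ccc2c(c1)[nH]c1ccccc12",     # carbazole
    "c1ccc2c(c1)oc1ccccc12",        # dibenzofuran
    "c1ccc2c(c1)ccc1ccccc12",       # phenanthrene
    "c1ccc2c(c1)sc1ccccc12",        # dibenzothiophene
    "c1ccc2c(c1)ncc1ccccc12",       # acridine-like aza ring
    "c1cc2ccc3cccc4ccc(c1)c2c34",   # pyrene
    "c1ccc2c(c1)cc1ccc3ccccc3c1n2", # fused aza system
    "c1ccc2c(c1)cnc1ccccc12",       # phenanthridine
    "c1cnc2[nH]ccc2c1",             # azaindole
    "c1ccc2nsnc2c1",                # benzothiadiazole
)

HYDROGEN_TOKENS = {"H", "[H]", "*[H]", "[H]*", HYDROGEN_SMILES}


@dataclass(frozen=True)
class ScaffoldSpec:
    """One core template with per-site substituent pools."""

    template: str
    pools: tuple[tuple[str, ...], ...]


@dataclass(frozen=True)
class LibrarySpec:
    """A reproducible combinatorial library definition.

    ``fill`` is the fraction of the full combination enumeration to emit
    (seeded sampling without replacement when < 1); ``decoys`` adds that
    many unrelated singleton molecules from :data:`DECOY_VOCABULARY`.
    """

    scaffolds: tuple[ScaffoldSpec, ...]
    fill: float = 1.0
    seed: int = 0
    decoys: int = 0


@dataclass(frozen=True)
class ExpectedSeries:
    """Ground-truth series: member ids and per-designed-site R-group sets."""

    scaffold_index: int
    members: frozenset[str]
    site_tables: tuple[frozenset[str], ...]


@dataclass(frozen=True)
class GroundTruth:
    series: tuple[ExpectedSeries, ...]
    edges: Mapping[tuple[str, str], int]

    def site_rgroup_sets(self) -> list[frozenset[str]]:
        return [t for es in self.series for t in es.site_tables]


class LibrarySpecError(ValueError):
    """Invalid or non-recoverable library specification."""


def _canonical_pool(pool: Sequence[str], where: str) -> tuple[str, ...]:
    out: list[str] = []
    for sub in pool:
        if sub in HYDROGEN_TOKENS:
            smi = HYDROGEN_SMILES
        else:
            try:
                smi = canonical_rgroup(sub)
            except ValueError as exc:
                raise LibrarySpecError(f"{where}: bad substituent {sub!r}: {exc}") from exc
        if smi in out:
            raise LibrarySpecError(f"{where}: duplicate substituent {sub!r}")
        out.append(smi)
    if not out:
        raise LibrarySpecError(f"{where}: empty pool")
    return tuple(out)


def _attachment_element(rgroup_smiles: str) -> int:
    if rgroup_smiles == HYDROGEN_SMILES:
        return 1
    params = Chem.SmilesParserParams()
    params.removeHs = False
    mol = Chem.MolFromSmiles(rgroup_smiles, params)
    dummy = next(a for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
    return dummy.GetNeighbors()[0].GetAtomicNum()


def _rgroup_heavy(rgroup_smiles: str) -> int:
    if rgroup_smiles == HYDROGEN_SMILES:
        return 0
    params = Chem.SmilesParserParams()
    params.removeHs = False
    return heavy_atom_count(Chem.MolFromSmiles(rgroup_smiles, params))


def _assemble(template_mol: Chem.Mol, substituents: Sequence[str]) -> str:
    """Attach one substituent per numbered site; hydrogen saturates the site."""
    combined = Chem.RWMol(template_mol)
    for site, sub in enumerate(substituents, start=1):
        if sub == HYDROGEN_SMILES:
            continue
        params = Chem.SmilesParserParams()
        params.removeHs = False
        frag = Chem.RWMol(Chem.MolFromSmiles(sub, params))
        for a in frag.GetAtoms():
            if a.GetAtomicNum() == 0:
                a.SetAtomMapNum(site)
        combined = Chem.RWMol(Chem.CombineMols(combined.GetMol(), frag.GetMol()))
    zipped = Chem.molzip(combined.GetMol())
    rw = Chem.RWMol(zipped)
    for a in rw.GetAtoms():
        if a.GetAtomicNum() == 0:  # unfilled sites become hydrogen
            a.SetAtomicNum(1)
            a.SetAtomMapNum(0)
            a.SetIsotope(0)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    mol = Chem.RemoveHs(mol)
    return Chem.MolToSmiles(mol)


def _validate_scaffold(idx: int, template_mol: Chem.Mol, pools: Sequence[Sequence[str]],
                       saturated: str) -> None:
    where = f"scaffold[{idx}]"
    k = len(pools)
    n_sites = sum(1 for a in template_mol.GetAtoms() if a.GetAtomicNum() == 0)
    if n_sites != k:
        raise LibrarySpecError(f"{where}: template has {n_sites} sites but {k} pools")
    if k < 1 or k > 4:
        raise LibrarySpecError(f"{where}: site count {k} outside 1..4")
    heavy = heavy_atom_count(template_mol)
    if heavy < 8:
        raise LibrarySpecError(f"{where}: scaffold must have >= 8 heavy atoms, got {heavy}")
    if any(c.kind == "bond" for c in eligible_cut_bonds(saturated)):
        raise LibrarySpecError(f"{where}: scaffold is not rigid (has cuttable bonds)")
    for j, pool in enumerate(pools, start=1):
        oversized = [s for s in pool if _rgroup_heavy(s) > 13]
        if oversized:
            raise LibrarySpecError(f"{where} site {j}: substituents over 13 heavy atoms: {oversized}")
    worst = sum(max(_rgroup_heavy(s) for s in pool) for pool in pools)
    if worst > heavy:
        raise LibrarySpecError(
            f"{where}: largest substituent combination ({worst} heavy atoms) can "
            f"violate the half rule against a {heavy}-atom core"
        )


def _validate_recoverable(idx: int, members: Sequence[tuple[str, ...]]) -> None:
    """Check that a series-sized scaffold's emitted members determine its core."""
    where = f"scaffold[{idx}]"
    k = len(members[0])
    for j in range(k):
        values = {m[j] for m in members}
        if len(values) < 2:
            raise LibrarySpecError(
                f"{where} site {j + 1}: only one distinct substituent among emitted "
                "members; raise fill or diversify the pool"
            )
        if HYDROGEN_SMILES in values:
            continue
        if any(_rgroup_heavy(v) == 1 for v in values):
            continue
        if len({_attachment_element(v) for v in values}) >= 2:
            continue
        raise LibrarySpecError(
            f"{where} site {j + 1}: all substituents share an extendable attachment "
            "prefix; the core would be ambiguous"
        )


def generate_library(
    spec: LibrarySpec, validate: bool = True
) -> tuple[list[CompoundRecord], GroundTruth]:
    """Enumerate (or seeded-sample) the library and its ground truth.

    Returns canonicalized compound records plus the expected series, site
    tables and replacement edges.  Decoy singletons never perturb the
    ground truth.
    """
    rng = random.Random(spec.seed)
    records: list[CompoundRecord] = []
    seen_structures: dict[str, str] = {}
    expected: list[ExpectedSeries] = []
    counter = 0
    saturations = []
    for si, sc in enumerate(spec.scaffolds):
        template_mol = Chem.MolFromSmiles(sc.template)
        if template_mol is None:
            raise LibrarySpecError(f"scaffold[{si}]: unparseable template {sc.template!r}")
        pools = tuple(_canonical_pool(p, f"scaffold[{si}] site {j + 1}")
                      for j, p in enumerate(sc.pools))
        saturated = _assemble(template_mol, tuple(HYDROGEN_SMILES for _ in pools))
        if validate:
            if saturated in saturations:
                raise LibrarySpecError(
                    f"scaffold[{si}] shares its parent ring system with an earlier "
                    "scaffold; series membership would be ambiguous"
                )
            _validate_scaffold(si, template_mol, pools, saturated)
        saturations.append(saturated)
        combos = list(itertools.product(*pools))
        if not 0 < spec.fill <= 1:
            raise LibrarySpecError("fill must be in (0, 1]")
        if spec.fill < 1:
            n_emit = max(1, round(spec.fill * len(combos)))
            combos = [combos[i] for i in sorted(rng.sample(range(len(combos)), n_emit))]
        member_ids: list[str] = []
        member_combos: list[tuple[str, ...]] = []
        for combo in combos:
            counter += 1
            cid = f"L{counter:05d}"
            smiles = _assemble(template_mol, combo)
            if smiles in seen_structures:
                raise LibrarySpecError(
                    f"structure collision: {cid} duplicates {seen_structures[smiles]}"
                )
            seen_structures[smiles] = cid
            records.append(make_record(cid, smiles))
            member_ids.append(cid)
            member_combos.append(combo)
        if len(member_ids) >= 3:
            if validate:
                _validate_recoverable(si, member_combos)
            tables = tuple(
                frozenset(m[j] for m in member_combos) for j in range(len(pools))
            )
            expected.append(ExpectedSeries(si, frozenset(member_ids), tables))
        else:
            log.info("scaffold[%d]: %d member(s), below series size", si, len(member_ids))
    if spec.decoys > len(DECOY_VOCABULARY):
        raise LibrarySpecError(
            f"at most {len(DECOY_VOCABULARY)} decoys available, {spec.decoys} requested"
        )
    for di in range(spec.decoys):
        smiles = Chem.MolToSmiles(parse_smiles(DECOY_VOCABULARY[di]))
        if validate and smiles in saturations:
            raise LibrarySpecError(f"decoy {di} coincides with a scaffold")
        if smiles in seen_structures:
            raise LibrarySpecError(f"decoy {di} duplicates {seen_structures[smiles]}")
        seen_structures[smiles] = f"D{di + 1:04d}"
        records.append(make_record(f"D{di + 1:04d}", smiles))
    edges: dict[tuple[str, str], int] = {}
    for es in expected:
        for table in es.site_tables:
            rs = sorted(table)
            for i in range(len(rs)):
                for j in range(i + 1, len(rs)):
                    edges[(rs[i], rs[j])] = edges.get((rs[i], rs[j]), 0) + 1
    return records, GroundTruth(tuple(expected), edges)


def oracle_network(ground_truth: GroundTruth) -> nx.Graph:
    """The expected replacement network by the naive double-loop algorithm.

    Independent of :func:`rgroupnet.network.build_network`: iterates every
    ground-truth site table and counts co-occurring pairs directly.
    """
    g = nx.Graph()
    for table in ground_truth.site_rgroup_sets():
        rs = sorted(table)
        for r in rs:
            if r not in g:
                g.add_node(r)
        for i in range(len(rs)):
            for j in range(i + 1, len(rs)):
                if g.has_edge(rs[i], rs[j]):
                    g[rs[i]][rs[j]]["weight"] += 1
                else:
                    g.add_edge(rs[i], rs[j], weight=1)
    return g


def random_library_spec(seed: int) -> LibrarySpec:
    """A seeded, recoverable random library specification.

    Samples 1-2 scaffolds and, per site, hydrogen plus 2-3 substituents
    from the vocabularies; full enumeration (fill=1) and 0-2 decoys.
    """
    rng = random.Random(seed)
    n_scaffolds = rng.randint(1, 2)
    templates = rng.sample(SCAFFOLD_VOCABULARY, n_scaffolds)
    scaffolds = []
    for t in templates:
        k = t.count("*")
        pools = tuple(
            tuple(["H"] + rng.sample(SUBSTITUENT_VOCABULARY, rng.randint(2, 3)))
            for _ in range(k)
        )
        scaffolds.append(ScaffoldSpec(t, pools))
    return LibrarySpec(tuple(scaffolds), fill=1.0, seed=seed, decoys=rng.randint(0, 2))


def linear_chain(n_heavy: int) -> str:
    """A linear all-carbon substituent of ``n_heavy`` atoms (for stress tests)."""
    if n_heavy < 1:
        raise ValueError("n_heavy must be >= 1")
    return "*" + "C" * n_heavy
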