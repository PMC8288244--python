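"""Shared RDKit helpers: canonicalization of molecules, cores and R-group fragments.

Conventions used throughout the package:

* A **compound** is a plain canonical SMILES string (no attachment points).
* An **R-group** is a fragment SMILES with exactly one unlabeled attachment
  point ``*`` (dummy atom, isotope 0).  The hydrogen R-group is the unique
  fragment with zero heavy atoms and the fixed canonical form ``*[H]``.
* A **core** is a fragment SMILES whose attachment points carry isotope
  labels ``[1*] .. [k*]`` numbering the substitution sites.  Numbering is
  canonical: the same chemical core produced from different compounds yields
  the identical string (site indices follow canonical atom ranks of the
  unlabeled core).
"""

from __future__ import annotations

import functools

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Fixed canonical representation of the hydrogen R-group (zero heavy atoms).
HYDROGEN_SMILES = "*[H]"


class ChemError(ValueError):
    """Raised for unparseable or structurally invalid chemical input."""


def parse_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`ChemError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemError(f"unparseable SMILES: {smiles!r}")
    return mol


def heavy_atom_count(mol: Chem.Mol) -> int:
    """Number of non-hydrogen, non-dummy atoms."""
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def mol_weight(mol: Chem.Mol) -> float:
    return float(Descriptors.MolWt(mol))


_largest_fragment = rdMolStandardize.LargestFragmentChooser()


def canonical_compound(smiles: str, strip_stereo: bool = False) -> str:
    """Canonical SMILES of the largest organic fragment of *smiles*.

    Multi-fragment records (salts, mixtures) are reduced to their largest
    organic fragment; set ``strip_stereo`` to drop stereodescriptors from
    fragment identity.
    """
    mol = parse_smiles(smiles)
    if len(Chem.GetMolFrags(mol)) > 1:
        mol = _largest_fragment.choose(mol)
    if strip_stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def _parse_fragment(smiles: str) -> Chem.Mol:
    params = Chem.SmilesParserParams()
    params.removeHs = False
    mol = Chem.MolFromSmiles(smiles, params)
    if mol is None:
        raise ChemError(f"unparseable fragment SMILES: {smiles!r}")
    return mol


def canonical_rgroup(smiles: str) -> str:
    """Canonicalize an R-group fragment carrying one attachment point.

    Accepts any SMILES with exactly one dummy atom; attachment-point labels
    (isotopes, atom maps) are cleared so that the same substituent observed
    at different sites maps to one identity.  Fragments whose only non-dummy
    atoms are hydrogens collapse to :data:`HYDROGEN_SMILES`.
    """
    mol = _parse_fragment(smiles)
    dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise ChemError(
            f"R-group must have exactly one attachment point, got {len(dummies)}: {smiles!r}"
        )
    if heavy_atom_count(mol) == 0:
        return HYDROGEN_SMILES
    rw = Chem.RWMol(mol)
    for a in rw.GetAtoms():
        a.SetAtomMapNum(0)
        if a.GetAtomicNum() == 0:
            a.SetIsotope(0)
    return Chem.MolToSmiles(Chem.RemoveHs(rw.GetMol()))


def rgroup_heavy_atoms(smiles: str) -> int:
    """Heavy-atom count of an R-group fragment (0 for the hydrogen R-group)."""
    if smiles == HYDROGEN_SMILES:
        return 0
    return heavy_atom_count(_parse_fragment(smiles))


@functools.lru_cache(maxsize=100_000)
def saturate_core(core_smiles: str) -> str:
    """Replace every attachment point of a core with hydrogen.

    Returns the canonical SMILES of the resulting plain molecule, i.e. the
    fully unsubstituted (all-hydrogen) analogue of the core.
    """
    mol = _parse_fragment(core_smiles)
    rw = Chem.RWMol(mol)
    for a in rw.GetAtoms():
        if a.GetAtomicNum() == 0:
            a.SetAtomicNum(1)
            a.SetIsotope(0)
            a.SetAtomMapNum(0)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    out = Chem.RemoveHs(out)
    return Chem.MolToSmiles(out)
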