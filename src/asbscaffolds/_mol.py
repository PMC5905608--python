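"""Low-level RDKit helpers shared across the package.

Attachment points are dummy atoms (atomic number 0) whose atom map number
carries the substitution-site label (1..n). Substituent fragments carry a
single dummy whose map number identifies the site they occupy. Heavy-atom
counts never include dummies or hydrogens, so size arithmetic is unambiguous.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Optional

from rdkit import Chem
from rdkit import RDLogger

# RDKit is chatty on invalid SMILES; parse failures are reported explicitly
# by the callers instead.
RDLogger.DisableLog("rdApp.error")


def mol_from_smiles(smiles: str) -> Optional[Chem.Mol]:
    """Parse SMILES, returning None on failure instead of raising."""
    return Chem.MolFromSmiles(smiles)


def canonical_smiles(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol)


def heavy_atom_count(mol: Chem.Mol) -> int:
    """Number of non-hydrogen, non-dummy atoms."""
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def attachment_atoms(mol: Chem.Mol) -> list[Chem.Atom]:
    return [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]


def n_attachment_points(mol: Chem.Mol) -> int:
    return len(attachment_atoms(mol))


def normalize_site_numbering(mol: Chem.Mol) -> Chem.Mol:
    """Renumber attachment-point map numbers 1..n by canonical atom rank.

    The ranking is computed with map numbers cleared, so the result does not
    depend on the incoming numbering: two structures identical up to a site
    permutation map to the same canonical SMILES. Idempotent. Molecules
    without attachment points are returned unchanged (as a copy).
    """
    mol = Chem.Mol(mol)
    dummies = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if not dummies:
        return mol
    probe = Chem.Mol(mol)
    for a in probe.GetAtoms():
        a.SetAtomMapNum(0)
    ranks = list(Chem.CanonicalRankAtoms(probe, breakTies=True))
    for site, idx in enumerate(sorted(dummies, key=lambda i: ranks[i]), start=1):
        mol.GetAtomWithIdx(idx).SetAtomMapNum(site)
    return mol


def canonical_form(mol: Chem.Mol) -> str:
    """Canonical SMILES with site numbering itself canonicalized first."""
    return canonical_smiles(normalize_site_numbering(mol))


def strip_attachment_map(mol: Chem.Mol) -> Chem.Mol:
    """Copy with all attachment-point map numbers cleared (substituent form)."""
    mol = Chem.Mol(mol)
    for a in mol.GetAtoms():
        if a.GetAtomicNum() == 0:
            a.SetAtomMapNum(0)
    return mol


def fragment_on_bonds(mol: Chem.Mol, bond_indices: list[int]) -> list[Chem.Mol]:
    """Cut the given acyclic bonds; return fragments with mapped dummies.

    The dummy atoms created for cut i (0-based) receive atom map number i+1
    on both sides, so fragments can be re-zipped with :func:`reassemble`.
    """
    labels = [(i + 1, i + 1) for i in range(len(bond_indices))]
    fragmented = Chem.FragmentOnBonds(
        mol, bond_indices, addDummies=True, dummyLabels=labels
    )
    pieces = []
    for piece in Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=True):
        piece = Chem.Mol(piece)
        for a in piece.GetAtoms():
            if a.GetAtomicNum() == 0:
                a.SetAtomMapNum(a.GetIsotope())
                a.SetIsotope(0)
        pieces.append(piece)
    return pieces


def reassemble(core: Chem.Mol, substituents: Iterable[Chem.Mol]) -> Chem.Mol:
    """Zip a core and its substituents back together on matching site maps."""
    combined = core
    for sub in substituents:
        combined = Chem.CombineMols(combined, sub)
    out = Chem.molzip(combined)
    Chem.SanitizeMol(out)
    return out


def replace_sites_with_h(
    mol: Chem.Mol, keep_sites: Iterable[int]
) -> Optional[Chem.Mol]:
    """Replace attachment points not in ``keep_sites`` by hydrogen.

    Returns None when a removed site is attached through a non-single bond
    (hydrogen cannot occupy it).
    """
    keep = set(keep_sites)
    rw = Chem.RWMol(mol)
    for a in rw.GetAtoms():
        if a.GetAtomicNum() == 0 and a.GetAtomMapNum() not in keep:
            bonds = a.GetBonds()
            if any(b.GetBondType() != Chem.BondType.SINGLE for b in bonds):
                return None
            a.SetAtomicNum(1)
            a.SetAtomMapNum(0)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.RemoveHs(out)


def site_subset_forms(mol: Chem.Mol) -> dict[frozenset[int], str]:
    """Canonical forms of a multi-site structure with every subset of sites kept.

    Keys are the kept-site subsets (the empty set gives the bare, fully
    hydrogenated molecule); values are canonical SMILES after renumbering the
    kept sites. Subsets that would put hydrogen on a non-single bond are
    skipped.
    """
    sites = sorted(a.GetAtomMapNum() for a in attachment_atoms(mol))
    out: dict[frozenset[int], str] = {}
    for r in range(len(sites) + 1):
        for subset in combinations(sites, r):
            variant = replace_sites_with_h(mol, subset)
            if variant is None:
                continue
            out[frozenset(subset)] = canonical_form(variant)
    return out
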