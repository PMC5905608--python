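"""Retrosynthetic bond perception and size-restricted fragmentation.

Bonds eligible for cutting are acyclic single (or, for the olefin class,
double) bonds matching one of eleven retrosynthetic environments, in the
spirit of RECAP-style fragmentation: compounds are cleaved only where a
plausible synthetic step would join building blocks, so the resulting
matched molecular pairs reflect chemistry a medicinal chemist could actually
perform. A bond matching several environments is assigned to the first
matching class in :data:`RULE_ORDER` (fixed precedence, for determinism).

A ``Fragmentation`` is a (core, substituents) decomposition: cutting k bonds
must leave exactly one connected piece bearing all k attachment points (the
core) and k single-attachment substituents, each of which passes the size
rules. Re-zipping the pieces reproduces the parent molecule exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from rdkit import Chem

from ._mol import (
    canonical_form,
    canonical_smiles,
    fragment_on_bonds,
    heavy_atom_count,
    n_attachment_points,
    reassemble,
    strip_attachment_map,
)
from .chem_io import Compound
from .config import PipelineConfig

# rule_id -> two-atom SMARTS; the matched bond (atom0-atom1) is the cut bond.
# Recursive environments keep each pattern at exactly two atoms so the match
# tuple is the bond itself. Order defines precedence for overlapping matches.
RETROSYNTHETIC_RULES: dict[str, str] = {
    "amide": "[CX3;$([CX3]=[OX1]);!$([CX3](=[OX1])([#7])[#7])]!@[NX3]",
    "ester": "[OX2;$([OX2][CX3]=[OX1])]!@[#6;!$([CX3]=[OX1])]",
    "amine": (
        "[NX3;!$([NX3][CX3]=[O,N,S]);!$([NX3][SX4]);"
        "!$([NX3][#7,#8]);!$([NX3]=*)]!@[CX4]"
    ),
    "urea": "[CX3;$([CX3](=[OX1])([#7])[#7])]!@[NX3]",
    "ether": "[OX2;!$([OX2][CX3]=[OX1]);!$([OX2][#16,#15,#14])]!@"
    "[#6;!$([CX3]=[OX1])]",
    "olefin": "[CX3;$([CX3]=[CX3]);!$([CX3]=[O,N,S])]=!@[CX3;!$([CX3]=[O,N,S])]",
    "quaternary_n": "[NX4+]!@[#6]",
    "aromatic_n_aliphatic_c": "[n]!@[CX4]",
    "lactam_n_aliphatic_c": "[NX3;R;$([NX3][CX3]=[OX1])]!@[CX4]",
    "aromatic_c_aromatic_c": "[c]!@[c]",
    "sulfonamide": "[SX4;$([SX4](=[OX1])=[OX1])]!@[NX3]",
}

RULE_ORDER: tuple[str, ...] = tuple(RETROSYNTHETIC_RULES)

_COMPILED = {rid: Chem.MolFromSmarts(s) for rid, s in RETROSYNTHETIC_RULES.items()}


@dataclass(frozen=True)
class CutSite:
    """An acyclic bond eligible for retrosynthetic cutting."""

    atoms: tuple[int, int]  # sorted atom-index pair
    rule_id: str
    bond_idx: int


@dataclass
class Fragmentation:
    """A (core, substituents) decomposition of one compound.

    The core carries attachment points mapped 1..k; substituent i carries a
    single attachment point mapped i+1, so the decomposition re-zips
    unambiguously.
    """

    compound_id: str
    core: Chem.Mol
    substituents: list[Chem.Mol]
    cut_sites: list[CutSite]

    @property
    def k(self) -> int:
        return len(self.substituents)

    @property
    def core_form(self) -> str:
        """Site-normalized canonical SMILES of the core."""
        return canonical_form(self.core)

    @property
    def substituent_forms(self) -> list[str]:
        return [canonical_smiles(strip_attachment_map(s)) for s in self.substituents]

    @property
    def core_heavy(self) -> int:
        return heavy_atom_count(self.core)

    @property
    def substituent_heavy(self) -> list[int]:
        return [heavy_atom_count(s) for s in self.substituents]

    def reassembles(self, mol: Chem.Mol) -> bool:
        return canonical_smiles(reassemble(self.core, self.substituents)) == (
            canonical_smiles(mol)
        )


def find_retrosynthetic_bonds(
    compound: Compound | Chem.Mol, config: PipelineConfig | None = None
) -> list[CutSite]:
    """All acyclic bonds matching an enabled retrosynthetic rule.

    Each bond is assigned exactly one rule (first match in precedence order);
    the list is ordered by atom indices for determinism.
    """
    config = config or PipelineConfig()
    mol = compound.structure if isinstance(compound, Compound) else compound
    assigned: dict[int, CutSite] = {}
    for rule_id in RULE_ORDER:
        if rule_id in config.disabled_rules:
            continue
        for match in mol.GetSubstructMatches(_COMPILED[rule_id]):
            a0, a1 = match[0], match[1]
            bond = mol.GetBondBetweenAtoms(a0, a1)
            if bond is None or bond.IsInRing():
                continue
            if bond.GetIdx() not in assigned:
                assigned[bond.GetIdx()] = CutSite(
                    atoms=tuple(sorted((a0, a1))),
                    rule_id=rule_id,
                    bond_idx=bond.GetIdx(),
                )
    return sorted(assigned.values(), key=lambda s: s.atoms)


def passes_size_rules(
    core_heavy: int, substituent_heavy: int, config: PipelineConfig
) -> bool:
    """Substituent small enough in absolute terms and relative to the core."""
    return (
        substituent_heavy <= config.max_substituent_heavy_atoms
        and core_heavy >= config.core_to_substituent_min_ratio * substituent_heavy
    )


def enumerate_single_cut(
    compound: Compound, config: PipelineConfig | None = None
) -> list[Fragmentation]:
    """All size-rule-passing one-cut decompositions, both role assignments."""
    config = config or PipelineConfig()
    mol = compound.structure
    out: list[Fragmentation] = []
    for site in find_retrosynthetic_bonds(mol, config):
        pieces = fragment_on_bonds(mol, [site.bond_idx])
        if len(pieces) != 2:
            continue
        for core, sub in (pieces, pieces[::-1]):
            if passes_size_rules(
                heavy_atom_count(core), heavy_atom_count(sub), config
            ):
                out.append(
                    Fragmentation(
                        compound_id=compound.compound_id,
                        core=core,
                        substituents=[sub],
                        cut_sites=[site],
                    )
                )
    return out


def enumerate_multi_cut(
    compound: Compound, k: int, config: PipelineConfig | None = None
) -> list[Fragmentation]:
    """All size-rule-passing k-cut decompositions with a connected core.

    A cut-site subset qualifies only when exactly one resulting piece bears
    all k attachment points (that piece is the core) and every other piece
    bears exactly one (the substituents), each passing the size rules.
    """
    config = config or PipelineConfig()
    if k < 2:
        raise ValueError("enumerate_multi_cut requires k >= 2")
    mol = compound.structure
    sites = find_retrosynthetic_bonds(mol, config)
    if len(sites) < k:
        return []
    out: list[Fragmentation] = []
    for combo in combinations(sites, k):
        pieces = fragment_on_bonds(mol, [s.bond_idx for s in combo])
        counts = [n_attachment_points(p) for p in pieces]
        if sorted(counts) != [1] * k + [k]:
            continue
        core = pieces[counts.index(k)]
        subs = [p for p, c in zip(pieces, counts) if c == 1]
        core_heavy = heavy_atom_count(core)
        if all(
            passes_size_rules(core_heavy, heavy_atom_count(s), config) for s in subs
        ):
            # order substituents by their site map for a stable record
            subs = sorted(
                subs,
                key=lambda s: next(
                    a.GetAtomMapNum() for a in s.GetAtoms() if a.GetAtomicNum() == 0
                ),
            )
            out.append(
                Fragmentation(
                    compound_id=compound.compound_id,
                    core=core,
                    substituents=subs,
                    cut_sites=list(combo),
                )
            )
    return out


def enumerate_fragmentations(
    compound: Compound, config: PipelineConfig | None = None
) -> list[Fragmentation]:
    """Single- and multi-cut decompositions up to the site limit."""
    config = config or PipelineConfig()
    out = enumerate_single_cut(compound, config)
    for k in range(2, config.max_substitution_sites + 1):
        out.extend(enumerate_multi_cut(compound, k, config))
    return out
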