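"""Combinatorial analog libraries with known ground-truth scaffolds.

The generator builds analog series by attaching sampled substituents at the
numbered sites of a template scaffold. Templates are chosen so that every
attachment bond falls into a retrosynthetic bond class (amide/sulfonamide at
an arylamine nitrogen), i.e. the libraries satisfy the fragmentation
method's own preconditions; substituent pools are acyl/sulfonyl fragments
small enough to pass the size rules against each template by construction.

Positive controls (1-3 sites) must be recovered exactly; decoys carry no
retrosynthetic bond and can never join a series; the ambiguous control
builds two sub-series with structurally different invariant parts bridged
into one connected RMMP component, which must fail derivation with
``ambiguous_sub_series``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from itertools import product
from typing import Optional

from rdkit import Chem

from ._mol import (
    canonical_form,
    heavy_atom_count,
    mol_from_smiles,
    normalize_site_numbering,
    reassemble,
)
from .chem_io import Compound, CompoundSet
from .config import PipelineConfig
from .fragmentation import passes_size_rules

# Templates: attachment points are arylamine nitrogens; joining an acyl or
# sulfonyl pool fragment creates an amide or sulfonamide bond, which the
# fragmentation rules can cut back. Multi-site templates are deliberately
# asymmetric (sites in distinct symmetry classes), so distinct substituent
# combinations always yield distinct analogs and a substituent conserved at
# one site cannot migrate to an equivalent position.
TEMPLATES: dict[int, str] = {
    1: "[*:1]Nc1ccc2ccccc2c1",               # 2-aminonaphthalene, 11 heavy
    2: "[*:1]Nc1ccc2c(N[*:2])cccc2c1",       # naphthalene-2,5-diamine, 12 heavy
    3: "Cc1cc(N[*:2])cc(N[*:3])c1N[*:1]",    # 2-methylbenzene-1,3,5-triamine, 10
}

# Acyl/sulfonyl substituents, 2-5 heavy atoms each (attachment excluded);
# none contains an internal retrosynthetic bond, so the only cuttable bond
# of an attached substituent is the one joining it to the template.
SUBSTITUENT_VOCABULARY: tuple[str, ...] = (
    "[*:1]C=O",             # formyl, 2
    "[*:1]C(C)=O",          # acetyl, 3
    "[*:1]C(=O)CC",         # propanoyl, 4
    "[*:1]C(=O)CCC",        # butanoyl, 5
    "[*:1]C(=O)C(C)C",      # isobutyryl, 5
    "[*:1]C(=O)C1CC1",      # cyclopropanecarbonyl, 5
    "[*:1]C(=O)CF",         # fluoroacetyl, 4
    "[*:1]C(=O)CCl",        # chloroacetyl, 4
    "[*:1]C(=O)C(F)F",      # difluoroacetyl, 5
    "[*:1]C(=O)CBr",        # bromoacetyl, 4
    "[*:1]S(C)(=O)=O",      # methanesulfonyl, 4
    "[*:1]S(CC)(=O)=O",     # ethanesulfonyl, 5
)

# Molecules with no retrosynthetic bond at all: they yield no fragmentation,
# hence no RMMP, hence never join a series.
DECOY_VOCABULARY: tuple[str, ...] = (
    "Cc1ccccc1",
    "CCCCCCC",
    "CC1CCCCC1",
    "CC(C)CC(C)C",
    "c1ccc2ccccc2c1",
    "CC(C)c1ccccc1",
    "CCCCCC(C)C",
    "C1CCC2CCCCC2C1",
)


@dataclass
class LibrarySpec:
    """Recipe for one combinatorial analog library."""

    n_sites: int
    analogs_per_library: int
    decoy_count: int = 0
    seed: int = 0
    substituent_pools: Optional[list[list[str]]] = None
    template: Optional[str] = None

    def __post_init__(self) -> None:
        if self.template is None:
            if self.n_sites not in TEMPLATES:
                raise ValueError(f"no built-in template with {self.n_sites} sites")
            self.template = TEMPLATES[self.n_sites]
        if self.substituent_pools is None:
            template_mol = mol_from_smiles(self.template)
            core_heavy = heavy_atom_count(template_mol)
            config = PipelineConfig()
            pool = [
                s
                for s in SUBSTITUENT_VOCABULARY
                if passes_size_rules(
                    core_heavy, heavy_atom_count(mol_from_smiles(s)), config
                )
            ]
            self.substituent_pools = [list(pool) for _ in range(self.n_sites)]
        if len(self.substituent_pools) != self.n_sites:
            raise ValueError("one substituent pool required per site")
        # a connected matched-pair network on m analogs varies at most m-1
        # sites, so every site can only show >= 2 substituents when
        # m >= n_sites + 1
        if self.analogs_per_library < self.n_sites + 1:
            raise ValueError(
                f"a {self.n_sites}-site library needs at least "
                f"{self.n_sites + 1} analogs"
            )
        if not any(len(set(p)) >= 2 for p in self.substituent_pools):
            raise ValueError("at least one pool needs >= 2 distinct substituents")
        template_mol = mol_from_smiles(self.template)
        core_heavy = heavy_atom_count(template_mol)
        config = PipelineConfig()
        for pool in self.substituent_pools:
            for s in pool:
                sub_heavy = heavy_atom_count(mol_from_smiles(s))
                if not passes_size_rules(core_heavy, sub_heavy, config):
                    raise ValueError(f"pool substituent {s!r} violates size rules")


@dataclass
class GroundTruth:
    expected_scaffold: Optional[str]
    expected_n_sites: int
    expected_member_ids: frozenset[str]
    expected_outcome: str  # single_site | multi_site | failed
    expected_failure_reason: Optional[str] = None
    bridge_id: Optional[str] = None
    decoy_ids: frozenset[str] = frozenset()


def _attach(template: Chem.Mol, substituents: list[str]) -> Chem.Mol:
    subs = []
    for site, smi in enumerate(substituents, start=1):
        sub = Chem.Mol(mol_from_smiles(smi))
        for a in sub.GetAtoms():
            if a.GetAtomicNum() == 0:
                a.SetAtomMapNum(site)
        subs.append(sub)
    return reassemble(template, subs)


def generate_library(spec: LibrarySpec) -> tuple[CompoundSet, GroundTruth]:
    """Build a seeded analog library plus decoys, with its ground truth.

    Sampling guarantees at least two distinct substituents at *every* site
    across the emitted analogs (otherwise a constant site would merge into a
    larger conserved core and the template would not be the true scaffold).
    Multi-site libraries are expected to resolve at stage two; single-site
    libraries at stage one.
    """
    rng = random.Random(spec.seed)
    template = mol_from_smiles(spec.template)
    n_combos = 1
    for pool in spec.substituent_pools:
        n_combos *= len(set(pool))
    if n_combos < spec.analogs_per_library:
        raise ValueError(
            f"pools yield {n_combos} distinct analogs, "
            f"{spec.analogs_per_library} requested"
        )
    n = spec.analogs_per_library
    # Grow the sample by single-site mutations of already chosen analogs:
    # successive picks then differ at exactly one site, so the library is a
    # connected matched-pair network by construction (a prerequisite for it
    # to be one analog series). Retry until every site shows >= 2 distinct
    # substituents; a constant site would make a larger core the true
    # conserved structure and falsify the ground truth.
    chosen: list[tuple[str, ...]] = []
    for attempt in range(200):
        start = tuple(rng.choice(pool) for pool in spec.substituent_pools)
        chosen = [start]
        guard = 0
        while len(chosen) < n and guard < 10000:
            guard += 1
            base = list(rng.choice(chosen))
            site = rng.randrange(spec.n_sites)
            base[site] = rng.choice(spec.substituent_pools[site])
            candidate = tuple(base)
            if candidate not in chosen:
                chosen.append(candidate)
        if len(chosen) == n and (
            n == 1
            or all(
                len({combo[i] for combo in chosen}) >= 2
                for i in range(spec.n_sites)
            )
        ):
            break
    else:
        raise ValueError(
            "could not sample a connected library with >= 2 substituents "
            "per site; request more analogs or enlarge the pools"
        )

    compounds = CompoundSet(source_label=f"LIB{spec.seed}")
    member_ids = []
    for i, combo in enumerate(sorted(chosen), start=1):
        cid = f"LIB{spec.seed}-{i:03d}"
        mol = _attach(template, list(combo))
        compounds.add(Compound(compound_id=cid, structure=mol))
        member_ids.append(cid)
    if len(compounds) != len(chosen) + 0:
        raise ValueError(
            "template symmetry collapsed distinct substituent combinations "
            "into duplicate analogs; use an asymmetric template"
        )

    if spec.decoy_count > len(DECOY_VOCABULARY):
        raise ValueError(
            f"at most {len(DECOY_VOCABULARY)} distinct decoys available"
        )
    decoy_ids = []
    for i in range(spec.decoy_count):
        cid = f"DEC{spec.seed}-{i + 1:03d}"
        smi = DECOY_VOCABULARY[i % len(DECOY_VOCABULARY)]
        compounds.add(Compound(compound_id=cid, structure=mol_from_smiles(smi)))
        decoy_ids.append(cid)

    truth = GroundTruth(
        expected_scaffold=canonical_form(normalize_site_numbering(template)),
        expected_n_sites=spec.n_sites,
        expected_member_ids=frozenset(member_ids),
        expected_outcome="single_site" if spec.n_sites == 1 else "multi_site",
        decoy_ids=frozenset(decoy_ids),
    )
    return compounds, truth


# Ambiguous control: one connected RMMP component containing two sub-series
# whose conserved cores have different invariant parts. Sub-series A varies
# the acyl group of an N-(2-naphthyl)amide; sub-series B varies the O-alkyl
# group of alkoxyacetyl analogs whose acyl groups are too large to pair
# through the arylamine core. The methoxyacetyl compound bridges both.
_AMBIG_A = [
    ("AMB-A1", "CC(=O)Nc1ccc2ccccc2c1"),          # acetyl
    ("AMB-A2", "CCC(=O)Nc1ccc2ccccc2c1"),         # propanoyl
]
_AMBIG_BRIDGE = ("AMB-BR", "COCC(=O)Nc1ccc2ccccc2c1")  # methoxyacetyl
_AMBIG_B = [
    ("AMB-B1", "CCOCC(=O)Nc1ccc2ccccc2c1"),       # ethoxyacetyl
    ("AMB-B2", "CCCOCC(=O)Nc1ccc2ccccc2c1"),      # propoxyacetyl
]


def generate_ambiguous_series(
    seed: int = 0, include_bridge: bool = True
) -> tuple[CompoundSet, GroundTruth]:
    """Deterministic negative control for scaffold derivation.

    With the bridge, the five compounds form one connected series that fails
    with ``ambiguous_sub_series``; with the bridge removed, the two
    sub-series separate and each resolves single-site.
    """
    records = list(_AMBIG_A)
    if include_bridge:
        records.append(_AMBIG_BRIDGE)
    records.extend(_AMBIG_B)
    compounds = CompoundSet(source_label=f"AMB{seed}")
    for cid, smi in records:
        compounds.add(Compound(compound_id=cid, structure=mol_from_smiles(smi)))
    truth = GroundTruth(
        expected_scaffold=None,
        expected_n_sites=0,
        expected_member_ids=frozenset(cid for cid, _ in records),
        expected_outcome="failed" if include_bridge else "single_site",
        expected_failure_reason="ambiguous_sub_series" if include_bridge else None,
        bridge_id=_AMBIG_BRIDGE[0] if include_bridge else None,
    )
    return compounds, truth


def write_library(compounds: CompoundSet, path) -> None:
    """Fixture export as a smiles-table file (CLI round-trip tests)."""
    from .chem_io import write_compounds

    write_compounds(compounds, path)
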