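"""Reading, standardizing and writing compound and scaffold data.

Input dialects
--------------
``smiles-table``: tab-separated text, columns ``id``, ``smiles`` and the
optional ``targets`` and ``classes`` columns (semicolon-joined values);
lines starting with ``#`` are comments. ``sdf``: standard SD files with
annotations taken from the ``TARGETS`` and ``CLASSES`` tags.

Output: the ranked scaffold table, a TSV with columns
``rank, scaffold_smiles, n_sites, n_analogs, source, target_ids,
class_labels``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from ._mol import canonical_form, canonical_smiles, mol_from_smiles
from .config import PipelineConfig

logger = logging.getLogger(__name__)

SCAFFOLD_TABLE_COLUMNS = (
    "rank",
    "scaffold_smiles",
    "n_sites",
    "n_analogs",
    "source",
    "target_ids",
    "class_labels",
)

VALID_CLASS_LABELS = {"drug", "probe", "alert", "other"}


@dataclass
class Compound:
    """A standardized structure with optional target/class annotations."""

    compound_id: str
    structure: Chem.Mol
    source: str = "OTHER"
    target_ids: frozenset[str] = frozenset()
    class_labels: frozenset[str] = frozenset()

    @property
    def smiles(self) -> str:
        return canonical_smiles(self.structure)


@dataclass
class ParseReport:
    """Per-file account of records that failed to parse or were merged."""

    n_read: int = 0
    failed_ids: list[str] = field(default_factory=list)
    duplicate_ids: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_failed(self) -> int:
        return len(self.failed_ids)


class CompoundSet:
    """Ordered, structure-deduplicated collection of compounds.

    Structure-level duplicates keep the first-seen id; target and class
    annotations of later duplicates are merged into the kept record.
    """

    def __init__(self, source_label: str = "") -> None:
        self.source_label = source_label
        self._by_id: dict[str, Compound] = {}
        self._by_structure: dict[str, str] = {}  # canonical smiles -> id
        self.report = ParseReport()

    def add(self, compound: Compound) -> None:
        if compound.compound_id in self._by_id:
            raise ValueError(f"duplicate compound_id {compound.compound_id!r}")
        key = compound.smiles
        if key in self._by_structure:
            kept_id = self._by_structure[key]
            kept = self._by_id[kept_id]
            kept.target_ids = kept.target_ids | compound.target_ids
            kept.class_labels = kept.class_labels | compound.class_labels
            self.report.duplicate_ids.append((kept_id, compound.compound_id))
            logger.info(
                "duplicate structure: %s kept, %s merged",
                kept_id,
                compound.compound_id,
            )
            return
        self._by_structure[key] = compound.compound_id
        self._by_id[compound.compound_id] = compound

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Compound]:
        return iter(self._by_id.values())

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._by_id

    def __getitem__(self, compound_id: str) -> Compound:
        return self._by_id[compound_id]

    def ids(self) -> list[str]:
        return list(self._by_id)


_largest_fragment = rdMolStandardize.LargestFragmentChooser()
_uncharger = rdMolStandardize.Uncharger()


def standardize_structure(
    raw: Chem.Mol, config: PipelineConfig | None = None
) -> Optional[Chem.Mol]:
    """Largest covalent fragment, charge neutralization, fixed aromaticity.

    Stereo descriptors are removed when ``config.keep_stereo`` is false.
    Returns None when standardization leaves no atoms. Idempotent.
    """
    config = config or PipelineConfig()
    mol = _largest_fragment.choose(raw)
    if mol is None or mol.GetNumAtoms() == 0:
        return None
    mol = _uncharger.uncharge(mol)
    if not config.keep_stereo:
        mol = Chem.Mol(mol)
        Chem.RemoveStereochemistry(mol)
    Chem.SanitizeMol(mol)
    return mol


def _parse_annotations(value: str) -> frozenset[str]:
    return frozenset(v.strip() for v in value.split(";") if v.strip())


def _smiles_table_records(path: Path) -> Iterator[tuple[str, str, str, str]]:
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None and fields[0].lower() == "id":
                header = [f.lower() for f in fields]
                continue
            if header is None:
                header = ["id", "smiles", "targets", "classes"]
            row = dict(zip(header, fields))
            yield (
                row.get("id", ""),
                row.get("smiles", ""),
                row.get("targets", ""),
                row.get("classes", ""),
            )


def read_compounds(
    path: str | Path,
    format: str = "smiles-table",
    source_label: str = "OTHER",
    config: PipelineConfig | None = None,
) -> CompoundSet:
    """Read, standardize and deduplicate a compound collection.

    Unparsable records are skipped and listed in ``result.report.failed_ids``;
    an unreadable file raises. Record order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    config = config or PipelineConfig()
    out = CompoundSet(source_label=source_label)

    if format == "smiles-table":
        records = (
            (cid, mol_from_smiles(smi), targets, classes)
            for cid, smi, targets, classes in _smiles_table_records(path)
        )
    elif format == "sdf":
        def _sdf_records():
            supplier = Chem.SDMolSupplier(str(path), sanitize=True)
            for i, mol in enumerate(supplier):
                if mol is None:
                    yield (f"record_{i}", None, "", "")
                    continue
                cid = (
                    mol.GetProp("_Name")
                    if mol.HasProp("_Name") and mol.GetProp("_Name").strip()
                    else f"record_{i}"
                )
                targets = mol.GetProp("TARGETS") if mol.HasProp("TARGETS") else ""
                classes = mol.GetProp("CLASSES") if mol.HasProp("CLASSES") else ""
                yield (cid, mol, targets, classes)

        records = _sdf_records()
    else:
        raise ValueError(f"unknown format {format!r}")

    for cid, mol, targets, classes in records:
        out.report.n_read += 1
        if mol is None:
            out.report.failed_ids.append(cid)
            logger.warning("unparsable record %s skipped", cid)
            continue
        std = standardize_structure(mol, config)
        if std is None:
            out.report.failed_ids.append(cid)
            logger.warning("record %s empty after standardization", cid)
            continue
        out.add(
            Compound(
                compound_id=cid,
                structure=std,
                source=source_label,
                target_ids=_parse_annotations(targets),
                class_labels=_parse_annotations(classes) & VALID_CLASS_LABELS,
            )
        )
    return out


def write_compounds(compounds: CompoundSet, path: str | Path) -> None:
    """Write a CompoundSet back out as a smiles-table file."""
    with open(path, "w") as fh:
        fh.write("id\tsmiles\ttargets\tclasses\n")
        for c in compounds:
            fh.write(
                f"{c.compound_id}\t{c.smiles}\t"
                f"{';'.join(sorted(c.target_ids))}\t"
                f"{';'.join(sorted(c.class_labels))}\n"
            )


def write_scaffold_table(collection, path: str | Path) -> None:
    """Write the ranked scaffold table (TSV, schema in the module docstring)."""
    if not collection.ranked:
        raise ValueError("collection is not ranked; call rank_scaffolds first")
    with open(path, "w") as fh:
        fh.write("\t".join(SCAFFOLD_TABLE_COLUMNS) + "\n")
        for rank, scaffold in enumerate(collection.scaffolds, start=1):
            fh.write(
                "\t".join(
                    [
                        str(rank),
                        scaffold.smiles,
                        str(scaffold.n_sites),
                        str(scaffold.n_analogs),
                        scaffold.source,
                        ";".join(sorted(scaffold.target_ids)),
                        ";".join(sorted(scaffold.class_labels)),
                    ]
                )
                + "\n"
            )


def read_scaffold_table(path: str | Path):
    """Read a scaffold table written by :func:`write_scaffold_table`."""
    from .annotation_stats import ScaffoldCollection
    from .scaffold_derivation import ASBScaffold

    scaffolds = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != SCAFFOLD_TABLE_COLUMNS:
            raise ValueError(f"unexpected scaffold table header: {header}")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            row = dict(zip(SCAFFOLD_TABLE_COLUMNS, fields))
            mol = mol_from_smiles(row["scaffold_smiles"])
            if mol is None:
                raise ValueError(f"bad scaffold SMILES: {row['scaffold_smiles']}")
            scaffolds.append(
                ASBScaffold(
                    structure=mol,
                    n_sites=int(row["n_sites"]),
                    series_id=-1,
                    analog_ids=frozenset(),
                    source=row["source"],
                    target_ids=_parse_annotations(row["target_ids"]),
                    class_labels=_parse_annotations(row["class_labels"]),
                    n_analogs_override=int(row["n_analogs"]),
                )
            )
    sources = {s.source for s in scaffolds}
    collection = ScaffoldCollection(
        scaffolds=scaffolds, source_labels=sources, ranked=True
    )
    return collection


__all__ = [
    "Compound",
    "CompoundSet",
    "ParseReport",
    "read_compounds",
    "write_compounds",
    "standardize_structure",
    "canonical_form",
    "write_scaffold_table",
    "read_scaffold_table",
    "SCAFFOLD_TABLE_COLUMNS",
]
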