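"""Exhaustive RMMP generation by indexing single-cut cores.

Every size-rule-passing single-cut fragmentation of every compound is filed
under its canonical core string; two compounds filed under the same core
with different substituents form a retrosynthetic matched molecular pair
(RMMP), provided the exchanged substituents do not differ by more than the
configured number of heavy atoms. The exchange-size rule is applied at pair
level because the chemical modification only exists pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .chem_io import CompoundSet
from .config import PipelineConfig
from .fragmentation import enumerate_single_cut


@dataclass(frozen=True)
class RMMP:
    """A compound pair sharing a core and differing by one substituent swap.

    ``compound_a < compound_b`` under lexicographic id order, so each
    unordered pair is stored once.
    """

    compound_a: str
    compound_b: str
    core: str  # site-normalized canonical SMILES, one attachment point
    substituent_a: str
    substituent_b: str


@dataclass
class CoreIndex:
    """Canonical core string -> [(compound_id, substituent, heavy count)]."""

    entries: dict[str, list[tuple[str, str, int]]]

    @property
    def n_fragmentations(self) -> int:
        return sum(len(v) for v in self.entries.values())


def build_core_index(compounds: CompoundSet, config: PipelineConfig) -> CoreIndex:
    """Index every size-rule-passing single-cut fragmentation of the set."""
    entries: dict[str, list[tuple[str, str, int]]] = {}
    for compound in compounds:
        for frag in enumerate_single_cut(compound, config):
            entries.setdefault(frag.core_form, []).append(
                (
                    compound.compound_id,
                    frag.substituent_forms[0],
                    frag.substituent_heavy[0],
                )
            )
    return CoreIndex(entries=entries)


def generate_rmmps(index: CoreIndex, config: PipelineConfig) -> list[RMMP]:
    """All RMMPs implied by the index, deduplicated on (pair, core).

    One record per unordered compound pair per shared core with distinct
    substituents whose heavy-atom difference is within the exchange limit.
    Deterministic order: (compound_a, compound_b, core).
    """
    seen: dict[tuple[str, str, str], RMMP] = {}
    for core in sorted(index.entries):
        rows = index.entries[core]
        for i in range(len(rows)):
            cid_i, sub_i, heavy_i = rows[i]
            for j in range(i + 1, len(rows)):
                cid_j, sub_j, heavy_j = rows[j]
                if cid_i == cid_j or sub_i == sub_j:
                    continue
                if abs(heavy_i - heavy_j) > config.max_exchange_size_difference:
                    continue
                (a, sub_a), (b, sub_b) = sorted(
                    [(cid_i, sub_i), (cid_j, sub_j)], key=lambda t: t[0]
                )
                key = (a, b, core)
                if key not in seen:
                    seen[key] = RMMP(
                        compound_a=a,
                        compound_b=b,
                        core=core,
                        substituent_a=sub_a,
                        substituent_b=sub_b,
                    )
    return [seen[k] for k in sorted(seen)]


def write_rmmp_table(rmmps: list[RMMP], path: str | Path) -> None:
    """Inspection export: one row per RMMP."""
    with open(path, "w") as fh:
        fh.write("compound_a\tcompound_b\tcore_smiles\tsub_a\tsub_b\n")
        for r in rmmps:
            fh.write(
                f"{r.compound_a}\t{r.compound_b}\t{r.core}\t"
                f"{r.substituent_a}\t{r.substituent_b}\n"
            )
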