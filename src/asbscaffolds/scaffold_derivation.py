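"""Derivation of the unique analog-series-based (ASB) scaffold of a series.

Derivation is a two-stage process. Stage one looks for a single-site
scaffold: one single-cut core shared by every member of the series, thereby
capturing all pairwise RMMP relationships. Stage two, attempted only when
stage one fails, maps multiple substitution sites — represented by different
nonredundant single-cut cores — onto one multi-site scaffold. Candidate
multi-site scaffolds are generated exclusively from the members' own
multi-cut cores, never by abstract graph merging, so every emitted scaffold
is chemically realizable from the series.

A series yields one and only one scaffold, or a defined failure:

``no_common_core``
    no candidate core, at any site count within the limit, covers all
    members.
``ambiguous_sub_series``
    the members split into sub-series supported by structurally different
    maximal cores (distinct invariant parts) none of which covers the whole
    series.
``site_limit_exceeded``
    a covering core exists but needs more substitution sites than allowed.

A member "admits" a core when one of its size-rule-passing fragmentations
has that core, where (policy, switchable) hydrogen may occupy designated
sites the member does not use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from rdkit import Chem

from ._mol import (
    canonical_form,
    canonical_smiles,
    heavy_atom_count,
    mol_from_smiles,
    normalize_site_numbering,
    replace_sites_with_h,
    site_subset_forms,
)
from .chem_io import Compound, CompoundSet
from .config import PipelineConfig
from .fragmentation import (
    enumerate_multi_cut,
    enumerate_single_cut,
    find_retrosynthetic_bonds,
)
from .series_extraction import AnalogSeries

# bounded probe beyond the site limit, used only to distinguish
# site_limit_exceeded from the other failure reasons
_SITE_LIMIT_PROBE_EXTRA = 2
_PROBE_MAX_CUT_SITES = 14


@dataclass
class CoreRecord:
    """A candidate core with the series members that admit it."""

    core: Chem.Mol
    core_form: str
    covered_ids: frozenset[str]
    n_sites: int
    heavy: int
    invariant_form: str  # canonical form with attachment points hydrogenated

    @property
    def coverage(self) -> int:
        return len(self.covered_ids)


@dataclass
class ASBScaffold:
    """The unique scaffold of an analog series, with numbered sites R_1..R_n."""

    structure: Chem.Mol
    n_sites: int
    series_id: int
    analog_ids: frozenset[str]
    source: str = ""
    target_ids: frozenset[str] = frozenset()
    class_labels: frozenset[str] = frozenset()
    sources: frozenset[str] = frozenset()
    analogs_per_source: dict | None = None
    drug_exclusive: bool = False
    n_analogs_override: int | None = None

    @property
    def smiles(self) -> str:
        return canonical_form(self.structure)

    @property
    def n_analogs(self) -> int:
        if self.n_analogs_override is not None:
            return self.n_analogs_override
        return len(self.analog_ids)


@dataclass
class DerivationResult:
    outcome: str  # single_site | multi_site | failed
    series_id: int
    scaffold: Optional[ASBScaffold] = None
    failure_reason: Optional[str] = None

    def __post_init__(self) -> None:
        assert (self.outcome == "failed") == (self.scaffold is None)


def _invariant_form(core: Chem.Mol) -> str:
    """The core's structure with its attachment point(s) hydrogenated."""
    bare = replace_sites_with_h(core, ())
    if bare is None:  # attachment on a non-single bond: keep sites as-is
        return canonical_form(core)
    return canonical_smiles(bare)


class _SeriesContext:
    """Caches per-member fragmentations and core tables for one series."""

    def __init__(
        self, series: AnalogSeries, compounds: CompoundSet, config: PipelineConfig
    ) -> None:
        self.series = series
        self.config = config
        self.members = {cid: compounds[cid] for cid in series.member_ids}
        self.full_forms = {
            cid: canonical_smiles(c.structure) for cid, c in self.members.items()
        }
        self._core_tables: dict[int, dict[str, dict]] = {}

    def core_table(self, max_k: int) -> dict[str, dict]:
        """core_form -> {mol, n_sites, heavy, members: set of ids}."""
        if max_k not in self._core_tables:
            table: dict[str, dict] = {}
            for cid, compound in self.members.items():
                frags = list(enumerate_single_cut(compound, self.config))
                for k in range(2, max_k + 1):
                    frags.extend(enumerate_multi_cut(compound, k, self.config))
                for frag in frags:
                    form = frag.core_form
                    rec = table.get(form)
                    if rec is None:
                        rec = {
                            "mol": normalize_site_numbering(frag.core),
                            "n_sites": frag.k,
                            "heavy": frag.core_heavy,
                            "members": set(),
                        }
                        table[form] = rec
                    rec["members"].add(cid)
            self._core_tables[max_k] = table
        return self._core_tables[max_k]

    def coverage(self, core_mol: Chem.Mol, max_k: int) -> frozenset[str]:
        """Members admitting a fragmentation equal to the core, H-at-site aware."""
        table = self.core_table(max_k)
        variants = site_subset_forms(core_mol)
        n_sites = sum(1 for a in core_mol.GetAtoms() if a.GetAtomicNum() == 0)
        all_sites = frozenset(
            a.GetAtomMapNum() for a in core_mol.GetAtoms() if a.GetAtomicNum() == 0
        )
        covered: set[str] = set()
        for cid in self.members:
            member_cores = {
                form for form, rec in table.items() if cid in rec["members"]
            }
            for subset, form in variants.items():
                if not self.config.allow_hydrogen_site and subset != all_sites:
                    continue
                if len(subset) == 0:
                    if self.config.allow_hydrogen_site and (
                        self.full_forms[cid] == form
                    ):
                        covered.add(cid)
                        break
                elif form in member_cores:
                    covered.add(cid)
                    break
        return frozenset(covered)


def collect_candidate_cores(
    series: AnalogSeries,
    compounds: CompoundSet,
    config: PipelineConfig | None = None,
    _ctx: _SeriesContext | None = None,
) -> list[CoreRecord]:
    """All single-cut cores over the members, with coverage bookkeeping.

    Deduplicated on canonical core string; ordered by descending coverage,
    then descending heavy atoms, then canonical string.
    """
    config = config or PipelineConfig()
    ctx = _ctx or _SeriesContext(series, compounds, config)
    records = []
    for form, rec in ctx.core_table(1).items():
        covered = ctx.coverage(rec["mol"], 1)
        records.append(
            CoreRecord(
                core=rec["mol"],
                core_form=form,
                covered_ids=covered,
                n_sites=1,
                heavy=rec["heavy"],
                invariant_form=_invariant_form(rec["mol"]),
            )
        )
    records.sort(key=lambda r: (-r.coverage, -r.heavy, r.core_form))
    return records


def find_single_site_scaffold(
    series: AnalogSeries, cores: list[CoreRecord]
) -> Optional[ASBScaffold]:
    """The core shared by every member, if any (most heavy atoms wins ties)."""
    qualifying = [r for r in cores if r.covered_ids == series.member_ids]
    if not qualifying:
        return None
    best = min(qualifying, key=lambda r: (-r.heavy, r.core_form))
    return ASBScaffold(
        structure=best.core,
        n_sites=1,
        series_id=series.series_id,
        analog_ids=series.member_ids,
    )


def _nonredundant(cores: list[CoreRecord]) -> list[CoreRecord]:
    """Drop cores whose coverage is subsumed by a same-invariant-part core.

    A core is redundant when another core with an identical invariant part
    (structure after hydrogenating the attachment point) covers a superset
    of its members; such cores represent the same substitution site.
    """
    keep: list[CoreRecord] = []
    for r in cores:
        subsumed = any(
            o is not r
            and o.invariant_form == r.invariant_form
            and o.covered_ids >= r.covered_ids
            and (o.covered_ids > r.covered_ids or o.core_form < r.core_form)
            for o in cores
        )
        if not subsumed:
            keep.append(r)
    return keep


def find_multisite_scaffold(
    series: AnalogSeries,
    cores: list[CoreRecord],
    compounds: CompoundSet,
    config: PipelineConfig | None = None,
    _ctx: _SeriesContext | None = None,
) -> DerivationResult:
    """Stage two: map multiple substitution sites onto one scaffold.

    Candidates are the members' own multi-cut cores (2..max sites). The
    scaffold is the candidate covering every member, maximal by heavy atoms,
    then fewest sites, then canonical string. Failures are classified as
    documented in the module docstring.
    """
    config = config or PipelineConfig()
    ctx = _ctx or _SeriesContext(series, compounds, config)
    max_k = config.max_substitution_sites

    table = ctx.core_table(max_k)
    multi = [
        (form, rec) for form, rec in sorted(table.items()) if rec["n_sites"] >= 2
    ]
    full: list[CoreRecord] = []
    union_covered: set[str] = set()
    for form, rec in multi:
        covered = ctx.coverage(rec["mol"], max_k)
        union_covered |= covered
        if covered == series.member_ids:
            full.append(
                CoreRecord(
                    core=rec["mol"],
                    core_form=form,
                    covered_ids=covered,
                    n_sites=rec["n_sites"],
                    heavy=rec["heavy"],
                    invariant_form=_invariant_form(rec["mol"]),
                )
            )
    if full:
        best = min(full, key=lambda r: (-r.heavy, r.n_sites, r.core_form))
        return DerivationResult(
            outcome="multi_site",
            series_id=series.series_id,
            scaffold=ASBScaffold(
                structure=best.core,
                n_sites=best.n_sites,
                series_id=series.series_id,
                analog_ids=series.member_ids,
            ),
        )

    # failure analysis ------------------------------------------------------
    if _covering_core_beyond_limit(ctx, config):
        return DerivationResult(
            outcome="failed",
            series_id=series.series_id,
            failure_reason="site_limit_exceeded",
        )

    for r in cores:
        union_covered |= r.covered_ids
    maximal = [
        r
        for r in _nonredundant(cores)
        if not any(o.covered_ids > r.covered_ids for o in cores)
    ]
    invariant_parts = {r.invariant_form for r in maximal}
    if union_covered == set(series.member_ids) and len(invariant_parts) >= 2:
        reason = "ambiguous_sub_series"
    else:
        reason = "no_common_core"
    return DerivationResult(
        outcome="failed", series_id=series.series_id, failure_reason=reason
    )


def _covering_core_beyond_limit(
    ctx: _SeriesContext, config: PipelineConfig
) -> bool:
    """Bounded probe: would a few more sites produce a covering core?"""
    if any(
        len(find_retrosynthetic_bonds(c.structure, config)) > _PROBE_MAX_CUT_SITES
        for c in ctx.members.values()
    ):
        return False
    probe_max = config.max_substitution_sites + _SITE_LIMIT_PROBE_EXTRA
    seen: set[str] = set()
    for compound in ctx.members.values():
        for k in range(config.max_substitution_sites + 1, probe_max + 1):
            for frag in enumerate_multi_cut(compound, k, config):
                form = frag.core_form
                if form in seen:
                    continue
                seen.add(form)
                core = normalize_site_numbering(frag.core)
                if _probe_coverage(ctx, core, probe_max) == ctx.series.member_ids:
                    return True
    return False


def _probe_coverage(
    ctx: _SeriesContext, core_mol: Chem.Mol, probe_max: int
) -> frozenset[str]:
    """Coverage for an over-limit probe core (members may cut up to probe_max)."""
    table = ctx.core_table(probe_max)
    variants = site_subset_forms(core_mol)
    all_sites = frozenset(
        a.GetAtomMapNum() for a in core_mol.GetAtoms() if a.GetAtomicNum() == 0
    )
    covered = set()
    for cid in ctx.members:
        member_cores = {form for form, rec in table.items() if cid in rec["members"]}
        for subset, form in variants.items():
            if not ctx.config.allow_hydrogen_site and subset != all_sites:
                continue
            if len(subset) == 0:
                if ctx.config.allow_hydrogen_site and ctx.full_forms[cid] == form:
                    covered.add(cid)
                    break
            elif form in member_cores:
                covered.add(cid)
                break
    return frozenset(covered)


def derive_asb_scaffold(
    series: AnalogSeries,
    compounds: CompoundSet,
    config: PipelineConfig | None = None,
) -> DerivationResult:
    """Two-stage derivation: single-site first, multi-site on failure."""
    config = config or PipelineConfig()
    ctx = _SeriesContext(series, compounds, config)
    cores = collect_candidate_cores(series, compounds, config, _ctx=ctx)
    single = find_single_site_scaffold(series, cores)
    if single is not None:
        return DerivationResult(
            outcome="single_site", series_id=series.series_id, scaffold=single
        )
    return find_multisite_scaffold(series, cores, compounds, config, _ctx=ctx)


def scaffold_matches_compound(
    scaffold: ASBScaffold, compound: Compound, config: PipelineConfig | None = None
) -> bool:
    """Does the analog decompose as scaffold + substituents at designated sites?

    Hydrogen at a designated site is accepted when the policy allows it. Used
    by the substructure invariant checks.
    """
    config = config or PipelineConfig()
    variants = site_subset_forms(scaffold.structure)
    full_form = canonical_smiles(compound.structure)
    all_sites = frozenset(
        a.GetAtomMapNum()
        for a in scaffold.structure.GetAtoms()
        if a.GetAtomicNum() == 0
    )
    frags = list(enumerate_single_cut(compound, config))
    for k in range(2, config.max_substitution_sites + 1):
        frags.extend(enumerate_multi_cut(compound, k, config))
    member_cores = {f.core_form for f in frags}
    for subset, form in variants.items():
        if not config.allow_hydrogen_site and subset != all_sites:
            continue
        if len(subset) == 0:
            if config.allow_hydrogen_site and form == full_form:
                return True
        elif form in member_cores:
            return True
    return False


def write_failure_report(
    results: list[DerivationResult], series_sizes: dict[int, int], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("series_id\tfailure_reason\tn_members\n")
        for r in results:
            if r.outcome == "failed":
                fh.write(
                    f"{r.series_id}\t{r.failure_reason}\t"
                    f"{series_sizes.get(r.series_id, 0)}\n"
                )


__all__ = [
    "CoreRecord",
    "ASBScaffold",
    "DerivationResult",
    "collect_candidate_cores",
    "find_single_site_scaffold",
    "find_multisite_scaffold",
    "derive_asb_scaffold",
    "normalize_site_numbering",
    "scaffold_matches_compound",
    "write_failure_report",
]
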