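"""Scaffold annotation, cross-source merging, ranking and summary statistics.

Scaffolds inherit the union of their analogs' target and class annotations.
Collections from different sources are merged on the canonical scaffold
string (after site normalization): a scaffold present in both sources is
kept once, labelled ``both``, with annotations united and per-source analog
counts retained. Ranking is by descending analog count with canonical-string
tie-breaks, giving gap-free ranks 1..n.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from .chem_io import CompoundSet
from .scaffold_derivation import ASBScaffold, DerivationResult
from .series_extraction import AnalogSeries


@dataclass
class ScaffoldCollection:
    scaffolds: list[ASBScaffold] = field(default_factory=list)
    source_labels: set[str] = field(default_factory=set)
    ranked: bool = False

    def __len__(self) -> int:
        return len(self.scaffolds)

    def forms(self) -> set[str]:
        return {s.smiles for s in self.scaffolds}

    def table_records(self) -> list[tuple]:
        """The serialized view used by the scaffold table (round-trip key)."""
        return [
            (
                s.smiles,
                s.n_sites,
                s.n_analogs,
                s.source,
                tuple(sorted(s.target_ids)),
                tuple(sorted(s.class_labels)),
            )
            for s in self.scaffolds
        ]


@dataclass
class SummaryStats:
    """Collection-level statistics mirroring the deposition's summary table."""

    n_series: int = 0
    n_scaffolds: int = 0
    as_coverage_pct: float = 0.0
    pct_single_site: float = 0.0
    pct_multi_site: float = 0.0
    n_scaffolds_single_target: int = 0
    n_scaffolds_multi_target: int = 0
    pct_multi_target: float = 0.0
    n_unique_targets: int = 0
    per_source: dict = field(default_factory=dict)
    n_shared: int = 0
    n_drug_associated: int = 0
    n_drug_exclusive: int = 0
    n_alert_associated: int = 0
    n_failed_by_reason: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def round1(x: float) -> float:
    """Percentages reported to one decimal, half-up."""
    return float(Decimal(str(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def annotate_scaffold(scaffold: ASBScaffold, compounds: CompoundSet) -> ASBScaffold:
    """Fill target/class annotations from the analogs the scaffold represents.

    ``target_ids``/``class_labels`` are unions over members; the scaffold is
    drug-exclusive when every member carries the drug label.
    """
    targets: set[str] = set()
    classes: set[str] = set()
    all_drug = len(scaffold.analog_ids) > 0
    for cid in sorted(scaffold.analog_ids):
        if cid not in compounds:
            raise ValueError(f"scaffold references unknown analog id {cid!r}")
        member = compounds[cid]
        targets |= member.target_ids
        classes |= member.class_labels
        all_drug = all_drug and ("drug" in member.class_labels)
    scaffold.target_ids = frozenset(targets)
    scaffold.class_labels = frozenset(classes)
    scaffold.drug_exclusive = all_drug
    return scaffold


def collection_from_results(
    results: list[DerivationResult], source_label: str
) -> ScaffoldCollection:
    """Deduplicated single-source collection from derivation results.

    Two series of one source can yield the same canonical scaffold; such
    scaffolds are kept once with analog ids united.
    """
    by_form: dict[str, ASBScaffold] = {}
    for r in results:
        if r.scaffold is None:
            continue
        s = r.scaffold
        s.source = source_label
        s.sources = frozenset({source_label})
        form = s.smiles
        if form in by_form:
            kept = by_form[form]
            kept.analog_ids = kept.analog_ids | s.analog_ids
            kept.target_ids = kept.target_ids | s.target_ids
            kept.class_labels = kept.class_labels | s.class_labels
        else:
            s.analogs_per_source = {source_label: s.n_analogs}
            by_form[form] = s
    for s in by_form.values():
        s.analogs_per_source = {source_label: s.n_analogs}
    return ScaffoldCollection(
        scaffolds=[by_form[f] for f in sorted(by_form)],
        source_labels={source_label},
    )


def merge_collections(
    a: ScaffoldCollection, b: ScaffoldCollection
) -> ScaffoldCollection:
    """Union on canonical form; |result| = |a| + |b| - |shared|.

    Shared scaffolds keep both source labels (reported as ``both``), the
    union of annotations, and the analog count of each source separately;
    their ranked analog count is the maximum across sources.
    """
    by_form: dict[str, ASBScaffold] = {}
    for coll in (a, b):
        for s in coll.scaffolds:
            form = s.smiles
            if form not in by_form:
                merged = ASBScaffold(
                    structure=s.structure,
                    n_sites=s.n_sites,
                    series_id=s.series_id,
                    analog_ids=s.analog_ids,
                    source=s.source,
                    target_ids=s.target_ids,
                    class_labels=s.class_labels,
                    sources=s.sources or frozenset({s.source}),
                    analogs_per_source=dict(s.analogs_per_source or {}),
                    drug_exclusive=s.drug_exclusive,
                    n_analogs_override=s.n_analogs_override,
                )
                by_form[form] = merged
            else:
                kept = by_form[form]
                kept.sources = (kept.sources or frozenset()) | (
                    s.sources or frozenset({s.source})
                )
                kept.target_ids = kept.target_ids | s.target_ids
                kept.class_labels = kept.class_labels | s.class_labels
                kept.drug_exclusive = kept.drug_exclusive and s.drug_exclusive
                per = kept.analogs_per_source or {}
                for src, n in (s.analogs_per_source or {s.source: s.n_analogs}).items():
                    per[src] = max(per.get(src, 0), n)
                kept.analogs_per_source = per
                kept.source = "both" if len(kept.sources) > 1 else kept.source
                kept.n_analogs_override = max(per.values()) if per else None
    return ScaffoldCollection(
        scaffolds=[by_form[f] for f in sorted(by_form)],
        source_labels=a.source_labels | b.source_labels,
    )


def rank_scaffolds(collection: ScaffoldCollection) -> ScaffoldCollection:
    """Order by descending analog count, canonical string ascending on ties."""
    ordered = sorted(collection.scaffolds, key=lambda s: (-s.n_analogs, s.smiles))
    return ScaffoldCollection(
        scaffolds=ordered, source_labels=set(collection.source_labels), ranked=True
    )


def summarize_collection(
    series: list[AnalogSeries],
    results: list[DerivationResult],
    merged: ScaffoldCollection,
) -> SummaryStats:
    """All summary statistics; percentages reported to one decimal."""
    stats = SummaryStats()
    stats.n_series = len(series)
    stats.n_scaffolds = len(merged)
    n_derived = sum(1 for r in results if r.outcome != "failed")
    if stats.n_series:
        stats.as_coverage_pct = round1(100.0 * n_derived / stats.n_series)
    failed: dict[str, int] = {}
    for r in results:
        if r.outcome == "failed":
            failed[r.failure_reason] = failed.get(r.failure_reason, 0) + 1
    stats.n_failed_by_reason = failed

    if merged.scaffolds:
        n_single = sum(1 for s in merged.scaffolds if s.n_sites == 1)
        stats.pct_single_site = round1(100.0 * n_single / len(merged))
        stats.pct_multi_site = round1(100.0 * (len(merged) - n_single) / len(merged))

    annotated = [s for s in merged.scaffolds if s.target_ids]
    stats.n_scaffolds_single_target = sum(
        1 for s in annotated if len(s.target_ids) == 1
    )
    stats.n_scaffolds_multi_target = sum(1 for s in annotated if len(s.target_ids) >= 2)
    if annotated:
        stats.pct_multi_target = round1(
            100.0 * stats.n_scaffolds_multi_target / len(annotated)
        )
    all_targets: set[str] = set()
    for s in annotated:
        all_targets |= s.target_ids
    stats.n_unique_targets = len(all_targets)

    for src in sorted(merged.source_labels):
        stats.per_source[src] = sum(
            1
            for s in merged.scaffolds
            if src in (s.sources or frozenset({s.source}))
        )
    stats.n_shared = sum(
        1 for s in merged.scaffolds if len(s.sources or frozenset()) > 1
    )
    stats.n_drug_associated = sum(
        1 for s in merged.scaffolds if "drug" in s.class_labels
    )
    stats.n_drug_exclusive = sum(1 for s in merged.scaffolds if s.drug_exclusive)
    stats.n_alert_associated = sum(
        1 for s in merged.scaffolds if "alert" in s.class_labels
    )
    return stats
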