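"""Annotation, merging, ranking and summary statistics."""

import pytest
from hypothesis import given, settings, strategies as st

from asbscaffolds import (
    annotate_scaffold,
    generate_library,
    merge_collections,
    rank_scaffolds,
    summarize_collection,
    LibrarySpec,
    ScaffoldCollection,
)
from asbscaffolds.annotation_stats import collection_from_results, round1
from asbscaffolds.scaffold_derivation import ASBScaffold
from asbscaffolds._mol import mol_from_smiles, normalize_site_numbering
from conftest import make_set, run_pipeline

SCAFFOLD_SMILES = [
    "c1ccc2cc(N[*:1])ccc2c1",
    "[*:1]Nc1ccc2c(N[*:2])cccc2c1",
    "O=C(CO[*:1])Nc1ccc2ccccc2c1",
    "[*:1]Nc1ccccc1",
    "Cc1cc(N[*:1])cc(N[*:2])c1N[*:3]",
    "[*:1]Nc1ccc2cc(C)ccc2c1",
    "CC(C)c1ccc(N[*:1])cc1",
]


def _scaffold(smi, source="A", n_analogs=2, targets=(), classes=()):
    mol = normalize_site_numbering(mol_from_smiles(smi))
    return ASBScaffold(
        structure=mol,
        n_sites=sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0),
        series_id=0,
        analog_ids=frozenset(f"{source}-{smi}-{i}" for i in range(n_analogs)),
        source=source,
        sources=frozenset({source}),
        target_ids=frozenset(targets),
        class_labels=frozenset(classes),
        analogs_per_source={source: n_analogs},
    )


def _collection(smiles, source="A", **kw):
    return ScaffoldCollection(
        scaffolds=[_scaffold(s, source=source, **kw) for s in smiles],
        source_labels={source},
    )


class TestAnnotate:
    def test_union_of_member_annotations(self, cfg, naphthamide_set):
        naphthamide_set["NAP-1"].target_ids = frozenset({"P1"})
        naphthamide_set["NAP-2"].target_ids = frozenset({"P1", "P2"})
        _, results = run_pipeline(naphthamide_set, cfg)
        scaffold = annotate_scaffold(results[0].scaffold, naphthamide_set)
        assert scaffold.target_ids == {"P1", "P2"}

    def test_unannotated_members_allowed(self, cfg, naphthamide_set):
        _, results = run_pipeline(naphthamide_set, cfg)
        scaffold = annotate_scaffold(results[0].scaffold, naphthamide_set)
        assert scaffold.target_ids == frozenset()

    def test_drug_exclusive_requires_all_members(self, cfg, naphthamide_set):
        for cid in ("NAP-1", "NAP-2", "NAP-3"):
            naphthamide_set[cid].class_labels = frozenset({"drug"})
        _, results = run_pipeline(naphthamide_set, cfg)
        scaffold = annotate_scaffold(results[0].scaffold, naphthamide_set)
        assert scaffold.class_labels == {"drug"} and scaffold.drug_exclusive

        naphthamide_set["NAP-2"].class_labels = frozenset({"probe"})
        scaffold = annotate_scaffold(results[0].scaffold, naphthamide_set)
        assert scaffold.drug_exclusive is False

    def test_unknown_analog_id_fatal(self, cfg, naphthamide_set):
        _, results = run_pipeline(naphthamide_set, cfg)
        scaffold = results[0].scaffold
        scaffold.analog_ids = scaffold.analog_ids | {"GHOST"}
        with pytest.raises(ValueError, match="unknown analog"):
            annotate_scaffold(scaffold, naphthamide_set)


class TestMerge:
    def test_disjoint_union(self):
        merged = merge_collections(
            _collection(SCAFFOLD_SMILES[:3], "A"),
            _collection(SCAFFOLD_SMILES[3:5], "B"),
        )
        assert len(merged) == 5
        assert sum(1 for s in merged.scaffolds if s.source == "both") == 0

    def test_overlap_inclusion_exclusion(self):
        merged = merge_collections(
            _collection(SCAFFOLD_SMILES[:4], "A"),
            _collection(SCAFFOLD_SMILES[2:5], "B"),
        )
        assert len(merged) == 4 + 3 - 2
        shared = [s for s in merged.scaffolds if s.source == "both"]
        assert len(shared) == 2
        assert all(s.sources == {"A", "B"} for s in shared)

    def test_empty_identity(self):
        coll = _collection(SCAFFOLD_SMILES[:3], "A")
        merged = merge_collections(coll, ScaffoldCollection())
        assert merged.forms() == coll.forms()

    def test_shared_keeps_max_count_per_source(self):
        a = _collection(SCAFFOLD_SMILES[:1], "A", n_analogs=7)
        b = _collection(SCAFFOLD_SMILES[:1], "B", n_analogs=3)
        merged = merge_collections(a, b)
        s = merged.scaffolds[0]
        assert s.analogs_per_source == {"A": 7, "B": 3}
        assert s.n_analogs == 7

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        ia=st.sets(st.integers(0, len(SCAFFOLD_SMILES) - 1)),
        ib=st.sets(st.integers(0, len(SCAFFOLD_SMILES) - 1)),
    )
    def test_inclusion_exclusion_property(self, ia, ib):
        a = _collection([SCAFFOLD_SMILES[i] for i in sorted(ia)], "A")
        b = _collection([SCAFFOLD_SMILES[i] for i in sorted(ib)], "B")
        merged = merge_collections(a, b)
        assert len(merged) == len(ia) + len(ib) - len(ia & ib)


class TestRank:
    def test_tie_break_by_canonical_string(self):
        coll = ScaffoldCollection(
            scaffolds=[
                _scaffold(SCAFFOLD_SMILES[0], n_analogs=7),
                _scaffold(SCAFFOLD_SMILES[1], n_analogs=3),
                _scaffold(SCAFFOLD_SMILES[2], n_analogs=3),
                _scaffold(SCAFFOLD_SMILES[3], n_analogs=2),
            ],
            source_labels={"A"},
        )
        ranked = rank_scaffolds(coll)
        counts = [s.n_analogs for s in ranked.scaffolds]
        assert counts == [7, 3, 3, 2]
        tied = [s.smiles for s in ranked.scaffolds if s.n_analogs == 3]
        assert tied == sorted(tied)
        assert ranked.ranked

    def test_empty_and_idempotent(self):
        assert len(rank_scaffolds(ScaffoldCollection())) == 0
        coll = rank_scaffolds(_collection(SCAFFOLD_SMILES[:4]))
        again = rank_scaffolds(coll)
        assert [s.smiles for s in coll.scaffolds] == [
            s.smiles for s in again.scaffolds
        ]


class TestSummarize:
    def _mixed_run(self, cfg):
        compounds, _ = generate_library(
            LibrarySpec(n_sites=2, analogs_per_library=6, seed=51)
        )
        lib2, _ = generate_library(
            LibrarySpec(n_sites=1, analogs_per_library=4, seed=52)
        )
        for i, c in enumerate(lib2):
            c.target_ids = frozenset({"P1"} if i % 2 else {"P1", "P2"})
            compounds.add(c)
        extraction, results = run_pipeline(compounds, cfg)
        for r in results:
            if r.scaffold:
                annotate_scaffold(r.scaffold, compounds)
        merged = rank_scaffolds(collection_from_results(results, "TEST"))
        return extraction, results, merged

    def test_coverage_and_site_split(self, cfg):
        extraction, results, merged = self._mixed_run(cfg)
        stats = summarize_collection(extraction.series, results, merged)
        assert stats.n_series == 2 and stats.n_scaffolds == 2
        assert stats.as_coverage_pct == 100.0
        assert stats.pct_single_site + stats.pct_multi_site == pytest.approx(
            100.0, abs=0.1
        )
        assert stats.pct_single_site == 50.0

    def test_target_split_sums_to_annotated(self, cfg):
        extraction, results, merged = self._mixed_run(cfg)
        stats = summarize_collection(extraction.series, results, merged)
        annotated = sum(1 for s in merged.scaffolds if s.target_ids)
        assert (
            stats.n_scaffolds_single_target + stats.n_scaffolds_multi_target
            == annotated
        )
        assert stats.n_unique_targets == 2

    def test_coverage_arithmetic(self, cfg):
        # 10 series, 9 scaffolds -> 90.0% coverage, independent of structures
        from asbscaffolds.series_extraction import AnalogSeries
        from asbscaffolds.scaffold_derivation import DerivationResult

        series = [
            AnalogSeries(series_id=i, member_ids=frozenset({f"a{i}", f"b{i}"}))
            for i in range(1, 11)
        ]
        results = [
            DerivationResult(
                outcome="failed", series_id=1, failure_reason="no_common_core"
            )
        ] + [
            DerivationResult(
                outcome="single_site",
                series_id=i,
                scaffold=_scaffold(SCAFFOLD_SMILES[0]),
            )
            for i in range(2, 11)
        ]
        stats = summarize_collection(series, results, ScaffoldCollection())
        assert stats.as_coverage_pct == 90.0
        assert stats.n_failed_by_reason == {"no_common_core": 1}

    def test_rounding_half_up(self):
        assert round1(84.35) == 84.4
        assert round1(15.649) == 15.6
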