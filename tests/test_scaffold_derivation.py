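"""Single- and multi-site scaffold derivation, failure modes, invariants."""

import pytest

from asbscaffolds import (
    PipelineConfig,
    collect_candidate_cores,
    derive_asb_scaffold,
    find_single_site_scaffold,
    generate_ambiguous_series,
    generate_library,
    normalize_site_numbering,
    scaffold_matches_compound,
    LibrarySpec,
)
from asbscaffolds._mol import canonical_smiles, mol_from_smiles
from conftest import AMINONAPHTHALENE_CORE, run_pipeline


def _single_series(compounds, cfg):
    extraction, results = run_pipeline(compounds, cfg)
    assert len(extraction.series) == 1
    return extraction.series[0], results[0]


class TestSingleSite:
    def test_naphthamide_series_scaffold(self, cfg, naphthamide_set):
        series, result = _single_series(naphthamide_set, cfg)
        assert result.outcome == "single_site"
        scaffold = result.scaffold
        assert scaffold.smiles == AMINONAPHTHALENE_CORE
        assert scaffold.n_sites == 1
        assert scaffold.n_analogs == 3

    def test_candidate_cores_cover_and_order(self, cfg, naphthamide_set):
        series, _ = _single_series(naphthamide_set, cfg)
        cores = collect_candidate_cores(series, naphthamide_set, cfg)
        assert cores[0].covered_ids == series.member_ids
        coverages = [c.coverage for c in cores]
        assert coverages == sorted(coverages, reverse=True)

    def test_largest_core_wins_ties(self, cfg):
        # alkoxyacetyl naphthamides: both the 16-heavy core (cut at the
        # O-alkyl ether bond) and the 15-heavy core (cut at the other ether
        # bond) cover the whole series; the larger conserved structure wins
        from conftest import make_set

        cs = make_set(
            [
                ("E1", "CCOCC(=O)Nc1ccc2ccccc2c1"),
                ("E2", "CCCOCC(=O)Nc1ccc2ccccc2c1"),
            ]
        )
        series, result = _single_series(cs, cfg)
        assert result.outcome == "single_site"
        assert result.scaffold.smiles == "O=C(CO[*:1])Nc1ccc2ccccc2c1"

    def test_no_common_core_returns_none(self, cfg):
        compounds, _ = generate_ambiguous_series(0)
        extraction, _ = run_pipeline(compounds, cfg)
        series = extraction.series[0]
        cores = collect_candidate_cores(series, compounds, cfg)
        assert find_single_site_scaffold(series, cores) is None


class TestMultiSite:
    def test_two_site_combinatorial_library(self, cfg):
        compounds, truth = generate_library(
            LibrarySpec(n_sites=2, analogs_per_library=9, seed=13)
        )
        _, result = _single_series(compounds, cfg)
        assert result.outcome == "multi_site"
        assert result.scaffold.n_sites == 2
        assert result.scaffold.smiles == truth.expected_scaffold
        assert result.scaffold.n_analogs == 9

    def test_three_site_three_core_series(self, cfg):
        # a series whose three nonredundant cores map onto one three-site
        # scaffold
        compounds, truth = generate_library(
            LibrarySpec(n_sites=3, analogs_per_library=8, seed=21)
        )
        _, result = _single_series(compounds, cfg)
        assert result.outcome == "multi_site"
        assert result.scaffold.n_sites == 3
        assert result.scaffold.smiles == truth.expected_scaffold

    def test_single_site_precedence(self, cfg):
        compounds, truth = generate_library(
            LibrarySpec(n_sites=1, analogs_per_library=6, seed=17)
        )
        _, result = _single_series(compounds, cfg)
        assert result.outcome == "single_site"
        assert result.scaffold.smiles == truth.expected_scaffold

    def test_site_limit_exceeded(self):
        cfg = PipelineConfig(max_substitution_sites=2)
        compounds, _ = generate_library(
            LibrarySpec(n_sites=3, analogs_per_library=8, seed=21)
        )
        _, result = _single_series(compounds, cfg)
        assert result.outcome == "failed"
        assert result.failure_reason == "site_limit_exceeded"


class TestAmbiguity:
    def test_bridged_sub_series_fail(self, cfg):
        compounds, truth = generate_ambiguous_series(0)
        _, result = _single_series(compounds, cfg)
        assert result.outcome == "failed"
        assert result.failure_reason == "ambiguous_sub_series"

    def test_bridge_removed_both_resolve(self, cfg):
        compounds, _ = generate_ambiguous_series(0, include_bridge=False)
        extraction, results = run_pipeline(compounds, cfg)
        assert len(extraction.series) == 2
        assert all(r.outcome == "single_site" for r in results)


class TestSiteNumbering:
    SCAFFOLD = "[*:1]Nc1ccc2c(N[*:2])cccc2c1"

    def test_idempotent(self):
        mol = normalize_site_numbering(mol_from_smiles(self.SCAFFOLD))
        again = normalize_site_numbering(mol)
        assert canonical_smiles(mol) == canonical_smiles(again)

    def test_permutation_invariant(self):
        swapped = self.SCAFFOLD.replace("[*:1]", "[*:9]").replace(
            "[*:2]", "[*:1]"
        ).replace("[*:9]", "[*:2]")
        a = normalize_site_numbering(mol_from_smiles(self.SCAFFOLD))
        b = normalize_site_numbering(mol_from_smiles(swapped))
        assert canonical_smiles(a) == canonical_smiles(b)

    def test_single_site_unchanged(self):
        mol = normalize_site_numbering(mol_from_smiles("[*:1]Nc1ccccc1"))
        assert "[*:1]" in canonical_smiles(mol)


class TestInvariants:
    @pytest.mark.parametrize("seed", [31, 32, 33])
    def test_scaffold_matches_every_analog(self, seed, cfg):
        sites = 1 + seed % 3
        compounds, _ = generate_library(
            LibrarySpec(n_sites=sites, analogs_per_library=4 + seed % 5, seed=seed)
        )
        _, result = _single_series(compounds, cfg)
        assert result.scaffold is not None
        for cid in result.scaffold.analog_ids:
            assert scaffold_matches_compound(result.scaffold, compounds[cid], cfg)

    def test_at_most_one_scaffold_per_series(self, cfg):
        compounds, _ = generate_library(
            LibrarySpec(n_sites=2, analogs_per_library=6, decoy_count=2, seed=41)
        )
        for cid, smi in [
            ("ZAN-1", "O=CNc1ccccc1"),
            ("ZAN-2", "CC(=O)Nc1ccccc1"),
        ]:
            from conftest import make_compound

            compounds.add(make_compound(smi, cid))
        extraction, results = run_pipeline(compounds, cfg)
        assert len(results) == len(extraction.series)
        n_scaffolds = sum(1 for r in results if r.scaffold is not None)
        assert n_scaffolds <= len(extraction.series)
        for series, result in zip(extraction.series, results):
            assert result.series_id == series.series_id
            if result.scaffold is not None:
                assert result.scaffold.analog_ids == series.member_ids
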