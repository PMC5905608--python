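# asbscaffolds

Extraction of **analog-series-based (ASB) scaffolds** from compound
collections.

In medicinal chemistry, a *scaffold* names the core structure of a compound
or a series of compounds. Classical scaffold definitions are derived from
individual molecules (e.g. ring-system frameworks), which means one analog
series can splinter into several scaffolds, none of which reflects how the
series was actually made. The ASB approach instead derives **one scaffold
per analog series**: compounds are fragmented only at retrosynthetic
(RECAP-type) bonds, pairs of compounds that differ by a single
size-restricted substituent exchange form retrosynthetic matched molecular
pairs (RMMPs), connected components of the RMMP network define analog
series, and each series is reduced to the unique core — with one or several
numbered substitution sites R<sub>1</sub>..R<sub>n</sub> — that every
member of the series can be reassembled from. The resulting scaffolds carry
synthetic information, capture all conserved structure of a series, and can
be annotated with the targets and drug/probe classifications of the
compounds they represent.

## Method in brief

1. **Standardize** structures (largest fragment, charge neutralization,
   fixed aromaticity model) and deduplicate by canonical SMILES.
2. **Fragment** each compound at acyclic bonds matching one of eleven
   retrosynthetic environments (amide, ester, amine, urea, ether, olefin,
   quaternary N, aromatic N–aliphatic C, lactam N–aliphatic C, aromatic
   C–aromatic C, sulfonamide). A decomposition into core + substituent(s)
   is kept only if each substituent has ≤ 13 heavy atoms and the core has
   at least twice the substituent's heavy atoms.
3. **Pair**: index single-cut cores across the collection; two compounds
   filed under the same core with different substituents (heavy-atom
   difference ≤ 8) form an RMMP.
4. **Series**: connected components of the RMMP network with ≥ 2 members.
5. **Derive**: search all RMMP cores of a series for one shared by every
   member (single-site scaffold); if none exists, map the series' multiple
   substitution sites onto one multi-site scaffold built from the members'
   own multi-cut cores. Series whose sub-series cannot be mapped to one
   scaffold fail with a defined reason (`ambiguous_sub_series`,
   `no_common_core`, or `site_limit_exceeded`).
6. **Annotate, merge, rank**: scaffolds inherit the union of their analogs'
   target/class annotations, collections from several sources are merged on
   canonical form (shared scaffolds are labelled `both`), and the final
   table is ranked by the number of analogs each scaffold represents.

## Worked example

```python
from asbscaffolds import *

cfg = PipelineConfig()

# a seeded combinatorial analog library: 9 diamide analogs of an
# asymmetric naphthalenediamine template, plus 2 inert decoys
compounds, truth = generate_library(
    LibrarySpec(n_sites=2, analogs_per_library=9, decoy_count=2, seed=5)
)

index = build_core_index(compounds, cfg)
rmmps = generate_rmmps(index, cfg)
extraction = extract_analog_series(compounds, rmmps, cfg)
result = derive_asb_scaffold(extraction.series[0], compounds, cfg)

print(len(rmmps))                      # 16
print([s.size for s in extraction.series], extraction.n_singletons)  # [9] 2
print(result.outcome)                  # multi_site
print(result.scaffold.smiles)          # c1cc(N[*:2])c2ccc(N[*:1])cc2c1
print(result.scaffold.smiles == truth.expected_scaffold)  # True
```

The 9 analogs form a single series held together by 16 RMMPs; the two
decoys stay singletons. No single-cut core covers all 9 members (they vary
at two positions), so derivation proceeds to stage two and recovers the
generating two-site template exactly: the scaffold SMILES carries the two
numbered attachment points, and `n_analogs` reports the 9 compounds it
represents.

The same pipeline is available from the shell:

```sh
asb fixtures --sites 2 --analogs 9 --decoys 2 --seed 5 --out lib.tsv
asb extract --input lib.tsv smiles MYLIB --out run/
cat run/scaffolds.tsv
# rank  scaffold_smiles                 n_sites  n_analogs  source  target_ids  class_labels
# 1     c1cc(N[*:2])c2ccc(N[*:1])cc2c1  2        9          MYLIB
```

`run/` also contains `stats.json` (coverage, site split, target and class
statistics), `failures.tsv` (series that yielded no scaffold, with the
reason) and `manifest.json` (input digests and stage counts).

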