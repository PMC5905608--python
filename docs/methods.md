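# Methods

## Model and procedure

The package organizes structure–activity data around *analog series* and
their *series-based scaffolds* rather than per-compound frameworks. The
underlying model of an analog series is a connected network of
retrosynthetic matched molecular pairs (RMMPs): two compounds belong to the
same series when they can be linked — directly or through intermediates —
by single-point substituent exchanges at bonds a chemist could plausibly
form. The scaffold of a series is the unique conserved structure from which
every member is obtained by attaching substituents at designated sites.

The procedure is two-staged. Stage one searches all single-cut cores of a
series for one that every member admits; if found, the scaffold has one
substitution site and, by construction, captures every pairwise RMMP
relationship of the series. Stage two runs only when stage one fails: the
series varies at more than one position, and candidate scaffolds are the
members' own multi-cut cores (2..`max_substitution_sites` simultaneous
cuts, connected core, every substituent passing the size rules). A
candidate covers a member when the member admits a fragmentation whose core
equals the candidate after site renumbering, with hydrogen permitted at
designated sites the member does not use. Because candidates are only
generated from actual fragmentations of series members, every emitted
scaffold is chemically realizable from the series — scaffolds are never
assembled by abstract graph merging.

### Assumptions

- Fragmentation only at the eleven retrosynthetic bond classes; molecules
  without such bonds cannot participate in series. The exact SMARTS
  environments are this package's operational definitions and each class
  can be disabled via `PipelineConfig.disabled_rules`.
- Substituent exchanges are size-restricted so that series reflect typical
  medicinal-chemistry analoging rather than gross structural changes.
- A series yields at most one scaffold; series that cannot be mapped to one
  scaffold are reported with a defined failure reason rather than forced.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_substituent_heavy_atoms` | 13 | absolute cap on a substituent's heavy atoms (attachment point excluded) |
| `core_to_substituent_min_ratio` | 2.0 | core must carry ≥ 2× the substituent's heavy atoms, so the conserved part dominates |
| `max_exchange_size_difference` | 8 | heavy-atom window for the two exchanged substituents of an RMMP; applied at pair level because the modification only exists pairwise |
| `max_substitution_sites` | 4 | cap on scaffold sites and simultaneous cuts |
| `min_series_size` | 2 | smallest RMMP component that counts as a series |
| `keep_stereo` | true | retain stereo descriptors through standardization |
| `allow_hydrogen_site` | true | an analog may leave a designated site unsubstituted |

The three size thresholds are pinned defaults chosen to express
"substitutions found in medicinal-chemistry analog series" while keeping
every number reproducible and configurable; they are deliberately
conservative (small substituents on dominant cores).

## Design choices where the design was open

- **Series = connected components.** Components are handed intact to
  scaffold derivation, which either resolves them or reports a failure.
  This places the multiple-sub-series failure mode at the derivation stage,
  where it can be diagnosed structurally, instead of attempting a finer
  series decomposition up front.
- **Nonredundant cores.** Two single-cut cores represent the same
  substitution site when their *invariant parts* (the core with its
  attachment point hydrogenated) are identical and one covers a superset of
  the other's members; the subsumed core is redundant. Cores with different
  invariant parts always represent genuinely different sites.
- **Failure classification.** After the multi-site search fails within the
  site limit, a bounded probe extends the search by two extra cuts: if a
  covering core exists only beyond `max_substitution_sites`, the series
  fails with `site_limit_exceeded`. Otherwise, if the maximal nonredundant
  cores show ≥ 2 distinct invariant parts and jointly cover the series, the
  members split into sub-series conserved around different structures:
  `ambiguous_sub_series`. Everything else is `no_common_core`.
- **Hydrogen at a site.** A multi-site scaffold must represent analogs that
  vary at different subsets of sites; an analog lacking a substituent at a
  designated site is therefore accepted, with hydrogen occupying the site.
  The policy is switchable (`allow_hydrogen_site`) because the opposite
  convention (every analog substituted everywhere) is also defensible.
- **Tie-breaks.** Among qualifying cores: most heavy atoms first (the
  scaffold should capture *all* conserved structure), then fewest sites,
  then canonical SMILES. All orderings in the pipeline are total, which
  gives byte-identical outputs across reruns.
- **Standardization** is the minimal conventional chain — largest covalent
  fragment, charge neutralization, one fixed aromaticity model — applied
  identically to all sources, and is idempotent.
- **Shared scaffolds across sources** keep both source labels (written as
  `both`), the union of annotations, and the analog count of each source;
  the ranked count is the per-source maximum.

## Numerical and representation choices

- Attachment points are dummy atoms whose atom-map number is the site
  label. Site numbers are canonicalized by the canonical atom rank of the
  attachment position (computed with labels cleared), so two scaffolds
  identical up to site permutation have the same canonical SMILES.
  Heavy-atom counts exclude dummies and hydrogens.
- Fragment/reassembly round-trips use RDKit bond fragmentation and
  `molzip`; every emitted fragmentation is required to rebuild its parent's
  canonical SMILES exactly (asserted in tests).
- Reported percentages are rounded half-up to one decimal; full precision
  is kept internally.
- A bond matching several retrosynthetic environments is assigned to the
  first matching class in a fixed precedence order (the order the classes
  are declared in), purely for determinism of rule attribution.

## Synthetic benchmark libraries

The fixture generator emulates combinatorial analoging: a template scaffold
with 1–3 attachment sites on arylamine nitrogens receives acyl/sulfonyl
substituents (2–5 heavy atoms), so every template–substituent bond is an
amide or sulfonamide the fragmentation rules can cut back. Three properties
are enforced by construction, because each is a precondition for the
generated ground truth to be correct:

- **Asymmetric templates.** Multi-site templates have all sites in distinct
  molecular symmetry classes; otherwise distinct substituent assignments
  can collapse into identical molecules and a substituent can be "conserved"
  across equivalent positions.
- **Connected sampling.** Analogs are grown by single-site mutations of
  already chosen analogs, so the library forms one connected matched-pair
  network. (A connected network on *m* analogs can vary at most *m* − 1
  sites, hence an *n*-site library needs ≥ *n* + 1 analogs.)
- **Per-site diversity.** Every site shows ≥ 2 distinct substituents across
  the library; a constant site would make template + constant substituent
  the true conserved core.

Decoys are molecules with no retrosynthetic bond at all; they can never
fragment and therefore never join a series. The ambiguous negative control
is a fixed five-compound set: two acyl-varying naphthamides, two
alkoxy-varying alkoxyacetamides whose acyl groups are too large to pair
through the arylamine core, and a methoxyacetyl bridge compound that
belongs to both sub-series — one connected component whose two maximal
cores have different invariant parts and no common covering core.

What the generator does **not** emulate: the structural diversity,
activity-data curation, ring-system variety and annotation sparsity of real
repositories. Passing the recovery benchmarks shows the machinery is
correct on series that satisfy the method's preconditions exactly; it does
not predict coverage rates on real collections, where series chemistry is
heterogeneous and the failure modes occur at their natural frequencies.

## Problem sizes

The test suite and the acceptance script run on libraries of 3–12 analogs
(60 libraries in the recovery benchmark, 8 sets in the pair-generation
cross-check, a 10-library two-source merge benchmark). These sizes fully
exercise every code path — both derivation stages, all three failure
reasons, merging, ranking and the CLI — while keeping the whole suite in
the tens of seconds.

## Known limitations

- Component-level series definition: a finer decomposition of mixed
  components into unique sub-series before derivation is not attempted;
  such components end as `ambiguous_sub_series` failures.
- The `site_limit_exceeded` probe is bounded (two cuts beyond the limit,
  skipped for molecules with more than 14 cuttable bonds); pathological
  series beyond the probe report `no_common_core` instead.
- Tautomer canonicalization is not performed; two tautomeric analog forms
  are treated as distinct structures.
- Scaffold derivation assumes standardized, pre-curated input; no activity
  curation is applied.
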