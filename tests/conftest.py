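import pytest

from asbscaffolds import (
    Compound,
    CompoundSet,
    PipelineConfig,
    build_core_index,
    derive_asb_scaffold,
    extract_analog_series,
    generate_rmmps,
)
from asbscaffolds._mol import mol_from_smiles


@pytest.fixture
def cfg():
    return PipelineConfig()


def make_compound(smiles: str, cid: str, **kw) -> Compound:
    mol = mol_from_smiles(smiles)
    assert mol is not None, f"bad fixture SMILES {smiles!r}"
    return Compound(compound_id=cid, structure=mol, **kw)


def make_set(records, source="TEST") -> CompoundSet:
    cs = CompoundSet(source_label=source)
    for cid, smiles in records:
        cs.add(make_compound(smiles, cid))
    return cs


def run_pipeline(compounds: CompoundSet, config: PipelineConfig):
    """Convenience: index -> pairs -> series -> derivation results."""
    index = build_core_index(compounds, config)
    rmmps = generate_rmmps(index, config)
    extraction = extract_analog_series(compounds, rmmps, config)
    results = [derive_asb_scaffold(s, compounds, config) for s in extraction.series]
    return extraction, results


# A hand-built three-member analog series: N-(2-naphthyl) amides differing
# only in the acyl group. The conserved core is the 2-aminonaphthalene
# fragment with one attachment point.
NAPHTHAMIDES = [
    ("NAP-1", "CC(=O)Nc1ccc2ccccc2c1"),       # acetamide
    ("NAP-2", "CCC(=O)Nc1ccc2ccccc2c1"),      # propanamide
    ("NAP-3", "CCCC(=O)Nc1ccc2ccccc2c1"),     # butanamide
]
AMINONAPHTHALENE_CORE = "c1ccc2cc(N[*:1])ccc2c1"


@pytest.fixture
def naphthamide_set():
    return make_set(NAPHTHAMIDES)
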