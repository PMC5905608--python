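"""Analog series as connected components of the RMMP network.

Compounds are nodes; each RMMP contributes an edge. Connected components
with at least ``min_series_size`` members are analog series; compounds
participating in no RMMP are singletons and are counted, not dropped
silently. Components that mix sub-series are handed intact to scaffold
derivation, which resolves or rejects them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .chem_io import CompoundSet
from .config import PipelineConfig
from .mmp_index import RMMP


@dataclass
class AnalogSeries:
    series_id: int
    member_ids: frozenset[str]
    rmmp_edges: list[RMMP] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class SeriesExtraction:
    series: list[AnalogSeries]
    singleton_ids: list[str]

    @property
    def n_singletons(self) -> int:
        return len(self.singleton_ids)


def extract_analog_series(
    compounds: CompoundSet,
    rmmps: list[RMMP],
    config: PipelineConfig | None = None,
) -> SeriesExtraction:
    """Partition the compound set into analog series and singletons.

    Series ids are assigned 1..n by descending size, ties broken by the
    smallest member id, so the numbering does not depend on input order.
    An RMMP naming an unknown compound id is a consistency error.
    """
    config = config or PipelineConfig()
    known = set(compounds.ids())
    graph = nx.Graph()
    graph.add_nodes_from(known)
    for r in rmmps:
        if r.compound_a not in known or r.compound_b not in known:
            raise ValueError(
                f"RMMP references unknown compound: {r.compound_a}/{r.compound_b}"
            )
        graph.add_edge(r.compound_a, r.compound_b)

    components = [set(c) for c in nx.connected_components(graph)]
    qualifying = [c for c in components if len(c) >= config.min_series_size]
    qualifying.sort(key=lambda c: (-len(c), min(c)))

    series = []
    for sid, members in enumerate(qualifying, start=1):
        edges = [
            r for r in rmmps if r.compound_a in members and r.compound_b in members
        ]
        series.append(
            AnalogSeries(series_id=sid, member_ids=frozenset(members), rmmp_edges=edges)
        )
    in_series = set().union(*(s.member_ids for s in series)) if series else set()
    singletons = sorted(known - in_series)
    return SeriesExtraction(series=series, singleton_ids=singletons)


def write_series_table(extraction: SeriesExtraction, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("series_id\tcompound_id\n")
        for s in extraction.series:
            for cid in sorted(s.member_ids):
                fh.write(f"{s.series_id}\t{cid}\n")
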