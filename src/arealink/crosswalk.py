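"""Build the mapping table between two misaligned spatial ID systems.

The construction has four steps:

1. :func:`choose_direction` — the database whose units have the larger
   median surface area seeds the analysis ID system (aggregating toward the
   coarser side never requires disaggregation);
2. :func:`classify_components` — within each transition matrix, connected
   components of the bipartite link graph are labelled by their cardinality
   pattern (one-to-one, many-to-one, one-to-many, many-to-many);
3. :func:`compose` — the chain M_1..M_p is composed into a single
   ecological<->medical linkage graph (a fine ID and a coarse ID are linked
   iff a path through every matrix connects them);
4. :func:`merge_overlapping` — coarse (medical) units that share at least
   one fine (ecological) unit cannot be told apart at the fine scale, so
   they are merged — transitively — into a single analysis unit.

The result guarantees the method's central property: every linked
ecological ID maps to exactly ONE analysis ID, so variables can always be
aggregated upward and disaggregation is never needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .core import ConfigError, DataError, GeometryTable, TransitionMatrix

__all__ = [
    "SITUATIONS",
    "EquivalenceComponent",
    "LinkageGraph",
    "MappingTable",
    "choose_direction",
    "classify_components",
    "compose",
    "merge_overlapping",
    "build_mapping_table",
]

SITUATIONS = ("one_to_one", "many_to_one", "one_to_many", "many_to_many")


@dataclass(frozen=True)
class EquivalenceComponent:
    """One connected component of a transition matrix's bipartite graph."""

    matrix_index: int
    sources: frozenset[str]
    targets: frozenset[str]
    links: frozenset[tuple[str, str]]

    @property
    def situation(self) -> str:
        ns, nt = len(self.sources), len(self.targets)
        if ns == 1 and nt == 1:
            return "one_to_one"
        if nt == 1:
            return "many_to_one"
        if ns == 1:
            return "one_to_many"
        return "many_to_many"


@dataclass
class LinkageGraph:
    """Bipartite ecological<->medical link set after composing the chain.

    ``paths`` retains one full ID path per link route (eco, temp..., med),
    used to emit the intermediate-ID columns of the mapping table.
    ``dangling`` lists, per matrix index, target IDs with no onward link in
    the next matrix (crosswalk gaps — excluded but reported, never silent).
    """

    links: frozenset[tuple[str, str]]
    paths: tuple[tuple[str, ...], ...] = ()
    dangling: dict[int, list[str]] = field(default_factory=dict)

    @property
    def eco_ids(self) -> frozenset[str]:
        return frozenset(e for e, _ in self.links)

    @property
    def medical_ids(self) -> frozenset[str]:
        return frozenset(m for _, m in self.links)


@dataclass
class MappingTable:
    """The final eco -> ... -> medical -> analysis correspondence.

    ``rows`` has one row per full ID path, with columns
    ``eco_id, temp_id_2..p, medical_id, analysis_id, situation``.
    ``analysis_units`` maps each analysis ID to its member medical IDs;
    multi-member units are the product of overlap merges.
    """

    rows: pd.DataFrame
    analysis_units: dict[str, frozenset[str]]
    eco_to_analysis: dict[str, str]
    medical_to_analysis: dict[str, str]

    @property
    def n_analysis_units(self) -> int:
        return len(self.analysis_units)

    def partition(self) -> set[frozenset[str]]:
        """The analysis partition of the medical IDs (name-free)."""
        return set(self.analysis_units.values())

    def members_of(self, analysis_id: str, side: str = "eco") -> frozenset[str]:
        if side == "medical":
            return self.analysis_units[analysis_id]
        return frozenset(
            e for e, a in self.eco_to_analysis.items() if a == analysis_id
        )

    def write_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, encoding="utf-8")


def choose_direction(
    areas_med: GeometryTable | Iterable[float],
    areas_eco: GeometryTable | Iterable[float],
) -> str:
    """Return ``"medical"`` or ``"eco"``: whichever database has the larger
    median unit surface area seeds the analysis units.

    A tie is ambiguous and must be resolved explicitly in configuration.
    """
    med = _median_area(areas_med, "medical")
    eco = _median_area(areas_eco, "eco")
    if med > eco:
        return "medical"
    if eco > med:
        return "eco"
    raise ConfigError(
        "ambiguous direction (equal median areas); specify base explicitly in config"
    )


def _median_area(obj, label: str) -> float:
    if isinstance(obj, GeometryTable):
        return obj.median_area_km2()
    areas = pd.Series(list(obj), dtype=float)
    if areas.empty:
        raise DataError(f"no {label} areas supplied")
    return float(areas.median())


def classify_components(matrix: TransitionMatrix) -> list[EquivalenceComponent]:
    """Split a matrix into connected components of its bipartite link graph
    and label each by its cardinality pattern."""
    g = nx.Graph()
    for s, t in matrix.links:
        g.add_edge(("s", s), ("t", t))
    comps = []
    for nodes in nx.connected_components(g):
        sources = frozenset(n for side, n in nodes if side == "s")
        targets = frozenset(n for side, n in nodes if side == "t")
        links = frozenset(
            (s, t) for s, t in matrix.links if s in sources and t in targets
        )
        comps.append(
            EquivalenceComponent(
                matrix_index=matrix.index,
                sources=sources,
                targets=targets,
                links=links,
            )
        )
    # deterministic order for reports
    comps.sort(key=lambda c: min(c.sources))
    return comps


def compose(matrices: Sequence[TransitionMatrix]) -> LinkageGraph:
    """Compose a chain of transition matrices into an eco<->medical linkage.

    Consecutive matrices must chain (output level of M_k = input level of
    M_{k+1}).  IDs present as targets of M_k but absent from the sources of
    M_{k+1} are dangling: their paths are dropped from the linkage but the
    IDs are reported per matrix.
    """
    if not matrices:
        raise ConfigError("no transition matrices supplied")
    for a, b in zip(matrices, matrices[1:]):
        if a.target_level != b.source_level:
            raise ConfigError(
                f"chain break: M_{a.index} outputs level {a.target_level} but "
                f"M_{b.index} expects level {b.source_level}"
            )
    paths: list[tuple[str, ...]] = [(s, t) for s, t in sorted(matrices[0].links)]
    dangling: dict[int, list[str]] = {}
    for prev, nxt in zip(matrices, matrices[1:]):
        onward: dict[str, list[str]] = {}
        for s, t in nxt.links:
            onward.setdefault(s, []).append(t)
        new_paths: list[tuple[str, ...]] = []
        dropped: set[str] = set()
        for p in paths:
            tail = p[-1]
            if tail in onward:
                for t in sorted(onward[tail]):
                    new_paths.append(p + (t,))
            else:
                dropped.add(tail)
        if dropped:
            dangling[prev.index] = sorted(dropped)
        paths = new_paths
    links = frozenset((p[0], p[-1]) for p in paths)
    return LinkageGraph(links=links, paths=tuple(paths), dangling=dangling)


def _union_find_components(links: Iterable[tuple[str, str]]) -> dict[str, frozenset[str]]:
    """Group medical IDs into components of the 'share >= 1 eco ID' relation."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_eco: dict[str, list[str]] = {}
    for e, m in links:
        parent.setdefault(m, m)
        by_eco.setdefault(e, []).append(m)
    for meds in by_eco.values():
        for m in meds[1:]:
            union(meds[0], m)
    groups: dict[str, set[str]] = {}
    for m in parent:
        groups.setdefault(find(m), set()).add(m)
    return {r: frozenset(g) for r, g in groups.items()}


def merge_overlapping(graph: LinkageGraph) -> MappingTable:
    """Merge medical units sharing ecological units into analysis units.

    The relation "shares >= 1 eco ID" is transitively closed; each closure
    component becomes one analysis unit, named by its sorted member medical
    IDs joined with ``+`` (deterministic and traceable).  When no overlaps
    exist the analysis units coincide with the medical units.
    """
    if not graph.links:
        raise DataError("empty linkage graph")
    groups = _union_find_components(graph.links)
    med_to_analysis: dict[str, str] = {}
    analysis_units: dict[str, frozenset[str]] = {}
    for members in groups.values():
        aid = "+".join(sorted(members))
        analysis_units[aid] = members
        for m in members:
            med_to_analysis[m] = aid
    eco_to_analysis = {e: med_to_analysis[m] for e, m in graph.links}

    # situation per composed eco<->medical component (for the mapping CSV)
    comp_matrix = TransitionMatrix(index=0, links=graph.links)
    situation_of_link: dict[tuple[str, str], str] = {}
    for comp in classify_components(comp_matrix):
        for link in comp.links:
            situation_of_link[link] = comp.situation

    p = len(graph.paths[0]) - 2 if graph.paths else 0
    cols = ["eco_id"] + [f"temp_id_{j}" for j in range(2, p + 2)] + ["medical_id"]
    records = []
    paths = graph.paths or tuple((e, m) for e, m in sorted(graph.links))
    for path in paths:
        eco, med = path[0], path[-1]
        aid = med_to_analysis[med]
        situation = (
            "overlap_merge"
            if len(analysis_units[aid]) > 1
            else situation_of_link[(eco, med)]
        )
        records.append(list(path) + [aid, situation])
    rows = pd.DataFrame(records, columns=cols + ["analysis_id", "situation"])
    rows = rows.sort_values(list(rows.columns)).reset_index(drop=True)
    return MappingTable(
        rows=rows,
        analysis_units=analysis_units,
        eco_to_analysis=eco_to_analysis,
        medical_to_analysis=med_to_analysis,
    )


def build_mapping_table(
    matrices: Sequence[TransitionMatrix],
    base: str = "medical",
) -> tuple[MappingTable, dict]:
    """Run the full construction: classify, compose, merge.

    ``matrices`` chain from the ecological level (sources of the first) to
    the medical level (targets of the last).  With ``base="eco"`` the chain
    is reversed so that the ecological IDs seed the analysis units instead.

    Returns the mapping table and a census: per matrix, the number and
    percentage of links in each equivalence situation, plus a summary of
    the overlap merges performed after composition.
    """
    if base not in ("medical", "eco"):
        raise ConfigError(f"base must be 'medical' or 'eco', got {base!r}")
    chain = list(matrices)
    if base == "eco":
        chain = [m.reversed() for m in reversed(chain)]

    census: dict = {"matrices": {}, "overlap_merges": {}}
    for m in chain:
        counts = {s: 0 for s in SITUATIONS}
        comp_counts = {s: 0 for s in SITUATIONS}
        for comp in classify_components(m):
            counts[comp.situation] += len(comp.links)
            comp_counts[comp.situation] += 1
        total = sum(counts.values())
        census["matrices"][f"M_{m.index}"] = {
            s: {
                "links": counts[s],
                "pct_links": 100.0 * counts[s] / total,
                "components": comp_counts[s],
            }
            for s in SITUATIONS
        }

    graph = compose(chain)
    table = merge_overlapping(graph)
    merged_units = {a: ms for a, ms in table.analysis_units.items() if len(ms) > 1}
    census["overlap_merges"] = {
        "merged_medical_ids": sum(len(ms) for ms in merged_units.values()),
        "analysis_units_created": len(merged_units),
    }
    census["n_analysis_units"] = table.n_analysis_units
    census["n_medical_units"] = len(table.medical_to_analysis)
    census["n_eco_units"] = len(table.eco_to_analysis)
    if graph.dangling:
        census["dangling_ids"] = {f"M_{k}": v for k, v in graph.dangling.items()}
    return table, census
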