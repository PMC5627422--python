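"""Synthetic three-level geographies with known ground truth.

The generator emulates the structure of the French application — fine
ecological units (communes) linked to coarse medical units through
postal-like intermediate codes — on a square grid of unit cells (1 km
side), so that every quantity downstream modules compute has an exact,
planted answer:

* cells are partitioned into ``n_codes`` contiguous code regions by
  seeded region growing (edge adjacency), a fraction of which are frozen
  as single-cell codes to plant one-to-one links;
* codes are partitioned into ``n_medical`` contiguous medical units the
  same way;
* ``frac_split`` plants fine units spanning two codes of the SAME medical
  unit (the split reconverges downstream, so no merge is needed);
* ``overlap_rate`` plants fine units shared between codes of DIFFERENT
  medical units — the true overlap merges the crosswalk must recover;
* ``fragmentation_rate`` relocates, for the chosen fraction of medical
  units, one distant cell into the unit, making its dissolved geometry
  discontinuous while every donor stays contiguous;
* event counts per fine unit are Poisson(``lambda_count``); the medical
  database records each cell's events thinned binomially with probability
  ``1 - undercount``, emulating imperfect case capture.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.ops import unary_union

from .core import (
    AggregatedTable,
    ConfigError,
    DataError,
    GeometryTable,
    TransitionMatrix,
    VarMeta,
    write_aggregated_table,
    write_geometries,
    write_transition_matrix,
)

__all__ = ["GeographyParams", "GroundTruth", "Geography", "generate_geography",
           "generate_counts", "write_fixture"]


@dataclass(frozen=True)
class GeographyParams:
    """Knobs of the synthetic geography.

    Defaults give a 20x20 grid (400 fine units, each 1 km²), 40 codes and
    10 medical units, with special-case rates in the few-percent range and
    a 6% undercount of events in the medical database.
    """

    grid_n: int = 20
    n_codes: int = 40
    n_medical: int = 10
    frac_one_to_one: float = 0.10  # codes frozen as single-cell (one-to-one links)
    frac_split: float = 0.05       # fine units spanning two same-medical codes
    overlap_rate: float = 0.10     # fraction of medical units sharing a fine unit
    fragmentation_rate: float = 0.0
    lambda_count: float = 30.0     # mean events per fine unit
    undercount: float = 0.06       # expected fraction of events missing medically
    seed: int = 0

    def validate(self) -> None:
        if self.grid_n < 2:
            raise ConfigError("grid_n must be >= 2")
        F = self.grid_n ** 2
        if not (1 <= self.n_medical <= self.n_codes <= F):
            raise ConfigError(
                f"need 1 <= n_medical ({self.n_medical}) <= n_codes "
                f"({self.n_codes}) <= grid_n**2 ({F})"
            )
        for name in ("frac_one_to_one", "frac_split", "overlap_rate",
                     "fragmentation_rate", "undercount"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.lambda_count < 0:
            raise ConfigError("lambda_count must be non-negative")


@dataclass
class GroundTruth:
    """What the generator planted; the answers downstream modules recover."""

    analysis_partition: set[frozenset[str]]
    eco_to_group: dict[str, frozenset[str]]  # cell id -> its analysis member set
    planted_fragmented: frozenset[str]       # medical ids made discontinuous
    planted_overlap_cells: dict[str, tuple[str, str]]  # cell -> (medical A, B)
    counts: dict[str, int] = field(default_factory=dict)  # true events per cell

    @property
    def n_analysis_units(self) -> int:
        return len(self.analysis_partition)


@dataclass
class Geography:
    params: GeographyParams
    m1: TransitionMatrix          # fine cell -> code
    m2: TransitionMatrix          # code -> medical
    fine_geoms: GeometryTable
    medical_geoms: GeometryTable
    truth: GroundTruth
    cell_to_code: dict[str, str]  # primary assignment (geometry-bearing)
    code_to_medical: dict[str, str]


_NEIGH4 = ((0, 1), (0, -1), (1, 0), (-1, 0))


def _grow_regions(
    items: list,
    adjacency: dict,
    n_regions: int,
    rng: np.random.Generator,
    n_frozen: int = 0,
) -> dict:
    """Partition ``items`` into ``n_regions`` connected regions by seeded
    growth on ``adjacency``; the first ``n_frozen`` regions stay singletons
    unless nothing else can grow.  Smallest-region-first growth keeps the
    partition balanced."""
    seeds = list(rng.choice(len(items), size=n_regions, replace=False))
    assign = {items[s]: r for r, s in enumerate(seeds)}
    frozen = set(range(n_frozen))
    while len(assign) < len(items):
        # regions able to grow, smallest first
        sizes: dict[int, int] = {}
        for it, r in assign.items():
            sizes[r] = sizes.get(r, 0) + 1
        candidates: dict[int, list] = {}
        for it, r in assign.items():
            for nb in adjacency[it]:
                if nb not in assign:
                    candidates.setdefault(r, []).append(nb)
        growable = [r for r in candidates if r not in frozen]
        if not growable:          # frozen regions are the only way forward
            growable = list(candidates)
            if not growable:
                raise DataError("region growing stalled (disconnected item set)")
        min_size = min(sizes[r] for r in growable)
        pool = [r for r in growable if sizes[r] == min_size]
        r = pool[rng.integers(len(pool))]
        opts = candidates[r]
        assign[opts[rng.integers(len(opts))]] = r
    return assign


def _connected(cells: set[tuple[int, int]]) -> bool:
    if not cells:
        return False
    start = next(iter(cells))
    seen = {start}
    stack = [start]
    while stack:
        r, c = stack.pop()
        for dr, dc in _NEIGH4:
            nb = (r + dr, c + dc)
            if nb in cells and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(cells)


def _cell_id(idx: int) -> str:
    return f"e{idx:04d}"


def generate_geography(params: GeographyParams) -> Geography:
    """Build the planted geography; deterministic for a given seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.grid_n
    F = n * n
    positions = [(i // n, i % n) for i in range(F)]
    pos_of = {_cell_id(i): positions[i] for i in range(F)}
    cell_ids = list(pos_of)
    cell_at = {p: cid for cid, p in pos_of.items()}

    cell_adj = {
        cid: [
            cell_at[(r + dr, c + dc)]
            for dr, dc in _NEIGH4
            if (r + dr, c + dc) in cell_at
        ]
        for cid, (r, c) in pos_of.items()
    }

    # --- level 1 -> 2: cells into contiguous codes -------------------------
    n_frozen = int(round(params.frac_one_to_one * params.n_codes))
    cell_region = _grow_regions(cell_ids, cell_adj, params.n_codes, rng, n_frozen)
    code_of_region = {r: f"z{r:03d}" for r in range(params.n_codes)}
    cell_to_code = {cid: code_of_region[r] for cid, r in cell_region.items()}

    # --- level 2 -> 3: codes into contiguous medical units -----------------
    code_ids = sorted(set(cell_to_code.values()))
    code_adj: dict[str, set[str]] = {z: set() for z in code_ids}
    for cid, nbs in cell_adj.items():
        for nb in nbs:
            a, b = cell_to_code[cid], cell_to_code[nb]
            if a != b:
                code_adj[a].add(b)
                code_adj[b].add(a)
    code_adj_l = {z: sorted(s) for z, s in code_adj.items()}
    code_region = _grow_regions(code_ids, code_adj_l, params.n_medical, rng)
    code_to_medical = {z: f"m{r:02d}" for z, r in code_region.items()}
    medical_ids = sorted(set(code_to_medical.values()))

    def cells_of_medical(m: str) -> set[tuple[int, int]]:
        return {
            pos_of[cid] for cid, z in cell_to_code.items() if code_to_medical[z] == m
        }

    # --- plant fragmentation: relocate a distant cell into chosen units ----
    n_frag = int(round(params.fragmentation_rate * params.n_medical))
    planted_frag: set[str] = set()
    recipients = list(rng.permutation(medical_ids))
    for m in recipients:
        if len(planted_frag) >= n_frag:
            break
        target_cells = cells_of_medical(m)
        donors = []
        for cid in cell_ids:
            z = cell_to_code[cid]
            d = code_to_medical[z]
            if d == m or d in planted_frag or d in (m,):
                continue
            r0, c0 = pos_of[cid]
            # Chebyshev distance >= 2 from every target cell: no edge or
            # corner contact, so the relocated cell is a true fragment
            if any(max(abs(r0 - r), abs(c0 - c)) < 2 for r, c in target_cells):
                continue
            code_cells = {
                pos_of[c2] for c2, z2 in cell_to_code.items() if z2 == z
            }
            if len(code_cells) < 2:
                continue
            donor_cells = cells_of_medical(d)
            if not _connected(donor_cells - {pos_of[cid]}):
                continue
            if not _connected(code_cells - {pos_of[cid]}):
                continue
            donors.append(cid)
        if not donors:
            continue
        moved = donors[rng.integers(len(donors))]
        my_codes = sorted(z for z, mm in code_to_medical.items() if mm == m)
        cell_to_code[moved] = my_codes[rng.integers(len(my_codes))]
        planted_frag.add(m)
    if len(planted_frag) < n_frag:
        raise DataError(
            f"could only plant {len(planted_frag)} of {n_frag} fragmented units; "
            "relax fragmentation_rate or enlarge the grid"
        )

    # --- base M1 links + planted splits and overlaps ------------------------
    links1: set[tuple[str, str]] = {(cid, z) for cid, z in cell_to_code.items()}
    extra_links: dict[str, str] = {}

    def border_neighbour_codes(cid: str) -> list[str]:
        z = cell_to_code[cid]
        return sorted(
            {cell_to_code[nb] for nb in cell_adj[cid] if cell_to_code[nb] != z}
        )

    # splits: second link to a neighbouring code of the SAME medical unit
    n_split = int(round(params.frac_split * F))
    split_candidates = []
    for cid in cell_ids:
        z = cell_to_code[cid]
        for z2 in border_neighbour_codes(cid):
            if code_to_medical[z2] == code_to_medical[z]:
                split_candidates.append((cid, z2))
                break
    rng.shuffle(split_candidates)
    for cid, z2 in split_candidates[:n_split]:
        links1.add((cid, z2))
        extra_links[cid] = z2

    # overlaps: second link to a neighbouring code of ANOTHER medical unit
    n_overlap_units = int(round(params.overlap_rate * params.n_medical))
    involved: set[str] = set()
    planted_overlap_cells: dict[str, tuple[str, str]] = {}
    border_cells = []
    for cid in cell_ids:
        if cid in extra_links:
            continue
        z = cell_to_code[cid]
        for z2 in border_neighbour_codes(cid):
            if code_to_medical[z2] != code_to_medical[z]:
                border_cells.append((cid, z2))
                break
    rng.shuffle(border_cells)
    for cid, z2 in border_cells:
        if len(involved) >= n_overlap_units:
            break
        a, b = code_to_medical[cell_to_code[cid]], code_to_medical[z2]
        if a in involved and b in involved:
            continue
        links1.add((cid, z2))
        planted_overlap_cells[cid] = (a, b)
        involved |= {a, b}
    if n_overlap_units > 0 and len(involved) < min(n_overlap_units, 2):
        raise DataError("could not plant any overlap; geography too small")

    m1 = TransitionMatrix(index=1, links=frozenset(links1),
                          source_level=1, target_level=2)
    m2 = TransitionMatrix(
        index=2,
        links=frozenset((z, m) for z, m in code_to_medical.items()),
        source_level=2,
        target_level=3,
    )

    # --- ground truth -------------------------------------------------------
    parent = {m: m for m in medical_ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for cid, (a, b) in planted_overlap_cells.items():
        parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for m in medical_ids:
        groups.setdefault(find(m), set()).add(m)
    partition = {frozenset(g) for g in groups.values()}
    group_of = {m: frozenset(g) for g in groups.values() for m in g}
    eco_to_group = {
        cid: group_of[code_to_medical[cell_to_code[cid]]] for cid in cell_ids
    }

    # --- geometries (1 km unit cells) ---------------------------------------
    fine_geoms = GeometryTable(
        geoms={cid: box(c, r, c + 1, r + 1) for cid, (r, c) in pos_of.items()},
        coord_unit="km",
    )
    med_members: dict[str, list] = {m: [] for m in medical_ids}
    for cid, z in cell_to_code.items():
        med_members[code_to_medical[z]].append(fine_geoms.geoms[cid])
    medical_geoms = GeometryTable(
        geoms={m: unary_union(gs) for m, gs in med_members.items()},
        coord_unit="km",
    )

    truth = GroundTruth(
        analysis_partition=partition,
        eco_to_group=eco_to_group,
        planted_fragmented=frozenset(planted_frag),
        planted_overlap_cells=planted_overlap_cells,
    )
    return Geography(
        params=params,
        m1=m1,
        m2=m2,
        fine_geoms=fine_geoms,
        medical_geoms=medical_geoms,
        truth=truth,
        cell_to_code=dict(cell_to_code),
        code_to_medical=code_to_medical,
    )


def generate_counts(
    geography: Geography,
    params: GeographyParams | None = None,
) -> tuple[AggregatedTable, AggregatedTable]:
    """Paired count databases: exact fine-level counts (ecological side)
    and binomially thinned, medically attributed counts (medical side).

    Each cell's events are attributed to its primary medical unit, so with
    ``undercount = 0`` the two databases agree exactly at any aggregate
    scale.  Fills ``geography.truth.counts`` with the true per-cell counts.
    """
    p = params or geography.params
    rng = np.random.default_rng([p.seed, 1])
    cell_ids = sorted(geography.cell_to_code)
    true_counts = rng.poisson(p.lambda_count, size=len(cell_ids))
    thinned = rng.binomial(true_counts, 1.0 - p.undercount)

    geography.truth.counts = {
        cid: int(c) for cid, c in zip(cell_ids, true_counts)
    }
    eco = AggregatedTable(
        data=pd.DataFrame({"births": true_counts},
                          index=pd.Index(cell_ids, name="id")),
        var_meta={"births": VarMeta(kind="count", tag="births")},
        level="eco",
    )
    med_totals: dict[str, int] = {m: 0 for m in geography.code_to_medical.values()}
    for cid, c in zip(cell_ids, thinned):
        m = geography.code_to_medical[geography.cell_to_code[cid]]
        med_totals[m] += int(c)
    med = AggregatedTable(
        data=pd.DataFrame(
            {"births": pd.Series(med_totals, dtype=int)}
        ).rename_axis("id"),
        var_meta={"births": VarMeta(kind="count", tag="births")},
        level="medical",
    )
    return eco, med


def write_fixture(geography: Geography, outdir: str | Path) -> dict[str, Path]:
    """Write the full fixture set (matrices, counts, geometries, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eco, med = generate_counts(geography)
    paths = {
        "m1": outdir / "m1.csv",
        "m2": outdir / "m2.csv",
        "eco_counts": outdir / "eco_counts.csv",
        "med_counts": outdir / "med_counts.csv",
        "fine_geoms": outdir / "fine_geoms.geojson",
        "medical_geoms": outdir / "medical_geoms.geojson",
        "truth": outdir / "truth.json",
    }
    write_transition_matrix(geography.m1, paths["m1"])
    write_transition_matrix(geography.m2, paths["m2"])
    write_aggregated_table(eco, paths["eco_counts"])
    write_aggregated_table(med, paths["med_counts"])
    write_geometries(geography.fine_geoms, paths["fine_geoms"])
    write_geometries(geography.medical_geoms, paths["medical_geoms"])
    truth = geography.truth
    paths["truth"].write_text(
        json.dumps(
            {
                "analysis_partition": sorted(
                    sorted(g) for g in truth.analysis_partition
                ),
                "planted_fragmented": sorted(truth.planted_fragmented),
                "planted_overlap_cells": {
                    k: list(v) for k, v in sorted(truth.planted_overlap_cells.items())
                },
                "counts": truth.counts,
                "params": asdict(geography.params),
            },
            indent=1,
        ),
        encoding="utf-8",
    )
    return paths
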