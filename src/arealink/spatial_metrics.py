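"""Spatial validation of the analysis units.

Two quality indices are computed on the dissolved analysis-unit map:

* **fragmentation index** — the share of analysis units whose territory is
  discontinuous (more than one connected part).  Connectivity is judged by
  rook contiguity: two parts sharing only a corner point are separate
  fragments, because one cannot cross a zero-width junction without leaving
  the unit.  Fragmented units matter because their area centroid can fall
  outside the unit itself, mislocating aggregated data;
* **spatial-resolution decline index** — the ratio of the median unit size
  (surface area or population) of a candidate analysis scale to that of the
  finest unit in the initial databases.  Smaller is finer; the analysis
  scale is compared against familiar administrative reference units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from .core import ConfigError, DataError, GeometryTable
from .crosswalk import MappingTable

__all__ = [
    "SpatialReport",
    "dissolve",
    "n_parts",
    "fragmentation_index",
    "centroid_containment",
    "resolution_decline_index",
    "spatial_report",
]


@dataclass
class SpatialReport:
    n_units: int
    n_fragmented: int
    fragmentation_pct: float  # full precision; round only at display
    n_centroid_outside: int
    median_area_km2: float
    iqr_area_km2: tuple[float, float]
    decline_indices: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_units": self.n_units,
            "n_fragmented": self.n_fragmented,
            "fragmentation_pct": self.fragmentation_pct,
            "n_centroid_outside": self.n_centroid_outside,
            "median_area_km2": self.median_area_km2,
            "iqr_area_km2": list(self.iqr_area_km2),
            "decline_indices": self.decline_indices,
        }

    def summary(self) -> str:
        lines = [
            f"analysis units: {self.n_units}",
            f"fragmented: {self.n_fragmented} ({self.fragmentation_pct:.1f}%)",
            f"centroid outside unit: {self.n_centroid_outside}",
            f"median area: {self.median_area_km2:.1f} km² "
            f"[{self.iqr_area_km2[0]:.1f}; {self.iqr_area_km2[1]:.1f}]",
        ]
        for name, d in self.decline_indices.items():
            parts = ", ".join(f"{k}={v:.1f}" for k, v in d.items())
            lines.append(f"decline index vs {name}: {parts}")
        return "\n".join(lines)


def dissolve(geoms: GeometryTable, mapping: MappingTable) -> GeometryTable:
    """Union member geometries into one geometry per analysis unit.

    The geometry IDs may be at the ecological or the medical level; the
    matching mapping side is chosen by ID overlap.  Analysis units with no
    member geometry raise an error naming the unit.
    """
    ids = set(geoms.ids)
    eco_hits = len(ids & set(mapping.eco_to_analysis))
    med_hits = len(ids & set(mapping.medical_to_analysis))
    if eco_hits == 0 and med_hits == 0:
        raise DataError("no geometry id appears in the mapping table")
    id_to_analysis = (
        mapping.eco_to_analysis if eco_hits >= med_hits else mapping.medical_to_analysis
    )
    members: dict[str, list] = {aid: [] for aid in mapping.analysis_units}
    missing = []
    for uid, g in geoms.geoms.items():
        aid = id_to_analysis.get(uid)
        if aid is None:
            missing.append(uid)
            continue
        members[aid].append(g)
    out = {}
    for aid, gs in members.items():
        if not gs:
            raise DataError(f"no member geometries for analysis unit {aid!r}")
        out[aid] = unary_union(gs)
    return GeometryTable(geoms=out, coord_unit=geoms.coord_unit)


def n_parts(geom) -> int:
    """Number of connected parts of a (multi)polygon under rook contiguity.

    Polygon unions performed by shapely already split corner-touching parts
    into separate polygons of a MultiPolygon, so the part count is the
    polygon count (zero-area slivers ignored).
    """
    if isinstance(geom, Polygon):
        return 1
    if isinstance(geom, MultiPolygon):
        return sum(1 for p in geom.geoms if p.area > 0)
    polys = [g for g in getattr(geom, "geoms", []) if isinstance(g, (Polygon, MultiPolygon))]
    return sum(n_parts(g) for g in polys) if polys else 1


def fragmentation_index(geoms: GeometryTable) -> tuple[int, float]:
    """Count discontinuous units and their share of all units (percent)."""
    if not geoms.geoms:
        raise DataError("empty geometry table")
    n_frag = sum(1 for g in geoms.geoms.values() if n_parts(g) > 1)
    return n_frag, 100.0 * n_frag / len(geoms.geoms)


def centroid_containment(geoms: GeometryTable) -> tuple[int, dict[str, bool]]:
    """Per-unit test whether the area centroid lies inside the unit
    (boundary counts as inside).  Returns (count outside, per-unit flags)."""
    inside = {uid: bool(g.covers(g.centroid)) for uid, g in geoms.geoms.items()}
    return sum(1 for v in inside.values() if not v), inside


def resolution_decline_index(median_target: float, median_initial: float) -> float:
    """Ratio of a candidate scale's median unit size to the finest initial
    unit's median size (surface area in km², or inhabitants)."""
    if median_target <= 0 or median_initial <= 0:
        raise DataError("decline index requires strictly positive medians")
    return median_target / median_initial


def spatial_report(
    analysis_geoms: GeometryTable,
    median_initial_area: float,
    references: dict[str, dict[str, float]] | None = None,
    analysis_median_pop: float | None = None,
    median_initial_pop: float | None = None,
) -> SpatialReport:
    """Assemble the spatial quality report for the analysis scale.

    ``references`` maps a reference-unit name (e.g. "canton") to its known
    ``median_area_km2`` and optionally ``median_pop``; each reference's
    decline index is computed against the same initial scale so the ratios
    are directly comparable.
    """
    n_frag, pct = fragmentation_index(analysis_geoms)
    n_out, _ = centroid_containment(analysis_geoms)
    areas = analysis_geoms.areas_km2().to_numpy()
    q1, q2, q3 = np.percentile(areas, [25, 50, 75])

    decline: dict[str, dict[str, float]] = {
        "analysis": {
            "surface_ratio": resolution_decline_index(float(q2), median_initial_area)
        }
    }
    if analysis_median_pop is not None and median_initial_pop is not None:
        decline["analysis"]["population_ratio"] = resolution_decline_index(
            analysis_median_pop, median_initial_pop
        )
    for name, ref in (references or {}).items():
        entry: dict[str, float] = {}
        if "median_area_km2" in ref:
            entry["surface_ratio"] = resolution_decline_index(
                float(ref["median_area_km2"]), median_initial_area
            )
        if "median_pop" in ref and median_initial_pop is not None:
            entry["population_ratio"] = resolution_decline_index(
                float(ref["median_pop"]), median_initial_pop
            )
        decline[name] = entry
    return SpatialReport(
        n_units=len(analysis_geoms.geoms),
        n_fragmented=n_frag,
        fragmentation_pct=pct,
        n_centroid_outside=n_out,
        median_area_km2=float(q2),
        iqr_area_km2=(float(q1), float(q3)),
        decline_indices=decline,
    )
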