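"""Domain types and file I/O for spatial crosswalk inputs.

Three kinds of artifact circulate through the pipeline:

* **transition matrices** — two-column ID crosswalks linking spatial IDs at
  one administrative level to the next (e.g. commune -> zip code);
* **aggregated tables** — per-spatial-unit variable values with metadata
  declaring each variable count, continuous or proportion;
* **geometry tables** — one (multi)polygon per spatial unit in a planar
  projected coordinate system, with areas reported in km².

IDs are opaque strings throughout: French commune and zip codes carry
leading zeros, so nothing here ever parses an ID as an integer.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from shapely.geometry import mapping as geom_mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

__all__ = [
    "ArealinkError",
    "ConfigError",
    "DataError",
    "VarMeta",
    "TransitionMatrix",
    "AggregatedTable",
    "GeometryTable",
    "read_transition_matrix",
    "write_transition_matrix",
    "read_aggregated_table",
    "write_aggregated_table",
    "read_geometries",
    "write_geometries",
]


class ArealinkError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(ArealinkError):
    """Invalid configuration or request (wrong method for a variable kind,
    ambiguous direction, chain break...)."""


class DataError(ArealinkError):
    """Malformed or inconsistent input data."""


VALID_KINDS = ("count", "continuous", "proportion")


@dataclass(frozen=True)
class VarMeta:
    """Metadata for one variable of an aggregated table.

    kind
        ``count`` (non-negative integers, aggregated by sum only),
        ``continuous`` or ``proportion`` (values in [0, 1]).
    weight_var
        name of a companion variable usable as weights in a weighted mean.
    tag
        semantic tag used to match variables shared by the two databases
        (e.g. both databases declare a variable tagged ``births``).
    """

    kind: str = "continuous"
    weight_var: str | None = None
    tag: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ConfigError(
                f"unknown variable kind {self.kind!r}; expected one of {VALID_KINDS}"
            )


@dataclass(frozen=True)
class TransitionMatrix:
    """A set of directed links between spatial-ID level ``j`` and ``j+1``.

    ``index`` is the matrix's position k in the chain M_1..M_p;
    ``source_level`` / ``target_level`` are the ID levels it connects
    (level 1 = ecological IDs, level p+1 = medical IDs, levels in between
    are temporary IDs created by the chaining).
    """

    index: int
    links: frozenset[tuple[str, str]]
    source_level: int = 1
    target_level: int = 2

    def __post_init__(self) -> None:
        if not self.links:
            raise DataError(f"empty matrix (M_{self.index})")
        for s, t in self.links:
            if not s or not t:
                raise DataError(f"malformed link in M_{self.index}: ({s!r}, {t!r})")

    @property
    def sources(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.links)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(t for _, t in self.links)

    def reversed(self) -> "TransitionMatrix":
        """Swap the link direction (used when the ecological units are the
        larger ones and must seed the analysis ID system)."""
        return TransitionMatrix(
            index=self.index,
            links=frozenset((t, s) for s, t in self.links),
            source_level=self.target_level,
            target_level=self.source_level,
        )


@dataclass
class AggregatedTable:
    """Per-spatial-unit variable values at one spatial level.

    ``data`` is indexed by the unit ID (string); one column per variable.
    Missing values stay NaN — they mark a unit as lacking that variable and
    are never imputed as zero.
    """

    data: pd.DataFrame
    var_meta: dict[str, VarMeta] = field(default_factory=dict)
    level: str = "unknown"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DataError(f"duplicate spatial unit {dup!r}")
        for var, meta in self.var_meta.items():
            if var not in self.data.columns:
                continue
            col = self.data[var].dropna()
            if meta.kind == "count":
                if (col < 0).any():
                    bad = col[col < 0].index[0]
                    raise DataError(f"invalid count for unit {bad!r} in {var!r}")
                if not (col == col.round()).all():
                    bad = col[col != col.round()].index[0]
                    raise DataError(
                        f"invalid count for unit {bad!r} in {var!r}: not an integer"
                    )
            elif meta.kind == "proportion":
                if ((col < 0) | (col > 1)).any():
                    bad = col[(col < 0) | (col > 1)].index[0]
                    raise DataError(
                        f"proportion out of range for unit {bad!r} in {var!r}"
                    )

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    def variables(self) -> list[str]:
        return list(self.data.columns)

    def completeness(self, var: str) -> float:
        """Fraction of units carrying a value for ``var``."""
        if var not in self.data.columns or len(self.data) == 0:
            return 0.0
        return float(self.data[var].notna().mean())


#: area conversion to km² per coordinate unit
_AREA_SCALE = {"km": 1.0, "m": 1e-6}


@dataclass
class GeometryTable:
    """Polygon or multipolygon geometries per spatial unit.

    Coordinates are assumed to be in a planar projected CRS; areas are
    planar.  ``coord_unit`` declares the linear unit of the coordinates
    ("km" or "m") so that areas can be reported in km².
    """

    geoms: dict[str, BaseGeometry]
    coord_unit: str = "km"

    def __post_init__(self) -> None:
        if self.coord_unit not in _AREA_SCALE:
            raise ConfigError(f"unknown coordinate unit {self.coord_unit!r}")
        for uid, g in self.geoms.items():
            if g.is_empty or g.area <= 0:
                raise DataError(f"zero-area geometry for unit {uid!r}")

    @property
    def ids(self) -> list[str]:
        return list(self.geoms)

    def area_km2(self, uid: str) -> float:
        return self.geoms[uid].area * _AREA_SCALE[self.coord_unit]

    def areas_km2(self) -> pd.Series:
        scale = _AREA_SCALE[self.coord_unit]
        return pd.Series({uid: g.area * scale for uid, g in self.geoms.items()})

    def median_area_km2(self) -> float:
        return float(self.areas_km2().median())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_transition_matrix(
    path: str | Path,
    k: int = 1,
    source_level: int | None = None,
    target_level: int | None = None,
) -> TransitionMatrix:
    """Read a two-column CSV crosswalk (header ``source_id,target_id``).

    Duplicate rows collapse to one link (set semantics); a blank ID raises
    a :class:`DataError` naming the offending line.
    """
    path = Path(path)
    links: set[tuple[str, str]] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DataError(f"empty matrix: {path}") from None
        if [h.strip() for h in header[:2]] != ["source_id", "target_id"]:
            raise DataError(
                f"{path}: expected header 'source_id,target_id', got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                raise DataError(f"{path}: malformed link on line {lineno}")
            links.add((row[0].strip(), row[1].strip()))
    if not links:
        raise DataError(f"empty matrix: {path}")
    return TransitionMatrix(
        index=k,
        links=frozenset(links),
        source_level=source_level if source_level is not None else k,
        target_level=target_level if target_level is not None else k + 1,
    )


def write_transition_matrix(matrix: TransitionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_id", "target_id"])
        for s, t in sorted(matrix.links):
            writer.writerow([s, t])


def read_aggregated_table(
    path: str | Path,
    meta: Mapping[str, VarMeta] | Mapping[str, Mapping[str, str]],
    level: str = "unknown",
    id_column: str = "id",
) -> AggregatedTable:
    """Read a CSV ``id,<var1>,<var2>,...`` table.

    Values are typed per the variable metadata; empty cells are recorded as
    missing (NaN), never as zero.
    """
    path = Path(path)
    var_meta = {
        v: (m if isinstance(m, VarMeta) else VarMeta(**m)) for v, m in meta.items()
    }
    df = pd.read_csv(path, dtype={id_column: str}, encoding="utf-8")
    if id_column not in df.columns:
        raise DataError(f"{path}: missing id column {id_column!r}")
    df = df.set_index(id_column)
    df.index.name = "id"
    for var in df.columns:
        df[var] = pd.to_numeric(df[var], errors="raise")
    return AggregatedTable(data=df, var_meta=var_meta, level=level)


def write_aggregated_table(table: AggregatedTable, path: str | Path) -> None:
    out = table.data.copy()
    # counts render as integers where complete
    for var, meta in table.var_meta.items():
        if meta.kind == "count" and var in out.columns and out[var].notna().all():
            out[var] = out[var].astype(int)
    out.to_csv(Path(path), index_label="id", encoding="utf-8")


def read_geometries(path: str | Path, coord_unit: str = "km") -> GeometryTable:
    """Read a GeoJSON FeatureCollection; each feature must carry an ``id``
    property (or top-level ``id``).  Invalid geometries are repaired with
    shapely's make_valid; zero-area results are rejected."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise DataError(f"{path}: not a GeoJSON FeatureCollection")
    geoms: dict[str, BaseGeometry] = {}
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        uid = props.get("id", feat.get("id"))
        if uid is None or str(uid) == "":
            raise DataError(f"{path}: feature {i} has no 'id' property")
        uid = str(uid)
        if uid in geoms:
            raise DataError(f"{path}: duplicate geometry id {uid!r}")
        g = shape(feat["geometry"])
        if not g.is_valid:
            g = make_valid(g)
        if g.is_empty or g.area <= 0:
            raise DataError(f"{path}: zero-area geometry for unit {uid!r}")
        geoms[uid] = g
    if not geoms:
        raise DataError(f"{path}: no features")
    return GeometryTable(geoms=geoms, coord_unit=coord_unit)


def write_geometries(table: GeometryTable, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"id": uid, "area_km2": table.area_km2(uid)},
            "geometry": geom_mapping(g),
        }
        for uid, g in table.geoms.items()
    ]
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc), encoding="utf-8")
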