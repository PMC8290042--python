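"""Readers and writers for the package's external representations.

Three file families are supported:

* **event tables** — delimited text (CSV/TSV by extension), one row per
  geotagged post: user id, timestamp, longitude, latitude;
* **place layers** — GeoJSON FeatureCollections of Polygon/MultiPolygon
  features in WGS84 lon/lat, carrying a place id and optionally a name and
  a parent-region id;
* **edge lists** — sparse pairwise place-to-place values (shared users,
  PCI, person-day movements, centroid distances) as CSV, mirroring the
  schema of publicly released connectivity matrices.

Floats in edge lists are serialized with 17 significant digits so that a
write/read cycle is bit-exact, including record order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry

EDGE_KINDS = frozenset(
    {"shared_users", "pci", "pci_directional", "person_days", "distance_miles"}
)
#: kinds stored once per unordered pair, with place_i < place_j
SYMMETRIC_KINDS = frozenset(
    {"shared_users", "pci", "person_days", "distance_miles"}
)

EVENT_COLUMNS = ("user_id", "timestamp", "lon", "lat")


class GeoDataError(ValueError):
    """Raised on malformed or invariant-violating external data."""


@dataclass
class EventTable:
    """Validated geotagged events plus a tally of rejected input rows."""

    events: pd.DataFrame  # columns: user_id, timestamp, lon, lat
    n_rejected: int = 0

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class EdgeList:
    """A sparse list of pairwise place values of a single kind.

    Symmetric kinds keep one record per unordered pair with
    ``place_i < place_j`` under lexicographic id order; the directional
    kind stores ``place_i`` as the origin.  Values are non-negative;
    PCI values are additionally bounded by 1.
    """

    kind: str
    df: pd.DataFrame  # columns: place_i, place_j, value

    def __post_init__(self) -> None:
        if self.kind not in EDGE_KINDS:
            raise GeoDataError(f"unknown edge-list kind: {self.kind!r}")
        df = self.df.reset_index(drop=True)
        df = df[["place_i", "place_j", "value"]].copy()
        df["place_i"] = df["place_i"].astype(str)
        df["place_j"] = df["place_j"].astype(str)
        df["value"] = df["value"].astype(float)
        if (df["value"] < 0).any():
            raise GeoDataError(f"negative value in {self.kind} edge list")
        if self.kind in ("pci", "pci_directional") and (df["value"] > 1).any():
            bad = df.loc[df["value"] > 1].iloc[0]
            raise GeoDataError(
                f"pci value {bad['value']} > 1 for pair "
                f"({bad['place_i']}, {bad['place_j']})"
            )
        if self.kind in SYMMETRIC_KINDS and len(df):
            if not (df["place_i"] < df["place_j"]).all():
                raise GeoDataError(
                    f"symmetric kind {self.kind}: records must satisfy "
                    "place_i < place_j"
                )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def value_dict(self) -> dict[tuple[str, str], float]:
        """Pair -> value mapping (keys as stored, i.e. ordered for
        symmetric kinds)."""
        return {
            (i, j): v
            for i, j, v in zip(self.df["place_i"], self.df["place_j"], self.df["value"])
        }


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order an unordered place pair lexicographically."""
    return (a, b) if a <= b else (b, a)


@dataclass
class PlaceLayer:
    """Polygon places with ids, optional names/parents and centroids."""

    places: pd.DataFrame  # place_id, name, parent_id, centroid_lon, centroid_lat
    geometries: dict[str, BaseGeometry] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.places["place_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise GeoDataError(f"duplicate place_id: {dup!r}")
        self.places = self.places.reset_index(drop=True)

    @property
    def place_ids(self) -> list[str]:
        return list(self.places["place_id"])

    def parent_map(self) -> dict[str, str]:
        """place_id -> parent_id for places that declare a parent."""
        sub = self.places.dropna(subset=["parent_id"])
        return dict(zip(sub["place_id"], sub["parent_id"]))

    def centroids(self) -> pd.DataFrame:
        return self.places.set_index("place_id")[["centroid_lon", "centroid_lat"]]


@dataclass
class PlaceSummary:
    """Per-place scalars: unique-user counts S_i and optional covariates."""

    df: pd.DataFrame  # place_id, user_count, + covariate columns

    def __post_init__(self) -> None:
        if (self.df["user_count"] < 0).any():
            raise GeoDataError("user_count must be non-negative")
        self.df = self.df.reset_index(drop=True)

    def user_counts(self) -> dict[str, int]:
        return dict(zip(self.df["place_id"].astype(str), self.df["user_count"]))


# ---------------------------------------------------------------------------
# event tables


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_events(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> EventTable:
    """Read a delimited event table, validating each row.

    ``columns`` maps the canonical names (``user_id``, ``timestamp``,
    ``lon``, ``lat``) to the file's header names; by default the canonical
    names are expected verbatim.  Rows with out-of-bounds coordinates,
    unparseable timestamps or empty user ids are skipped and tallied.
    """
    columns = dict(columns) if columns else {c: c for c in EVENT_COLUMNS}
    missing_keys = set(EVENT_COLUMNS) - set(columns)
    if missing_keys:
        raise GeoDataError(f"column mapping missing {sorted(missing_keys)}")
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    for want in EVENT_COLUMNS:
        if columns[want] not in raw.columns:
            raise GeoDataError(
                f"required column {columns[want]!r} (for {want}) not in header"
            )
    df = pd.DataFrame(
        {want: raw[columns[want]] for want in EVENT_COLUMNS}
    )
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="mixed")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    ok = (
        ts.notna()
        & lon.between(-180.0, 180.0)
        & lat.between(-90.0, 90.0)
        & (df["user_id"].str.len() > 0)
    )
    events = pd.DataFrame(
        {
            "user_id": df.loc[ok, "user_id"],
            "timestamp": ts[ok].dt.tz_localize(None),
            "lon": lon[ok],
            "lat": lat[ok],
        }
    ).reset_index(drop=True)
    return EventTable(events=events, n_rejected=int((~ok).sum()))


def write_events(table: pd.DataFrame | EventTable, path: str | Path) -> None:
    df = table.events if isinstance(table, EventTable) else table
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# place layers (GeoJSON)


def read_place_layer(
    path: str | Path,
    id_field: str = "place_id",
    name_field: str | None = "name",
    parent_field: str | None = None,
) -> PlaceLayer:
    """Read a GeoJSON FeatureCollection of polygon places.

    Centroids are computed from the geometries.  Non-polygonal features
    and duplicate ids raise :class:`GeoDataError`.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise GeoDataError("expected a GeoJSON FeatureCollection")
    rows = []
    geoms: dict[str, BaseGeometry] = {}
    for k, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        if id_field not in props:
            raise GeoDataError(f"feature {k} lacks id field {id_field!r}")
        pid = str(props[id_field])
        geom = geom_shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise GeoDataError(
                f"feature {pid!r} has non-polygon geometry {geom.geom_type}"
            )
        if pid in geoms:
            raise GeoDataError(f"duplicate place_id: {pid!r}")
        geoms[pid] = geom
        c = geom.centroid
        rows.append(
            {
                "place_id": pid,
                "name": str(props.get(name_field, pid)) if name_field else pid,
                "parent_id": (
                    str(props[parent_field])
                    if parent_field and props.get(parent_field) is not None
                    else None
                ),
                "centroid_lon": c.x,
                "centroid_lat": c.y,
            }
        )
    return PlaceLayer(places=pd.DataFrame(rows), geometries=geoms)


def write_place_layer(layer: PlaceLayer, path: str | Path) -> None:
    """Write a place layer as a GeoJSON FeatureCollection."""
    feats = []
    for _, row in layer.places.iterrows():
        pid = row["place_id"]
        props = {"place_id": pid, "name": row["name"]}
        if pd.notna(row.get("parent_id")):
            props["parent_id"] = row["parent_id"]
        feats.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": geom_mapping(layer.geometries[pid]),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# edge lists


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    """Write ``place_i,place_j,kind,value`` CSV; lossless float encoding."""
    with open(path, "w") as fh:
        fh.write("place_i,place_j,kind,value\n")
        for i, j, v in zip(
            edges.df["place_i"], edges.df["place_j"], edges.df["value"]
        ):
            fh.write(f"{i},{j},{edges.kind},{v:.17g}\n")


def read_edge_list(path: str | Path) -> EdgeList:
    df = pd.read_csv(path, dtype={"place_i": str, "place_j": str, "kind": str})
    if len(df) == 0:
        # header-only file: kind cannot be recovered, default to pci
        return EdgeList(kind="pci", df=pd.DataFrame(columns=["place_i", "place_j", "value"]))
    kinds = df["kind"].unique()
    if len(kinds) > 1:
        raise GeoDataError(f"mixed kinds in one edge list: {sorted(kinds)}")
    kind = kinds[0]
    if kind not in EDGE_KINDS:
        raise GeoDataError(f"unknown edge-list kind: {kind!r}")
    return EdgeList(kind=kind, df=df[["place_i", "place_j", "value"]])


# ---------------------------------------------------------------------------
# per-place summaries


def write_place_summary(summary: PlaceSummary, path: str | Path) -> None:
    summary.df.to_csv(path, index=False, float_format="%.17g")


def read_place_summary(path: str | Path) -> PlaceSummary:
    df = pd.read_csv(path, dtype={"place_id": str})
    if "user_count" not in df.columns:
        raise GeoDataError("summary file lacks a user_count column")
    return PlaceSummary(df=df)


def read_parent_map(path: str | Path) -> dict[str, str]:
    """Two-column CSV ``child_id,parent_id`` -> mapping."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise GeoDataError("parent map needs two columns: child_id,parent_id")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
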