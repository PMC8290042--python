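"""Point-to-place assignment, hierarchy mapping, and centroid distances.

Assignment uses "covers" semantics: a point on a polygon's boundary
belongs to that polygon.  When two places both cover a point (shared
boundaries, sliver overlaps) the lexicographically smallest place id
wins, with a warning — deterministic and independent of input order.

Distances are great-circle (haversine) on a sphere of radius 3958.8
statute miles between place centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point

from .geodata_io import EdgeList, EventTable, GeoDataError, PlaceLayer

EARTH_RADIUS_MILES = 3958.8


@dataclass
class AssignmentTable:
    """Events mapped to places; unmatched events are counted, not kept."""

    records: pd.DataFrame  # columns: user_id, timestamp, place_id
    unassigned_count: int = 0

    def __len__(self) -> int:
        return len(self.records)


def assign_points(
    events: pd.DataFrame | EventTable, layer: PlaceLayer
) -> AssignmentTable:
    """Assign each event to the place whose polygon covers it.

    Events covered by no polygon increment ``unassigned_count``; events
    covered by several polygons are assigned to the smallest place id
    and a single warning reports how many such ties occurred.
    """
    df = events.events if isinstance(events, EventTable) else events
    ids = layer.place_ids
    if not ids:
        raise GeoDataError("place layer is empty")
    geoms = [layer.geometries[p] for p in ids]
    tree = STRtree(geoms)
    pts = [Point(x, y) for x, y in zip(df["lon"], df["lat"])]
    # for points, 'intersects' coincides with 'covered by'
    ev_idx, pl_idx = tree.query(pts, predicate="intersects")
    assigned = pd.DataFrame({"event": ev_idx, "place": pl_idx})
    assigned["place_id"] = assigned["place"].map(lambda k: ids[k])
    n_ties = int(assigned["event"].duplicated().sum())
    if n_ties:
        warnings.warn(
            f"{n_ties} event(s) covered by multiple places; "
            "assigned to the smallest place id",
            stacklevel=2,
        )
    best = assigned.sort_values(["event", "place_id"]).drop_duplicates("event")
    records = df.iloc[best["event"].to_numpy()][["user_id", "timestamp"]].copy()
    records["place_id"] = best["place_id"].to_numpy()
    records = records.reset_index(drop=True)
    return AssignmentTable(
        records=records, unassigned_count=len(df) - len(records)
    )


def map_to_level(
    assignment: AssignmentTable, child_to_parent: Mapping[str, str]
) -> AssignmentTable:
    """Re-key assignments to a coarser level via a child->parent mapping.

    Unique-user quantities must be recounted after mapping (a user seen
    in two sibling children is one user at the parent), which is why the
    records themselves are re-keyed rather than any counts being summed.
    """
    present = assignment.records["place_id"].unique()
    orphans = [p for p in present if p not in child_to_parent]
    if orphans:
        raise GeoDataError(f"no parent for place_id {orphans[0]!r}")
    records = assignment.records.copy()
    records["place_id"] = records["place_id"].map(child_to_parent)
    return AssignmentTable(
        records=records, unassigned_count=assignment.unassigned_count
    )


def haversine_miles(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in statute miles (spherical Earth)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_MILES * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def centroid_distance(layer: PlaceLayer) -> EdgeList:
    """All-pairs centroid distances as an edge list of kind
    ``distance_miles`` (one record per unordered pair)."""
    cent = layer.centroids().sort_index()
    ids = cent.index.to_numpy()
    lon = cent["centroid_lon"].to_numpy()
    lat = cent["centroid_lat"].to_numpy()
    iu, ju = np.triu_indices(len(ids), k=1)
    d = haversine_miles(lon[iu], lat[iu], lon[ju], lat[ju])
    df = pd.DataFrame({"place_i": ids[iu], "place_j": ids[ju], "value": d})
    return EdgeList(kind="distance_miles", df=df)
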