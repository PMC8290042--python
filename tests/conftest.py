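"""Shared fixtures: toy layers, random incidence sets, brute-force oracles."""

from __future__ import annotations

import math
from collections import defaultdict
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from placeconn import IncidenceSet, PlaceLayer


@pytest.fixture
def unit_square_layer() -> PlaceLayer:
    """Four unit squares in a 2x2 grid: A B / C D (A at origin)."""
    cells = {
        "A": box(0, 0, 1, 1),
        "B": box(1, 0, 2, 1),
        "C": box(0, 1, 1, 2),
        "D": box(1, 1, 2, 2),
    }
    rows = [
        {
            "place_id": pid,
            "name": pid,
            "parent_id": "west" if pid in ("A", "C") else "east",
            "centroid_lon": geom.centroid.x,
            "centroid_lat": geom.centroid.y,
        }
        for pid, geom in cells.items()
    ]
    return PlaceLayer(places=pd.DataFrame(rows), geometries=cells)


def random_incidence(
    rng: np.random.Generator,
    max_places: int = 50,
    max_users: int = 500,
) -> IncidenceSet:
    """Random user-place observation sets (every user observes >=1 place)."""
    n_places = int(rng.integers(2, max_places + 1))
    n_users = int(rng.integers(1, max_users + 1))
    places = [f"p{k:03d}" for k in range(n_places)]
    user_places = {}
    for u in range(n_users):
        m = 1 + rng.geometric(0.6)  # mostly 1-3 places per user
        m = min(m, n_places)
        chosen = rng.choice(n_places, size=m, replace=False)
        user_places[f"u{u:04d}"] = frozenset(places[c] for c in chosen)
    period = (pd.Timestamp("2019-01-01"), pd.Timestamp("2020-01-01"))
    return IncidenceSet(period=period, user_places=user_places)


def brute_force_pci(
    user_places: dict[str, frozenset[str]],
) -> tuple[dict[tuple[str, str], int], dict[tuple[str, str], float]]:
    """Independent oracle: materialize per-place user sets, intersect
    every pair.  Returns shared-user counts and PCI for pairs with
    at least one shared user."""
    place_users: dict[str, set[str]] = defaultdict(set)
    for u, ps in user_places.items():
        for p in ps:
            place_users[p].add(u)
    shared = {}
    pci = {}
    for a, b in combinations(sorted(place_users), 2):
        s = len(place_users[a] & place_users[b])
        if s:
            shared[(a, b)] = s
            pci[(a, b)] = s / math.sqrt(len(place_users[a]) * len(place_users[b]))
    return shared, pci
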