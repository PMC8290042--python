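"""Synthetic worlds and mobility with known ground truth.

The generator builds a grid world of square places tiled into "states"
(parent regions), assigns each place a population, and simulates a year
of user-level geotagged events from a gravity process:

* users get home places with probability proportional to population;
* each user's event count is Poisson;
* each event is at home with probability ``1 - trip_fraction``,
  otherwise it is a trip whose destination j is drawn with probability
  proportional to  P_j * d(home, j)^(-beta) * gamma^[same state],
  the minimal kernel producing the three regularities connectivity
  indices exhibit on real mobility data: population scaling, power-law
  distance decay, and excess within-state interaction;
* event coordinates are uniform inside the destination cell and
  timestamps uniform over the period.

Everything is deterministic under a fixed seed, and the realized
user-place visit sets and trip counts are returned as ground truth so
every downstream stage can be checked against what actually happened.

``make_block_pci`` separately emits planted block-structured PCI
matrices for clustering tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .connectivity import PCIMatrix
from .geodata_io import EdgeList, GeoDataError, PlaceLayer, PlaceSummary
from .spatial import EARTH_RADIUS_MILES, haversine_miles

MILES_PER_DEGREE = 2.0 * np.pi * EARTH_RADIUS_MILES / 360.0  # ~69.093


@dataclass
class WorldConfig:
    """Grid-world geometry and demography."""

    grid_rows: int = 8
    grid_cols: int = 8
    cell_size_miles: float = 69.093
    states: int = 4
    population_range: tuple[int, int] = (5_000, 50_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows * self.grid_cols < 2:
            raise GeoDataError("world needs at least 2 places")


@dataclass
class MobilityConfig:
    """Gravity-mobility parameters.

    ``decay_exponent`` (beta) and ``same_state_boost`` (gamma) default
    to 1.7 and 3.0 — a clearly detectable decay and boundary effect.
    ``n_users`` overrides the population-proportional user count when
    set.  The default period is one calendar year.

    The default activity level (12 events/user/year, a quarter of them
    trips) keeps per-destination visit probabilities small.  That is
    both typical of geotagged social-media posting and necessary for
    unique shared-user counts to stay roughly proportional to trip
    flows: at high activity the visit indicator saturates (a user seen
    in a nearby place once is the same user seen there twenty times)
    and connectivity flattens relative to the underlying gravity
    kernel.
    """

    users_per_capita: float = 0.002
    n_users: int | None = None
    events_per_user_mean: float = 12.0
    trip_fraction: float = 0.25
    decay_exponent: float = 1.7
    same_state_boost: float = 3.0
    period: tuple[str, str] = ("2019-01-01", "2020-01-01")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.trip_fraction <= 1.0:
            raise GeoDataError("trip_fraction must be in [0, 1]")
        if self.decay_exponent < 0 or not np.isfinite(self.decay_exponent):
            raise GeoDataError("decay_exponent must be finite and >= 0")
        if self.same_state_boost < 1 or not np.isfinite(self.same_state_boost):
            raise GeoDataError("same_state_boost must be finite and >= 1")


def _state_tiling(rows: int, cols: int, states: int) -> tuple[int, int]:
    """Factor ``states`` into a p x q block tiling of the grid.

    Picks the factorization closest to square among those where p
    divides rows and q divides cols; errors when none exists.
    """
    options = [
        (p, states // p)
        for p in range(1, states + 1)
        if states % p == 0 and rows % p == 0 and cols % (states // p) == 0
    ]
    if not options:
        raise GeoDataError(
            f"{states} states cannot tile a {rows}x{cols} grid evenly"
        )
    return min(options, key=lambda pq: abs(pq[0] - pq[1]))


def make_world(config: WorldConfig) -> tuple[PlaceLayer, PlaceSummary]:
    """Build the grid place layer and its population summary.

    Cells are squares in degrees, centered on the equator so that a
    cell size of ~69.09 miles yields adjacent centroid distances of the
    same magnitude; state ids tile the grid in blocks.
    """
    rows, cols = config.grid_rows, config.grid_cols
    p, q = _state_tiling(rows, cols, config.states)
    step = config.cell_size_miles / MILES_PER_DEGREE
    if cols * step > 360.0 + 1e-9 or rows * step > 180.0 + 1e-9:
        raise GeoDataError("grid does not fit on the globe at this cell size")
    lat0 = -rows * step / 2.0
    lon0 = -cols * step / 2.0
    rng = np.random.default_rng(config.seed)
    recs = []
    geoms = {}
    for r in range(rows):
        for c in range(cols):
            pid = f"r{r:02d}c{c:02d}"
            state = f"s{(r // (rows // p)) * q + (c // (cols // q)):02d}"
            x0, y0 = lon0 + c * step, lat0 + r * step
            geom = box(x0, y0, x0 + step, y0 + step)
            geoms[pid] = geom
            recs.append(
                {
                    "place_id": pid,
                    "name": pid,
                    "parent_id": state,
                    "centroid_lon": x0 + step / 2.0,
                    "centroid_lat": y0 + step / 2.0,
                }
            )
    layer = PlaceLayer(places=pd.DataFrame(recs), geometries=geoms)
    lo, hi = config.population_range
    pops = rng.integers(lo, hi + 1, size=rows * cols)
    summary = PlaceSummary(
        df=pd.DataFrame(
            {
                "place_id": [r["place_id"] for r in recs],
                "user_count": 0,
                "population": pops,
            }
        )
    )
    return layer, summary


@dataclass
class SimulationResult:
    """Events plus the ground truth that generated them."""

    events: pd.DataFrame  # user_id, timestamp, lon, lat
    homes: dict[str, str]
    visit_sets: dict[str, frozenset[str]] = field(repr=False, default_factory=dict)
    trip_counts: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)
    # trip_counts: home x destination matrix of realized trip events


def simulate_events(
    layer: PlaceLayer, populations: PlaceSummary, config: MobilityConfig
) -> SimulationResult:
    """Simulate a stream of geotagged events from the gravity process."""
    places = layer.places.sort_values("place_id").reset_index(drop=True)
    ids = places["place_id"].to_numpy()
    n = len(ids)
    pop = (
        populations.df.set_index("place_id")["population"]
        .reindex(ids)
        .to_numpy(dtype=float)
    )
    if np.isnan(pop).any():
        raise GeoDataError("populations missing for some places")
    parents = places["parent_id"].to_numpy()
    lon = places["centroid_lon"].to_numpy()
    lat = places["centroid_lat"].to_numpy()
    dmat = haversine_miles(
        lon[:, None], lat[:, None], lon[None, :], lat[None, :]
    )
    bounds = np.array([layer.geometries[p].bounds for p in ids])  # minx,miny,maxx,maxy

    rng = np.random.default_rng(config.seed)
    n_users = (
        config.n_users
        if config.n_users is not None
        else max(2, int(round(config.users_per_capita * pop.sum())))
    )
    homes_idx = rng.choice(n, size=n_users, p=pop / pop.sum())
    event_counts = rng.poisson(config.events_per_user_mean, size=n_users)

    start = pd.Timestamp(config.period[0])
    end = pd.Timestamp(config.period[1])
    span = (end - start).total_seconds()

    uid = np.array([f"u{k:06d}" for k in range(n_users)])
    trip_counts = np.zeros((n, n), dtype=np.int64)

    frames = []
    # group users by home so one destination kernel serves each group
    for h in np.unique(homes_idx):
        sel = np.flatnonzero(homes_idx == h)
        counts = event_counts[sel]
        total = int(counts.sum())
        if total == 0:
            continue
        with np.errstate(divide="ignore"):
            w = pop * dmat[h] ** (-config.decay_exponent)
        w *= np.where(parents == parents[h], config.same_state_boost, 1.0)
        w[h] = 0.0  # home handled by the trip flag, not the kernel
        if w.sum() <= 0:
            w = np.zeros(n)
            w[(h + 1) % n] = 1.0
        w = w / w.sum()
        is_trip = rng.random(total) < config.trip_fraction
        place_idx = np.full(total, h)
        n_trips = int(is_trip.sum())
        if n_trips:
            place_idx[is_trip] = rng.choice(n, size=n_trips, p=w)
        ux = (bounds[place_idx, 2] - bounds[place_idx, 0]) * rng.random(total)
        uy = (bounds[place_idx, 3] - bounds[place_idx, 1]) * rng.random(total)
        secs = rng.random(total) * span
        np.add.at(trip_counts[h], place_idx[is_trip], 1)
        frames.append(
            pd.DataFrame(
                {
                    "user_id": np.repeat(uid[sel], counts),
                    "timestamp": start + pd.to_timedelta(secs, unit="s"),
                    "lon": bounds[place_idx, 0] + ux,
                    "lat": bounds[place_idx, 1] + uy,
                    "_place": ids[place_idx],
                }
            )
        )

    events = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["user_id", "timestamp", "lon", "lat", "_place"])
    )
    visit_sets = {
        u: frozenset(g) for u, g in events.groupby("user_id")["_place"]
    }
    events = events.drop(columns="_place")
    homes = {uid[k]: ids[homes_idx[k]] for k in range(n_users)}
    return SimulationResult(
        events=events,
        homes=homes,
        visit_sets=visit_sets,
        trip_counts=pd.DataFrame(trip_counts, index=ids, columns=ids),
    )


def boundary_validation_world(seed: int = 0) -> WorldConfig:
    """World used to validate boundary-effect inference.

    A 24-cell ring around the equator (cells of 15 degrees, so the ring
    closes exactly) tiled into 4 equal states, with equal populations.
    Translational symmetry makes every place geometrically equivalent:
    at any fixed distance, same-state and cross-state pairs are
    congruent, so with ``same_state_boost=1`` the boundary effect is
    exactly null and the regression's error assumptions approximately
    hold.  Bounded grids do not have this property — their corners see
    systematically fewer reachable destinations, which confounds state
    membership with accessibility.
    """
    return WorldConfig(
        grid_rows=1,
        grid_cols=24,
        cell_size_miles=15.0 * MILES_PER_DEGREE,
        states=4,
        population_range=(20_000, 20_000),
        seed=seed,
    )


def make_block_pci(
    n_blocks: int,
    block_size: int,
    intra_pci: float,
    inter_pci: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[PCIMatrix, dict[str, int]]:
    """Planted block-structured PCI matrix plus its true labels.

    Off-diagonal values are the block mean (``intra_pci`` within a
    block, ``inter_pci`` across) plus Gaussian noise truncated to
    [0, 1].  Values truncated to exactly 0 are left implicit, matching
    the sparse zero-pair convention.  Place user counts are set to a
    constant 100 so the matrix passes the default minimum-user filter.
    """
    if not 0.0 <= inter_pci < intra_pci <= 1.0:
        raise GeoDataError("need 0 <= inter_pci < intra_pci <= 1")
    rng = np.random.default_rng(seed)
    ids = [
        f"b{b:02d}p{i:02d}" for b in range(n_blocks) for i in range(block_size)
    ]
    labels = {pid: int(pid[1:3]) for pid in ids}
    n = len(ids)
    rows = []
    for a in range(n):
        for b in range(a + 1, n):
            mean = intra_pci if labels[ids[a]] == labels[ids[b]] else inter_pci
            v = float(np.clip(mean + rng.normal(0.0, noise_sd), 0.0, 1.0)) if noise_sd else mean
            if v > 0:
                rows.append({"place_i": ids[a], "place_j": ids[b], "value": v})
    pci_df = pd.DataFrame(rows, columns=["place_i", "place_j", "value"])
    shared = pci_df.assign(value=pci_df["value"] * 100.0)
    summary = PlaceSummary(
        df=pd.DataFrame({"place_id": ids, "user_count": 100})
    )
    return (
        PCIMatrix(
            pci=EdgeList(kind="pci", df=pci_df),
            shared_users=EdgeList(kind="shared_users", df=shared),
            summary=summary,
        ),
        labels,
    )
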