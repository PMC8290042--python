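"""The Place Connectivity Index (PCI) and its companion quantities.

A user is *observed in* a place when they have at least one assigned
event there within the analysis period T (half-open ``[start, end)``).
With S_i the number of unique users observed in place i and S_ij the
number of users observed in both i and j,

    PCI_ij = S_ij / sqrt(S_i * S_j)

which lies in [0, 1]: 0 when the places share no user, 1 when i = j (or
when every user of each place is seen in the other and S_i = S_j).  The
geometric-mean denominator removes the first-order effect of place size
so that connectivity is comparable across places of very different user
counts.

A directional variant PCI_{i->j} = S_ij / S_i captures asymmetric pull;
its geometric mean over the two directions reproduces the symmetric
index exactly.

Person-day movements count (user, UTC-day) units of inter-place
movement, in one of two modes:

* ``home_based`` — a user with at least one event in place j != home on
  a given day contributes one movement to the pair (home, j);
* ``copresence`` — a user seen in m >= 2 distinct places on a day
  contributes one movement to each of the C(m, 2) unordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import sparse

from .geodata_io import EdgeList, GeoDataError, PlaceSummary
from .spatial import AssignmentTable

Period = tuple[pd.Timestamp, pd.Timestamp]


@dataclass
class IncidenceSet:
    """User <-> place observation sets within a period.

    ``user_places`` maps each user to the set of places they were
    observed in; ``place_users`` holds the unique-user counts S_i
    (derived, kept consistent by construction).
    """

    period: Period
    user_places: dict[str, frozenset[str]]
    place_users: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.place_users:
            counts: dict[str, int] = {}
            for places in self.user_places.values():
                for p in places:
                    counts[p] = counts.get(p, 0) + 1
            self.place_users = counts

    @property
    def n_users(self) -> int:
        return len(self.user_places)


@dataclass
class PCIMatrix:
    """Sparse symmetric PCI with its shared-user companion and S_i."""

    pci: EdgeList
    shared_users: EdgeList
    summary: PlaceSummary


@dataclass
class MovementMatrix:
    """Pairwise person-day movement counts."""

    person_days: EdgeList
    mode: str


def _as_period(period: Period) -> Period:
    start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    if not start < end:
        raise GeoDataError(f"period start {start} must precede end {end}")
    return start, end


def build_incidence(assignment: AssignmentTable, period: Period) -> IncidenceSet:
    """Collect each user's set of observed places within [start, end)."""
    start, end = _as_period(period)
    rec = assignment.records
    ts = pd.to_datetime(rec["timestamp"])
    inside = rec.loc[(ts >= start) & (ts < end), ["user_id", "place_id"]]
    user_places = {
        str(u): frozenset(g) for u, g in inside.groupby("user_id")["place_id"]
    }
    return IncidenceSet(period=(start, end), user_places=user_places)


def _incidence_matrix(
    incidence: IncidenceSet,
) -> tuple[np.ndarray, sparse.csr_matrix]:
    """Boolean users x places matrix over lexicographically sorted ids."""
    places = np.array(sorted(incidence.place_users))
    col = {p: k for k, p in enumerate(places)}
    rows, cols = [], []
    for u, (_, pset) in enumerate(sorted(incidence.user_places.items())):
        for p in pset:
            rows.append(u)
            cols.append(col[p])
    a = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(incidence.n_users, len(places)),
    )
    return places, a


def compute_pci(incidence: IncidenceSet) -> PCIMatrix:
    """Shared users and PCI for every place pair with S_ij > 0.

    Zero pairs are implicit (absent records); self-pairs are omitted
    from the edge lists since PCI_ii is identically 1.
    """
    if incidence.n_users == 0:
        raise GeoDataError("empty incidence set")
    places, a = _incidence_matrix(incidence)
    co = sparse.triu((a.T @ a).tocoo(), k=1).tocoo()
    s = np.array([incidence.place_users[p] for p in places], dtype=float)
    shared = pd.DataFrame(
        {
            "place_i": places[co.row],
            "place_j": places[co.col],
            "value": co.data.astype(float),
        }
    ).sort_values(["place_i", "place_j"], ignore_index=True)
    pci_vals = shared["value"].to_numpy() / np.sqrt(
        np.array([incidence.place_users[p] for p in shared["place_i"]])
        * np.array([incidence.place_users[p] for p in shared["place_j"]])
    )
    pci = shared.assign(value=pci_vals)
    summary = PlaceSummary(
        df=pd.DataFrame(
            {"place_id": places, "user_count": s.astype(int)}
        )
    )
    return PCIMatrix(
        pci=EdgeList(kind="pci", df=pci),
        shared_users=EdgeList(kind="shared_users", df=shared),
        summary=summary,
    )


def compute_directional_pci(incidence: IncidenceSet) -> EdgeList:
    """Directional index PCI_{i->j} = S_ij / S_i, both directions stored.

    The geometric mean of the two directions equals the symmetric PCI:
    sqrt(S_ij/S_i * S_ij/S_j) = S_ij / sqrt(S_i S_j).
    """
    sym = compute_pci(incidence).shared_users.df
    s = {p: float(c) for p, c in incidence.place_users.items()}
    fwd = pd.DataFrame(
        {
            "place_i": sym["place_i"],
            "place_j": sym["place_j"],
            "value": sym["value"] / sym["place_i"].map(s),
        }
    )
    rev = pd.DataFrame(
        {
            "place_i": sym["place_j"],
            "place_j": sym["place_i"],
            "value": sym["value"] / sym["place_j"].map(s),
        }
    )
    out = pd.concat([fwd, rev], ignore_index=True).sort_values(
        ["place_i", "place_j"], ignore_index=True
    )
    return EdgeList(kind="pci_directional", df=out)


def infer_home(assignment: AssignmentTable) -> dict[str, str]:
    """Each user's home: modal place by event count.

    Ties are broken by earliest first observation in the place, then by
    lexicographic place id.
    """
    rec = assignment.records
    g = (
        rec.groupby(["user_id", "place_id"])
        .agg(n=("timestamp", "size"), first_seen=("timestamp", "min"))
        .reset_index()
    )
    g = g.sort_values(
        ["user_id", "n", "first_seen", "place_id"],
        ascending=[True, False, True, True],
    )
    best = g.drop_duplicates("user_id")
    return dict(zip(best["user_id"].astype(str), best["place_id"].astype(str)))


def compute_person_day_movements(
    assignment: AssignmentTable,
    period: Period,
    mode: str = "home_based",
    home: dict[str, str] | None = None,
) -> MovementMatrix:
    """Person-day movement counts between place pairs within the period."""
    if mode not in ("home_based", "copresence"):
        raise GeoDataError(f"unknown person-day mode: {mode!r}")
    start, end = _as_period(period)
    rec = assignment.records
    ts = pd.to_datetime(rec["timestamp"])
    sub = rec.loc[(ts >= start) & (ts < end)].copy()
    sub["day"] = pd.to_datetime(sub["timestamp"]).dt.normalize()
    # distinct (user, day, place) triples
    triples = sub.drop_duplicates(["user_id", "day", "place_id"])

    counts: dict[tuple[str, str], int] = {}
    if mode == "copresence":
        for (_, _), places in triples.groupby(["user_id", "day"])["place_id"]:
            ps = sorted(places)
            for a, b in combinations(ps, 2):
                counts[(a, b)] = counts.get((a, b), 0) + 1
    else:
        if home is None:
            raise GeoDataError("home_based mode requires a home table")
        t = triples.copy()
        t["home"] = t["user_id"].map(home)
        if t["home"].isna().any():
            u = t.loc[t["home"].isna(), "user_id"].iloc[0]
            raise GeoDataError(f"no home for user {u!r}")
        away = t.loc[t["place_id"] != t["home"]]
        for h, j in zip(away["home"], away["place_id"]):
            key = (h, j) if h < j else (j, h)
            counts[key] = counts.get(key, 0) + 1

    pairs = sorted(counts)
    df = pd.DataFrame(
        {
            "place_i": [p[0] for p in pairs],
            "place_j": [p[1] for p in pairs],
            "value": [float(counts[p]) for p in pairs],
        },
        columns=["place_i", "place_j", "value"],
    )
    return MovementMatrix(
        person_days=EdgeList(kind="person_days", df=df), mode=mode
    )


def filter_min_users(pci_matrix: PCIMatrix, min_users: int = 5) -> PCIMatrix:
    """Drop places with S_i below ``min_users`` together with their edges.

    The default of 5 mirrors the convention of ignoring places with
    fewer than five observed users, whose index values are dominated by
    a handful of individuals.
    """
    if min_users < 0:
        raise GeoDataError("min_users must be >= 0")
    summary = pci_matrix.summary.df
    keep = set(summary.loc[summary["user_count"] >= min_users, "place_id"])

    def _filter(edges: EdgeList) -> EdgeList:
        df = edges.df
        ok = df["place_i"].isin(keep) & df["place_j"].isin(keep)
        return EdgeList(kind=edges.kind, df=df.loc[ok].reset_index(drop=True))

    return PCIMatrix(
        pci=_filter(pci_matrix.pci),
        shared_users=_filter(pci_matrix.shared_users),
        summary=PlaceSummary(
            df=summary.loc[summary["place_id"].isin(keep)].reset_index(drop=True)
        ),
    )
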