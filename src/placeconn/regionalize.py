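"""Regionalization: agglomerative clustering on inverse-PCI distances.

Places are grouped into connectivity communities by unweighted
average-linkage (UPGMA) agglomeration of the dissimilarity d_ij =
1/PCI_ij.  Pairs sharing no user (PCI = 0) receive a finite sentinel —
ten times the largest finite dissimilarity — so they merge last without
breaking the arithmetic.  Cutting the dendrogram at a target number of
communities k yields the regionalization; several k can be requested in
one pass and the assignments are nested by construction.

The linkage is implemented here rather than delegated so that ties in
the merge order are broken deterministically: among equally close
community pairs, the one whose combined member set has the
lexicographically smallest (min id, max id) is merged first.  The
Lance-Williams update d(A∪B, C) = (|A| d(A,C) + |B| d(B,C)) / (|A|+|B|)
reproduces unweighted average linkage exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import PCIMatrix
from .geodata_io import EdgeList, GeoDataError


@dataclass
class Merge:
    """One agglomeration step."""

    community_a: tuple[str, ...]
    community_b: tuple[str, ...]
    linkage_distance: float
    new_size: int


@dataclass
class RegionAssignment:
    """place_id -> community label (0..k-1)."""

    labels: dict[str, int]
    k: int


@dataclass
class Dendrogram:
    merges: list[Merge]

    def __len__(self) -> int:
        return len(self.merges)


def pci_to_distance(
    pci_matrix: PCIMatrix | EdgeList, sentinel_factor: float = 10.0
) -> tuple[list[str], np.ndarray]:
    """Inverse-PCI dissimilarity matrix over the retained places.

    Expects the minimum-user filter to have been applied already.
    d_ij = 1/PCI_ij for observed pairs; unobserved pairs (no shared
    users) get ``sentinel_factor`` times the largest finite distance;
    d_ii = 0.
    """
    if isinstance(pci_matrix, PCIMatrix):
        edges = pci_matrix.pci
        ids = sorted(pci_matrix.summary.df["place_id"].astype(str))
    else:
        edges = pci_matrix
        ids = sorted(set(edges.df["place_i"]) | set(edges.df["place_j"]))
    n = len(ids)
    if n < 2:
        raise GeoDataError(f"need >= 2 retained places, got {n}")
    pos = {p: k for k, p in enumerate(ids)}
    d = np.full((n, n), np.nan)
    np.fill_diagonal(d, 0.0)
    for i, j, v in zip(edges.df["place_i"], edges.df["place_j"], edges.df["value"]):
        if v > 0:
            d[pos[i], pos[j]] = d[pos[j], pos[i]] = 1.0 / v
    off = d[~np.eye(n, dtype=bool)]
    finite = off[np.isfinite(off)]
    if finite.size == 0:
        raise GeoDataError("no positive PCI pair among retained places")
    sentinel = sentinel_factor * float(finite.max())
    d[np.isnan(d)] = sentinel
    return ids, d


def cluster(
    ids: list[str], dissimilarity: np.ndarray, k_list: list[int]
) -> tuple[Dendrogram, dict[int, RegionAssignment]]:
    """Average-linkage agglomeration with cuts at each requested k.

    Deterministic: among tied closest pairs, the merge whose combined
    member set has the smallest (min id, max id) — ties beyond that
    broken on the full sorted member tuple — is performed first.
    """
    n = len(ids)
    if n != dissimilarity.shape[0] or dissimilarity.shape[0] != dissimilarity.shape[1]:
        raise GeoDataError("dissimilarity shape does not match ids")
    for k in k_list:
        if not 1 <= k <= n:
            raise GeoDataError(f"k={k} out of range [1, {n}]")
    wanted = set(k_list)

    members: dict[int, tuple[str, ...]] = {c: (ids[c],) for c in range(n)}
    sizes = {c: 1 for c in range(n)}
    d = {
        (a, b): float(dissimilarity[a, b])
        for a in range(n)
        for b in range(a + 1, n)
    }
    active = set(range(n))
    merges: list[Merge] = []
    assignments: dict[int, RegionAssignment] = {}

    def snapshot(k: int) -> RegionAssignment:
        comms = sorted(active, key=lambda c: members[c][0])
        labels = {p: lbl for lbl, c in enumerate(comms) for p in members[c]}
        return RegionAssignment(labels=labels, k=k)

    if n in wanted:
        assignments[n] = snapshot(n)

    next_id = n
    while len(active) > 1:
        min_dist = min(d.values())
        candidates = [pair for pair, dist in d.items() if dist == min_dist]

        def tie_key(pair: tuple[int, int]) -> tuple:
            merged = tuple(sorted(members[pair[0]] + members[pair[1]]))
            return (merged[0], merged[-1], merged)

        a, b = min(candidates, key=tie_key)
        dist_ab = d.pop((a, b))
        merged_members = tuple(sorted(members[a] + members[b]))
        merges.append(
            Merge(
                community_a=members[a],
                community_b=members[b],
                linkage_distance=dist_ab,
                new_size=len(merged_members),
            )
        )
        # Lance-Williams update for unweighted average linkage
        new_d = {}
        for c in active:
            if c in (a, b):
                continue
            dac = d.pop((min(a, c), max(a, c)))
            dbc = d.pop((min(b, c), max(b, c)))
            new_d[c] = (sizes[a] * dac + sizes[b] * dbc) / (sizes[a] + sizes[b])
        active -= {a, b}
        members[next_id] = merged_members
        sizes[next_id] = sizes[a] + sizes[b]
        for c, v in new_d.items():
            d[(min(c, next_id), max(c, next_id))] = v
        active.add(next_id)
        next_id += 1
        if len(active) in wanted:
            assignments[len(active)] = snapshot(len(active))

    return Dendrogram(merges=merges), assignments


def regionalize(
    pci_matrix: PCIMatrix | EdgeList, k_list: list[int]
) -> tuple[Dendrogram, dict[int, RegionAssignment]]:
    """Convenience: inverse-PCI dissimilarity then multi-cut clustering."""
    ids, d = pci_to_distance(pci_matrix)
    return cluster(ids, d, k_list)


def assignments_frame(assignments: dict[int, RegionAssignment]) -> pd.DataFrame:
    """Long-format table place_id,k,label for export."""
    rows = []
    for k in sorted(assignments):
        for pid in sorted(assignments[k].labels):
            rows.append({"place_id": pid, "k": k, "label": assignments[k].labels[pid]})
    return pd.DataFrame(rows, columns=["place_id", "k", "label"])
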