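"""Grouping of sparse signal pixels into candidate pattern centers.

The binary mask produced by the adaptive threshold is sparse: a single
diffraction pattern contributes a loose cloud of pixels, and stray noise
contributes isolated ones.  Pixels are grouped patch-wise (25 × 25
windows) by single linkage — any pixel strictly closer than the linkage
distance to a member joins the cluster — isolated pixels are discarded,
and each cluster's integer midpoint (the coordinate-wise mean, rounded
half away from zero) becomes a candidate pattern center.

Patch-wise grouping alone would split a cluster that straddles a window
border, so a cross-patch repair pass re-links border pixels (restoring
full-image single-linkage components) and additionally merges clusters
whose midpoints nearly coincide.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class ClusterConfig:
    """Parameters of the patch-wise clustering stage.

    Attributes
    ----------
    patch
        Side of the square clustering window in px (default 25).
    linkage_dist
        Pixels strictly closer than this (Euclidean) are linked
        (default 3, so diagonal √2 and 2-px gaps link, 3-px gaps don't).
    min_size
        Clusters smaller than this are dropped as isolated noise
        (default 2).
    merge_dist
        Clusters whose midpoints are within this distance are merged —
        they are fragments of one pattern (default 5 px, below the
        ~10 px central footprint of the smallest patterns).
    """

    patch: int = 25
    linkage_dist: float = 3.0
    min_size: int = 2
    merge_dist: float = 5.0

    def __post_init__(self) -> None:
        if self.patch < self.linkage_dist:
            raise ValueError("patch must be >= linkage_dist")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


@dataclass(frozen=True)
class PixelCluster:
    """A group of linked signal pixels and its integer midpoint."""

    members: tuple[tuple[int, int], ...]
    midpoint: tuple[int, int]

    def __len__(self) -> int:
        return len(self.members)


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def _midpoint(coords: np.ndarray) -> tuple[int, int]:
    mean = coords.mean(axis=0)
    return (_round_half_away(float(mean[0])), _round_half_away(float(mean[1])))


def _single_linkage_groups(coords: np.ndarray, linkage_dist: float) -> list[np.ndarray]:
    """Connected components of the strict 'distance < linkage_dist' graph."""
    n = len(coords)
    if n == 1:
        return [np.array([0])]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=linkage_dist, output_type="ndarray")
    if len(pairs):  # query_pairs is <=; the linkage rule is strict <
        d2 = ((coords[pairs[:, 0]] - coords[pairs[:, 1]]) ** 2).sum(axis=1)
        pairs = pairs[d2 < linkage_dist ** 2]
    if len(pairs):
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        n_comp, labels = connected_components(adj, directed=False)
    else:
        n_comp, labels = n, np.arange(n)
    return [np.flatnonzero(labels == k) for k in range(n_comp)]


def _build_cluster(coords: np.ndarray) -> PixelCluster:
    members = tuple(sorted((int(r), int(c)) for r, c in coords))
    return PixelCluster(members=members, midpoint=_midpoint(coords))


def cluster_mask(mask: np.ndarray, cfg: ClusterConfig | None = None) -> list[PixelCluster]:
    """Patch-wise single-linkage clustering of a binary mask.

    Within each non-overlapping ``patch``×``patch`` window, set pixels
    are grouped by strict single linkage.  Clusters split across patch
    borders are repaired by re-linking border pixels across patches and
    by merging midpoints closer than ``merge_dist``; the isolated-pixel
    rule (``min_size``) is applied after the repair so a small cluster
    straddling a border is not lost.
    """
    cfg = cfg or ClusterConfig()
    coords_all = np.argwhere(mask)
    if len(coords_all) == 0:
        return []

    patch_of = (coords_all[:, 0] // cfg.patch) * (10 ** 9) + coords_all[:, 1] // cfg.patch
    by_patch: dict[int, list[int]] = defaultdict(list)
    for i, p in enumerate(patch_of):
        by_patch[int(p)].append(i)

    # provisional clusters per patch (singletons kept until after merging)
    cluster_id = np.full(len(coords_all), -1, dtype=np.int64)
    next_id = 0
    for p, idx in by_patch.items():
        idx = np.asarray(idx)
        for grp in _single_linkage_groups(coords_all[idx], cfg.linkage_dist):
            cluster_id[idx[grp]] = next_id
            next_id += 1

    parent = np.arange(next_id)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    # pass 1: re-link pixels near patch borders across patches (restores
    # the full-image single-linkage components)
    margin = cfg.linkage_dist
    off_r = coords_all[:, 0] % cfg.patch
    off_c = coords_all[:, 1] % cfg.patch
    near_border = (
        (off_r < margin) | (off_r >= cfg.patch - margin)
        | (off_c < margin) | (off_c >= cfg.patch - margin)
    )
    border_idx = np.flatnonzero(near_border)
    if len(border_idx) > 1:
        bc = coords_all[border_idx]
        tree = cKDTree(bc)
        pairs = tree.query_pairs(r=cfg.linkage_dist, output_type="ndarray")
        if len(pairs):
            d2 = ((bc[pairs[:, 0]] - bc[pairs[:, 1]]) ** 2).sum(axis=1)
            pairs = pairs[d2 < cfg.linkage_dist ** 2]
        for a, b in pairs:
            ia, ib = border_idx[a], border_idx[b]
            if patch_of[ia] != patch_of[ib]:
                union(int(cluster_id[ia]), int(cluster_id[ib]))

    # pass 2: merge clusters whose midpoints nearly coincide — they are
    # fragments of one pattern, whether split by a patch border or by a
    # hole in the mask inside one patch
    mids = np.zeros((next_id, 2))
    for cid in range(next_id):
        mids[cid] = coords_all[cluster_id == cid].mean(axis=0)
    mid_int = np.array([[_round_half_away(m[0]), _round_half_away(m[1])] for m in mids])
    if next_id > 1 and cfg.merge_dist > 0:
        tree = cKDTree(mid_int)
        for a, b in tree.query_pairs(r=cfg.merge_dist, output_type="ndarray"):
            union(int(a), int(b))

    merged: dict[int, list[int]] = defaultdict(list)
    for i in range(len(coords_all)):
        merged[find(int(cluster_id[i]))].append(i)

    clusters = []
    for idx in merged.values():
        if len(idx) >= cfg.min_size:
            clusters.append(_build_cluster(coords_all[np.asarray(idx)]))
    clusters.sort(key=lambda c: c.midpoint)
    return clusters


def cluster_mask_oracle(mask: np.ndarray, linkage_dist: float = 3.0,
                        min_size: int = 2) -> list[PixelCluster]:
    """Reference clustering: full-image single linkage, no patches.

    Breadth-first traversal of the strict 'distance < linkage_dist'
    graph over all set pixels; intended for small masks as the
    independent check of :func:`cluster_mask`.
    """
    coords = [tuple(int(v) for v in rc) for rc in np.argwhere(mask)]
    if not coords:
        return []
    d2_max = linkage_dist ** 2
    unvisited = set(range(len(coords)))
    clusters = []
    while unvisited:
        seed = unvisited.pop()
        queue = [seed]
        component = [seed]
        while queue:
            i = queue.pop(0)
            ri, ci = coords[i]
            linked = [j for j in unvisited
                      if (coords[j][0] - ri) ** 2 + (coords[j][1] - ci) ** 2 < d2_max]
            for j in linked:
                unvisited.discard(j)
            queue.extend(linked)
            component.extend(linked)
        if len(component) >= min_size:
            clusters.append(_build_cluster(np.array([coords[i] for i in component])))
    clusters.sort(key=lambda c: c.midpoint)
    return clusters
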