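"""Lesion clustering on the patch grid and caption-bag construction.

Abnormal (non-normal) patch predictions are points on the integer patch
grid; DBSCAN with Euclidean metric groups adjacent abnormal patches into
lesion clusters (eps = 1.5 grid units makes the 8-neighborhood adjacent,
min_samples = 4 suppresses isolated false positives).  Each cluster's
patches form an unordered, size-capped caption bag — the unit a captioning
model describes.

The implementation is classical DBSCAN made deterministic: points are
processed in lexicographic (i, j) scan order, so border points reachable
from two clusters always join the cluster whose core point comes first in
scan order, and cluster ids are canonicalized by each cluster's
lexicographically smallest member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import InputContractError, PnkitError


@dataclass(frozen=True)
class PatchPoint:
    i: int
    j: int
    predicted_class: str
    abnormal: bool = True

    def __post_init__(self):
        if self.i < 0 or self.j < 0:
            raise PnkitError(f"grid indices must be >= 0, got ({self.i},{self.j})")


@dataclass(frozen=True)
class ClusterParams:
    eps: float = 1.5
    min_samples: int = 4

    def __post_init__(self):
        if self.eps <= 0:
            raise PnkitError("eps must be > 0")
        if self.min_samples < 1:
            raise PnkitError("min_samples must be >= 1")


@dataclass
class Cluster:
    id: int
    points: list[PatchPoint]

    @property
    def size(self) -> int:
        return len(self.points)

    def bounding_box(self) -> tuple[int, int, int, int]:
        ii = [p.i for p in self.points]
        jj = [p.j for p in self.points]
        return min(ii), min(jj), max(ii), max(jj)


def dbscan_clusters(
    points: Sequence[PatchPoint],
    params: ClusterParams = ClusterParams(),
    normal_class: str = "c-normal",
) -> tuple[list[Cluster], list[PatchPoint]]:
    """Deterministic DBSCAN over abnormal patch points.

    Core points have at least ``min_samples`` neighbors within ``eps``
    (counting themselves); clusters are the density-reachable sets; points
    neither core nor reachable are noise.  The caller must pre-filter to
    abnormal points — a normal-class point raises ``INPUT_CONTRACT``.
    """
    for p in points:
        if not p.abnormal or p.predicted_class == normal_class:
            raise InputContractError(
                f"normal-class point at ({p.i},{p.j}) supplied to dbscan_clusters",
                point=(p.i, p.j),
            )
    pts = sorted(points, key=lambda p: (p.i, p.j))
    n = len(pts)
    if n == 0:
        return [], []
    coords = np.array([(p.i, p.j) for p in pts], dtype=float)
    tree = cKDTree(coords)
    neighborhoods = [sorted(tree.query_ball_point(coords[k], params.eps)) for k in range(n)]
    core = [len(nb) >= params.min_samples for nb in neighborhoods]

    labels = [-1] * n  # -1 = unassigned/noise
    cluster_id = 0
    for k in range(n):  # canonical scan order
        if labels[k] != -1 or not core[k]:
            continue
        labels[k] = cluster_id
        frontier = [k]
        while frontier:
            q = frontier.pop(0)
            if not core[q]:
                continue
            for nb in neighborhoods[q]:
                if labels[nb] == -1:
                    labels[nb] = cluster_id
                    frontier.append(nb)
        cluster_id += 1

    members: dict[int, list[PatchPoint]] = {}
    noise: list[PatchPoint] = []
    for k, lab in enumerate(labels):
        if lab == -1:
            noise.append(pts[k])
        else:
            members.setdefault(lab, []).append(pts[k])
    # canonical ids: sort clusters by lexicographic smallest member
    ordered = sorted(members.values(), key=lambda ms: (ms[0].i, ms[0].j))
    clusters = [Cluster(id=c, points=ms) for c, ms in enumerate(ordered)]
    return clusters, noise


@dataclass
class CaptionBag:
    cluster_id: int
    patch_ids: list[tuple[int, int]]
    bag_size: int
    seed: int


def build_caption_bags(
    clusters: Sequence[Cluster],
    bag_size: int,
    seed: int = 0,
    pad: bool = False,
) -> list[CaptionBag]:
    """Fixed-size unordered patch bags per cluster.

    Clusters larger than ``bag_size`` are sampled uniformly without
    replacement; smaller clusters are kept whole, or resampled with
    replacement up to ``bag_size`` when ``pad`` (training mode).
    Deterministic under (seed, canonical cluster id).
    """
    if bag_size < 1:
        raise PnkitError("bag_size must be >= 1")
    bags = []
    for cluster in clusters:
        rng = np.random.default_rng([seed & 0x7FFFFFFF, cluster.id])
        ids = [(p.i, p.j) for p in cluster.points]
        if len(ids) > bag_size:
            take = rng.choice(len(ids), size=bag_size, replace=False)
            chosen = [ids[k] for k in sorted(take)]
        elif pad and len(ids) < bag_size:
            extra = rng.choice(len(ids), size=bag_size - len(ids), replace=True)
            chosen = ids + [ids[k] for k in extra]
        else:
            chosen = list(ids)
        bags.append(CaptionBag(cluster.id, chosen, bag_size, seed))
    return bags


@dataclass
class ClusterSummary:
    count: int
    sizes: list[int]
    total_points: int
    bounding_boxes: list[tuple[int, int, int, int]]


def cluster_summary(clusters: Sequence[Cluster]) -> ClusterSummary:
    sizes = [c.size for c in clusters]
    return ClusterSummary(
        count=len(clusters),
        sizes=sizes,
        total_points=sum(sizes),
        bounding_boxes=[c.bounding_box() for c in clusters],
    )
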