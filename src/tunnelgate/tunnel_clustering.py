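"""Group per-frame tunnels into clusters and merge them into superclusters.

Two stages mirror the ensemble analysis of tunnel networks:

1. *Within-trajectory* clustering groups the tunnels of one replicate by
   geometric similarity (average-linkage agglomerative clustering cut at
   ``within_threshold``) and discards rare clusters (observed in no more
   than ``min_occurrence_fraction`` of the frames).
2. *Supercluster merging* unifies the surviving clusters of all replicates
   and conditions (Ward linkage on representative spines, cut at
   ``merge_cutoff``), after excluding individual tunnels below the minimum
   bottleneck radius or length, and assembles per-replicate bottleneck
   time series.

The tunnel-to-tunnel metric resamples both spines to a fixed number of
points equidistant in arc length and averages the point-wise Euclidean
distances under that correspondence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dynamics_stats import BottleneckSeries
from .tunnel_detection import TunnelProfile

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterParams",
    "TunnelCluster",
    "ReplicateClusters",
    "SuperCluster",
    "resample_spine",
    "tunnel_distance",
    "cluster_within_trajectory",
    "filter_rare",
    "merge_superclusters",
    "superclusters_to_table",
]


@dataclass(frozen=True)
class ClusterParams:
    """Clustering thresholds (Angstrom unless noted)."""

    within_threshold: float = 4.5
    min_occurrence_fraction: float = 0.05
    merge_cutoff: float = 1.0
    min_tunnel_radius: float = 0.7
    min_tunnel_length: float = 5.0
    spine_samples: int = 20
    within_linkage: str = "average"
    merge_linkage: str = "ward"

    def __post_init__(self) -> None:
        if min(self.within_threshold, self.merge_cutoff, self.min_tunnel_radius,
               self.min_tunnel_length) <= 0:
            raise ValueError("all length thresholds must be positive")
        if not 0 <= self.min_occurrence_fraction <= 1:
            raise ValueError("min_occurrence_fraction must be in [0, 1]")
        if self.spine_samples < 2:
            raise ValueError("spine_samples must be >= 2")


@dataclass
class TunnelCluster:
    """A within-trajectory tunnel cluster (cluster id = CID)."""

    cluster_id: int
    members: dict[int, TunnelProfile]  # frame_index -> cheapest member tunnel
    n_frames: int
    representative: TunnelProfile

    @property
    def occurrence_fraction(self) -> float:
        return len(self.members) / self.n_frames


@dataclass
class ReplicateClusters:
    """Clusters of one replicate trajectory plus ensemble metadata."""

    replicate_id: str
    condition: str
    n_frames: int
    frame_spacing: float
    clusters: list[TunnelCluster]


@dataclass
class SuperCluster:
    """A tunnel branch identity merged across replicates and conditions."""

    supercluster_id: int
    members: list[tuple[str, str, int]]  # (condition, replicate_id, cluster_id)
    series: dict[tuple[str, str], BottleneckSeries]  # (condition, replicate_id)
    total_tunnels: int = 0

    def conditions(self) -> set[str]:
        return {cond for cond, _, _ in self.members}


# --------------------------------------------------------------------------
# Spine metric
# --------------------------------------------------------------------------

def resample_spine(
    centers: np.ndarray, n_samples: int, radii: np.ndarray | None = None
):
    """Resample a polyline (and optionally its radii) equidistantly in arc length."""
    centers = np.asarray(centers, dtype=float)
    seg = np.linalg.norm(np.diff(centers, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("degenerate zero-length spine")
    t = np.linspace(0.0, s[-1], n_samples)
    pts = np.column_stack([np.interp(t, s, centers[:, d]) for d in range(3)])
    if radii is None:
        return pts
    return pts, np.interp(t, s, np.asarray(radii, dtype=float))


def tunnel_distance(
    a: TunnelProfile, b: TunnelProfile, spine_samples: int = 20
) -> float:
    """Mean point-wise distance between arc-length-resampled spines (A)."""
    pa = resample_spine(a.centers, spine_samples)
    pb = resample_spine(b.centers, spine_samples)
    return float(np.mean(np.linalg.norm(pa - pb, axis=1)))


def _resampled_stack(profiles: Sequence[TunnelProfile], m: int) -> np.ndarray:
    return np.stack([resample_spine(p.centers, m) for p in profiles])


def _pairwise_condensed(points: np.ndarray) -> np.ndarray:
    """Condensed matrix of mean point-wise distances for (n, m, 3) spines."""
    n = len(points)
    dm = np.zeros((n, n))
    for k in range(points.shape[1]):
        diff = points[:, k, None, :] - points[None, :, k, :]
        dm += np.sqrt((diff * diff).sum(axis=-1))
    dm /= points.shape[1]
    np.fill_diagonal(dm, 0.0)
    return squareform(dm, checks=False)


# --------------------------------------------------------------------------
# Within-trajectory clustering
# --------------------------------------------------------------------------

def _member_rank(tp: TunnelProfile) -> tuple:
    # cheapest first; tunnel ids were assigned by ascending cost when the
    # cost itself is unavailable (profiles read back from a table)
    return (
        tp.cost if tp.cost is not None else np.inf,
        tp.tunnel_id if tp.tunnel_id is not None else 0,
    )


def _canonical_order(tunnels: Sequence[TunnelProfile]) -> list[TunnelProfile]:
    return sorted(
        tunnels,
        key=lambda tp: (
            tp.frame_index if tp.frame_index is not None else -1,
            _member_rank(tp),
            tuple(tp.centers[0]),
            tuple(tp.centers[-1]),
        ),
    )


def _representative(members: Sequence[TunnelProfile], m: int) -> TunnelProfile:
    pts, rads = zip(
        *(resample_spine(p.centers, m, p.radii) for p in members)
    )
    return TunnelProfile(
        centers=np.mean(pts, axis=0), radii=np.mean(rads, axis=0)
    )


def cluster_within_trajectory(
    tunnels: Sequence[TunnelProfile],
    n_frames: int,
    params: ClusterParams = ClusterParams(),
) -> list[TunnelCluster]:
    """Cluster one replicate's tunnels; cluster ids by descending occurrence.

    Per cluster and frame only the cheapest member is kept.  The result is
    invariant under permutation of the input order (a canonical sort is
    applied first).
    """
    if not tunnels:
        raise ValueError("at least one tunnel is required")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    ordered = _canonical_order(tunnels)
    if len(ordered) == 1:
        labels = np.array([1])
    else:
        cond = _pairwise_condensed(
            _resampled_stack(ordered, params.spine_samples)
        )
        z = linkage(cond, method=params.within_linkage)
        labels = fcluster(z, t=params.within_threshold, criterion="distance")

    groups: dict[int, list[TunnelProfile]] = {}
    for lab, tp in zip(labels, ordered):
        groups.setdefault(int(lab), []).append(tp)

    clusters = []
    for members in groups.values():
        per_frame: dict[int, TunnelProfile] = {}
        for tp in members:
            f = tp.frame_index if tp.frame_index is not None else 0
            if f not in per_frame or _member_rank(tp) < _member_rank(per_frame[f]):
                per_frame[f] = tp
        clusters.append((per_frame, members))

    # ids by descending occurrence; ties by earliest frame, then exit point
    def sort_key(item):
        per_frame, _ = item
        return (-len(per_frame), min(per_frame), tuple(per_frame[min(per_frame)].centers[-1]))

    out = []
    for cid, (per_frame, members) in enumerate(sorted(clusters, key=sort_key), start=1):
        out.append(
            TunnelCluster(
                cluster_id=cid,
                members=per_frame,
                n_frames=n_frames,
                representative=_representative(
                    list(per_frame.values()), params.spine_samples
                ),
            )
        )
    return out


def filter_rare(
    clusters: Sequence[TunnelCluster],
    n_frames: int,
    params: ClusterParams = ClusterParams(),
) -> list[TunnelCluster]:
    """Keep clusters observed in strictly more than the occurrence cutoff."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    return [
        c
        for c in clusters
        if len(c.members) / n_frames > params.min_occurrence_fraction
    ]


# --------------------------------------------------------------------------
# Supercluster merging
# --------------------------------------------------------------------------

def merge_superclusters(
    replicates: Sequence[ReplicateClusters],
    params: ClusterParams = ClusterParams(),
) -> list[SuperCluster]:
    """Merge per-replicate clusters across ensembles into superclusters.

    Tunnels with bottleneck radius below ``min_tunnel_radius`` or length
    below ``min_tunnel_length`` are excluded before the merge; clusters
    losing all members drop out.  Ward linkage on representative-spine
    distances is cut at ``merge_cutoff``; supercluster ids are assigned by
    descending total retained tunnel count.
    """
    if not replicates:
        raise ValueError("at least one replicate is required")

    entries = []  # (condition, replicate_id, cluster_id, retained members, rep spine)
    for rc in replicates:
        for cl in rc.clusters:
            retained = {
                f: tp
                for f, tp in cl.members.items()
                if tp.bottleneck_radius >= params.min_tunnel_radius
                and tp.length >= params.min_tunnel_length
            }
            if not retained:
                continue
            entries.append(
                (
                    rc,
                    cl.cluster_id,
                    retained,
                    _representative(list(retained.values()), params.spine_samples),
                )
            )
    if not entries:
        logger.warning("all tunnels were filtered out before the merge")
        return []

    entries.sort(
        key=lambda e: (e[0].condition, e[0].replicate_id, e[1])
    )
    reps = [e[3] for e in entries]
    if len(entries) == 1:
        labels = np.array([1])
    else:
        cond = _pairwise_condensed(
            np.stack([r.centers for r in reps])
        )
        z = linkage(cond, method=params.merge_linkage)
        labels = fcluster(z, t=params.merge_cutoff, criterion="distance")

    groups: dict[int, list] = {}
    for lab, entry in zip(labels, entries):
        groups.setdefault(int(lab), []).append(entry)

    def total_tunnels(group) -> int:
        return sum(len(retained) for _, _, retained, _ in group)

    ordered_groups = sorted(
        groups.values(),
        key=lambda g: (
            -total_tunnels(g),
            g[0][0].condition,
            g[0][0].replicate_id,
            g[0][1],
        ),
    )

    out = []
    for sc_id, group in enumerate(ordered_groups, start=1):
        members = []
        series: dict[tuple[str, str], BottleneckSeries] = {}
        ranks: dict[tuple[str, str, int], tuple] = {}
        for rc, cid, retained, _ in group:
            members.append((rc.condition, rc.replicate_id, cid))
            key = (rc.condition, rc.replicate_id)
            if key not in series:
                series[key] = BottleneckSeries(
                    supercluster_id=sc_id,
                    replicate_id=rc.replicate_id,
                    condition=rc.condition,
                    frame_spacing=rc.frame_spacing,
                    values=np.full(rc.n_frames, np.nan),
                    lengths=np.full(rc.n_frames, np.nan),
                )
            bs = series[key]
            for f, tp in retained.items():
                # cheapest wins when several clusters of one replicate
                # contribute to the same supercluster and frame
                rkey = (*key, f)
                rank = _member_rank(tp)
                if np.isnan(bs.values[f]) or rank < ranks[rkey]:
                    bs.values[f] = tp.bottleneck_radius
                    bs.lengths[f] = tp.length
                    ranks[rkey] = rank
        out.append(
            SuperCluster(
                supercluster_id=sc_id,
                members=members,
                series=series,
                total_tunnels=total_tunnels(group),
            )
        )
    return out


def superclusters_to_table(superclusters: Sequence[SuperCluster]) -> pd.DataFrame:
    """Long-form supercluster table: one row per detected (frame, replicate)."""
    rows = []
    for sc in superclusters:
        for (cond, rep), bs in sorted(sc.series.items()):
            present = np.flatnonzero(~np.isnan(bs.values))
            for f in present:
                rows.append(
                    (
                        sc.supercluster_id,
                        cond,
                        rep,
                        int(f),
                        bs.values[f],
                        bs.lengths[f],
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "supercluster_id",
            "condition",
            "replicate_id",
            "frame_index",
            "bottleneck_radius",
            "length",
        ],
    )
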