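"""Per-snapshot geometric tunnel search from a buried start point to bulk.

The search runs on a regular grid over the snapshot's bounding box.  Every
voxel carries its *free radius* (distance to the nearest atom surface); the
bulk solvent region is the flood fill of voxels whose free radius admits the
shell probe, and the volume swept by that probe (all points within
``shell_radius`` of a bulk voxel) marks the outside of the molecular
surface.  Tunnels are cheapest paths from the start point to the surface
over voxels admitting the probe, with the CAVER-style edge cost
``step_length * free_radius**(-cost_exponent)`` that prefers wide
pathways.  Paths are trimmed back from the surface by ``shell_depth`` of
arc length and reported as spines of spheres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_formats import PROFILE_COLUMNS, Snapshot

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionParams",
    "StartPointSpec",
    "TunnelProfile",
    "ScalarField",
    "compute_start_point",
    "free_radius_field",
    "classify_bulk",
    "outside_region",
    "grid_shortest_paths",
    "find_tunnels",
    "profile_geometry",
    "detect_ensemble",
    "profiles_to_table",
    "profiles_from_table",
]


@dataclass(frozen=True)
class DetectionParams:
    """Geometric search parameters.

    probe_radius
        Minimum free radius (A) a voxel must have to be traversable.
    shell_radius, shell_depth
        Shell-probe radius defining bulk solvent, and the arc length (A)
        trimmed from the bulk end of each tunnel.
    grid_spacing
        Voxel edge length (A); bottleneck radii are accurate to about one
        spacing.
    cost_exponent
        Exponent of the inverse free radius in the edge cost.
    duplicate_threshold
        Exit points closer than this (A) to a cheaper tunnel's exit are
        considered the same tunnel and suppressed.
    """

    probe_radius: float = 0.7
    shell_radius: float = 3.0
    shell_depth: float = 4.0
    grid_spacing: float = 0.5
    cost_exponent: float = 2.0
    duplicate_threshold: float = 4.5

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.shell_radius <= self.probe_radius:
            raise ValueError("shell_radius must exceed probe_radius")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.cost_exponent <= 0:
            raise ValueError("cost_exponent must be positive")


@dataclass(frozen=True)
class StartPointSpec:
    """Residues whose mass-weighted centroid defines the search start."""

    residues: tuple[tuple[str, int], ...]
    heavy_atoms_only: bool = True

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("at least one residue must be specified")


@dataclass
class TunnelProfile:
    """A tunnel as an ordered spine of spheres from start point to exit."""

    centers: np.ndarray  # (n, 3) A
    radii: np.ndarray  # (n,) A
    cost: float | None = None
    frame_index: int | None = None
    tunnel_id: int | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[1] != 3:
            raise ValueError("centers must be an (n, 3) array")
        if len(self.radii) != len(self.centers):
            raise ValueError("one radius per spine sphere required")

    @property
    def bottleneck_radius(self) -> float:
        return float(np.min(self.radii))

    @property
    def length(self) -> float:
        return float(
            np.sum(np.linalg.norm(np.diff(self.centers, axis=0), axis=1))
        )

    @property
    def exit_point(self) -> np.ndarray:
        return self.centers[-1]


@dataclass
class ScalarField:
    """A scalar quantity sampled at voxel centers of a regular grid."""

    values: np.ndarray  # (nx, ny, nz)
    origin: np.ndarray  # (3,) center of voxel (0,0,0)
    spacing: float

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing * np.arange(self.values.shape[axis])

    def index_of(self, point: np.ndarray) -> tuple[int, int, int]:
        """Index of the voxel whose center is nearest to ``point``."""
        idx = np.rint((np.asarray(point, float) - self.origin) / self.spacing)
        idx = np.clip(idx, 0, np.array(self.values.shape) - 1).astype(int)
        return tuple(idx)

    def center_of(self, index: Sequence[int]) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(index, dtype=float)


def compute_start_point(snapshot: Snapshot, spec: StartPointSpec) -> np.ndarray:
    """Mass-weighted centroid of the atoms of the requested residues."""
    positions = []
    masses = []
    for res_name, res_id in spec.residues:
        sel = [
            a
            for a in snapshot.atoms
            if a.residue_id == res_id and a.residue_name.upper() == res_name.upper()
        ]
        if spec.heavy_atoms_only:
            sel = [a for a in sel if not a.name.strip().lstrip("0123456789").upper().startswith("H")]
        if not sel:
            raise ValueError(f"residue {res_name}:{res_id} not found in snapshot")
        positions.extend(a.position for a in sel)
        masses.extend(a.mass for a in sel)
    pos = np.asarray(positions)
    m = np.asarray(masses)
    return (pos * m[:, None]).sum(axis=0) / m.sum()


def free_radius_field(
    snapshot: Snapshot,
    spacing: float = 0.5,
    margin: float | None = None,
    cap: float | None = None,
) -> ScalarField:
    """Exact free-radius field over the snapshot's padded bounding box.

    The value at a voxel center v is ``min over atoms a of
    (|v - a.position| - a.vdw_radius)``; negative inside atoms.  The
    default margin guarantees that box-boundary voxels are bulk for the
    default shell radius.

    With ``cap`` set, values above it are clamped to exactly ``cap``;
    values below are still exact.  Detection uses ``cap = shell_radius``:
    the bulk predicate and every traversable voxel's radius are unchanged,
    while the nearest-atom queries prune far voxels much faster.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if len(snapshot) == 0:
        raise ValueError("cannot compute a free-radius field for an empty snapshot")
    pos = snapshot.positions
    radii = snapshot.vdw_radii
    if margin is None:
        margin = float(radii.max()) + 3.0 + 2.0 * spacing
    lo = pos.min(axis=0) - margin
    hi = pos.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1

    if cap is not None:
        # exact below the cap: every atom scatter-min-updates all voxels
        # within cap + vdw_radius of itself; untouched voxels are provably
        # above the cap
        r_max = float(radii.max())
        k = int(np.ceil((cap + r_max) / spacing + np.sqrt(3.0) / 2.0))
        rng = np.arange(-k, k + 1)
        off = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
        reach = np.linalg.norm(off, axis=1) * spacing
        off = off[reach <= cap + r_max + spacing * np.sqrt(3.0) / 2.0]
        values = _capped_field_kernel(
            np.ascontiguousarray(pos),
            np.ascontiguousarray(radii),
            lo,
            int(shape[0]),
            int(shape[1]),
            int(shape[2]),
            spacing,
            float(cap),
            np.ascontiguousarray(off.astype(np.int64)),
        )
        return ScalarField(values, origin=lo, spacing=spacing)

    axes = [lo[d] + spacing * np.arange(shape[d]) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    values = np.full(len(grid), np.inf)
    # One KD-tree per distinct vdW radius keeps the minimum exact: within a
    # radius class the nearest atom minimizes |v - a| - r.
    for r in np.unique(radii):
        tree = cKDTree(pos[radii == r])
        d, _ = tree.query(grid, k=1)
        np.minimum(values, d - r, out=values)
    return ScalarField(values.reshape(tuple(shape)), origin=lo, spacing=spacing)


@njit(cache=True)
def _capped_field_kernel(
    pos, radii, lo, nx, ny, nz, spacing, cap, offsets
):  # pragma: no cover - exercised through free_radius_field
    values = np.full((nx, ny, nz), cap)
    for a in range(pos.shape[0]):
        bi = int(round((pos[a, 0] - lo[0]) / spacing))
        bj = int(round((pos[a, 1] - lo[1]) / spacing))
        bk = int(round((pos[a, 2] - lo[2]) / spacing))
        r = radii[a]
        for m in range(offsets.shape[0]):
            i = bi + offsets[m, 0]
            if i < 0 or i >= nx:
                continue
            j = bj + offsets[m, 1]
            if j < 0 or j >= ny:
                continue
            k = bk + offsets[m, 2]
            if k < 0 or k >= nz:
                continue
            dx = lo[0] + i * spacing - pos[a, 0]
            dy = lo[1] + j * spacing - pos[a, 1]
            dz = lo[2] + k * spacing - pos[a, 2]
            v = np.sqrt(dx * dx + dy * dy + dz * dz) - r
            if v < values[i, j, k]:
                values[i, j, k] = v
    return values


def classify_bulk(field: ScalarField, params: DetectionParams) -> np.ndarray:
    """Label voxels as bulk solvent (True) or interior (False).

    Bulk = voxels with free radius >= shell_radius that are connected to
    the grid boundary; wide internal voids stay interior.
    """
    candidate = field.values >= params.shell_radius
    labels, n = ndimage.label(candidate, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(candidate, dtype=bool)
    boundary_labels = np.unique(
        np.concatenate(
            [
                labels[0, :, :].ravel(),
                labels[-1, :, :].ravel(),
                labels[:, 0, :].ravel(),
                labels[:, -1, :].ravel(),
                labels[:, :, 0].ravel(),
                labels[:, :, -1].ravel(),
            ]
        )
    )
    boundary_labels = boundary_labels[boundary_labels > 0]
    return np.isin(labels, boundary_labels)


def outside_region(
    field: ScalarField, bulk: np.ndarray, shell_radius: float
) -> np.ndarray:
    """Volume swept by the shell probe: voxels within shell_radius of bulk.

    This is the outside of the molecular surface as seen by a spherical
    probe of ``shell_radius``; tunnels terminate on reaching it.
    """
    if not bulk.any():
        return bulk.copy()
    dist = ndimage.distance_transform_edt(
        ~bulk, sampling=(field.spacing,) * 3
    )
    return dist <= shell_radius + 1e-9


@njit(cache=True)
def _dijkstra_kernel(field, trav, si, sj, sk, spacing, cexp):  # pragma: no cover
    nx, ny, nz = field.shape
    n = nx * ny * nz
    dist = np.full(n, np.inf)
    pred = np.full(n, -1, np.int64)
    done = np.zeros(n, np.uint8)

    cap = 1 << 12
    hd = np.empty(cap)
    hn = np.empty(cap, np.int64)
    size = 0

    start = (si * ny + sj) * nz + sk
    dist[start] = 0.0
    hd[0] = 0.0
    hn[0] = start
    size = 1

    while size > 0:
        # pop min (dist, node); node index breaks ties for determinism
        d0 = hd[0]
        u = hn[0]
        size -= 1
        hd[0] = hd[size]
        hn[0] = hn[size]
        i = 0
        while True:
            l = 2 * i + 1
            r = l + 1
            small = i
            if l < size and (
                hd[l] < hd[small] or (hd[l] == hd[small] and hn[l] < hn[small])
            ):
                small = l
            if r < size and (
                hd[r] < hd[small] or (hd[r] == hd[small] and hn[r] < hn[small])
            ):
                small = r
            if small == i:
                break
            hd[i], hd[small] = hd[small], hd[i]
            hn[i], hn[small] = hn[small], hn[i]
            i = small
        if done[u]:
            continue
        done[u] = 1
        ui = u // (ny * nz)
        uj = (u // nz) % ny
        uk = u % nz
        for di in range(-1, 2):
            vi = ui + di
            if vi < 0 or vi >= nx:
                continue
            for dj in range(-1, 2):
                vj = uj + dj
                if vj < 0 or vj >= ny:
                    continue
                for dk in range(-1, 2):
                    if di == 0 and dj == 0 and dk == 0:
                        continue
                    vk = uk + dk
                    if vk < 0 or vk >= nz:
                        continue
                    v = (vi * ny + vj) * nz + vk
                    if done[v] or not trav[v]:
                        continue
                    step = spacing * np.sqrt(
                        float(di * di + dj * dj + dk * dk)
                    )
                    w = step * field[vi, vj, vk] ** (-cexp)
                    nd = d0 + w
                    better = nd < dist[v] or (
                        nd == dist[v] and u < pred[v]
                    )
                    if better:
                        dist[v] = nd
                        pred[v] = u
                        if size >= cap:
                            new_hd = np.empty(cap * 2)
                            new_hn = np.empty(cap * 2, np.int64)
                            new_hd[:cap] = hd
                            new_hn[:cap] = hn
                            hd = new_hd
                            hn = new_hn
                            cap *= 2
                        # push with sift-up
                        hd[size] = nd
                        hn[size] = v
                        c = size
                        size += 1
                        while c > 0:
                            p = (c - 1) // 2
                            if hd[c] < hd[p] or (
                                hd[c] == hd[p] and hn[c] < hn[p]
                            ):
                                hd[c], hd[p] = hd[p], hd[c]
                                hn[c], hn[p] = hn[p], hn[c]
                                c = p
                            else:
                                break
    return dist, pred


def grid_shortest_paths(
    field: ScalarField,
    traversable: np.ndarray,
    start_index: tuple[int, int, int],
    cost_exponent: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-source Dijkstra over the 26-connected voxel graph.

    Edge weight from u to v is ``|center_v - center_u| *
    free_radius(v)**(-cost_exponent)``.  Returns flat arrays of path costs
    and predecessor voxel indices (-1 where unreached); ties are broken by
    lexicographic voxel index so the result is deterministic.
    """
    si, sj, sk = start_index
    if not traversable[si, sj, sk]:
        raise ValueError("start voxel is not traversable")
    dist, pred = _dijkstra_kernel(
        field.values,
        np.ascontiguousarray(traversable.ravel()),
        si,
        sj,
        sk,
        field.spacing,
        cost_exponent,
    )
    return dist, pred


def _snap_start(
    field: ScalarField, start: np.ndarray, probe: float, max_snap: float = 3.0
) -> tuple[int, int, int]:
    idx = field.index_of(start)
    if field.values[idx] >= probe:
        return idx
    r = int(np.ceil(max_snap / field.spacing))
    shape = field.values.shape
    best = None
    best_d = np.inf
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            for dk in range(-r, r + 1):
                cand = (idx[0] + di, idx[1] + dj, idx[2] + dk)
                if any(c < 0 or c >= s for c, s in zip(cand, shape)):
                    continue
                if field.values[cand] < probe:
                    continue
                d = np.linalg.norm(field.center_of(cand) - start)
                if d <= max_snap and (d < best_d or (d == best_d and cand < best)):
                    best, best_d = cand, d
    if best is None:
        raise ValueError(
            f"start point {start} has free radius below the probe radius and "
            f"no admissible voxel within {max_snap} A"
        )
    logger.warning(
        "start point free radius below probe; snapped %.2f A to voxel %s",
        best_d,
        best,
    )
    return best


def find_tunnels(
    snapshot: Snapshot,
    start: np.ndarray,
    params: DetectionParams = DetectionParams(),
    field: ScalarField | None = None,
    bulk: np.ndarray | None = None,
) -> list[TunnelProfile]:
    """Detect tunnels from ``start`` to bulk solvent in one snapshot.

    Returns profiles sorted by ascending path cost; an unreachable bulk
    yields an empty list.  ``field`` and ``bulk`` may be supplied if
    already computed at ``params.grid_spacing``.
    """
    if field is None:
        max_r = float(snapshot.vdw_radii.max())
        field = free_radius_field(
            snapshot,
            spacing=params.grid_spacing,
            margin=max_r + params.shell_radius + params.grid_spacing,
            cap=params.shell_radius,
        )
    if bulk is None:
        bulk = classify_bulk(field, params)
    outside = outside_region(field, bulk, params.shell_radius)

    start = np.asarray(start, dtype=float)
    start_idx = _snap_start(field, start, params.probe_radius)
    if bulk[start_idx] or outside[start_idx]:
        raise ValueError("start point not buried")

    traversable = (field.values >= params.probe_radius) & ~outside
    traversable[start_idx] = True
    dist, pred = grid_shortest_paths(
        field, traversable, start_idx, params.cost_exponent
    )

    shape = field.values.shape
    ny, nz = shape[1], shape[2]
    # exit candidates: reached traversable voxels with an outside neighbor
    struct = np.ones((3, 3, 3), dtype=bool)
    near_outside = ndimage.binary_dilation(outside, structure=struct)
    exit_mask = traversable & near_outside & np.isfinite(
        dist.reshape(shape)
    )
    exit_flat = np.flatnonzero(exit_mask.ravel())
    if exit_flat.size == 0:
        return []
    order = np.lexsort((exit_flat, dist[exit_flat]))
    exit_flat = exit_flat[order]

    accepted: list[TunnelProfile] = []
    accepted_exits: list[np.ndarray] = []
    for f in exit_flat:
        ijk = np.array([f // (ny * nz), (f // nz) % ny, f % nz])
        center = field.center_of(ijk)
        if any(
            np.linalg.norm(center - e) < params.duplicate_threshold
            for e in accepted_exits
        ):
            continue
        profile = _path_to_profile(field, dist, pred, int(f), params)
        if profile is None:
            continue
        accepted_exits.append(center)
        profile.tunnel_id = len(accepted)
        accepted.append(profile)
    return accepted


def _path_to_profile(
    field: ScalarField,
    dist: np.ndarray,
    pred: np.ndarray,
    exit_flat: int,
    params: DetectionParams,
) -> TunnelProfile | None:
    shape = field.values.shape
    ny, nz = shape[1], shape[2]
    chain = []
    node = exit_flat
    while node != -1:
        chain.append(node)
        node = int(pred[node])
    chain.reverse()  # start -> exit
    if len(chain) < 2:
        return None
    idx = np.array(
        [[c // (ny * nz), (c // nz) % ny, c % nz] for c in chain]
    )
    centers = field.origin + field.spacing * idx.astype(float)
    radii = field.values[idx[:, 0], idx[:, 1], idx[:, 2]]

    # trim shell_depth of arc length from the bulk end
    seg = np.linalg.norm(np.diff(centers, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    keep = s <= s[-1] - params.shell_depth
    n_keep = max(int(keep.sum()), 2)
    centers = centers[:n_keep]
    radii = radii[:n_keep]
    return TunnelProfile(
        centers=centers, radii=radii, cost=float(dist[exit_flat])
    )


def profile_geometry(profile: TunnelProfile) -> tuple[float, float]:
    """Return (bottleneck radius, spine length) of a tunnel profile."""
    if len(profile.radii) < 2:
        raise ValueError("a tunnel spine needs at least 2 spheres")
    return profile.bottleneck_radius, profile.length


def detect_ensemble(
    ensemble,
    start: np.ndarray | StartPointSpec,
    params: DetectionParams = DetectionParams(),
    batch_size: int | None = None,
) -> list[TunnelProfile]:
    """Run tunnel detection on every snapshot of an ensemble.

    ``start`` is either a fixed point or a :class:`StartPointSpec`
    evaluated per frame.  ``batch_size`` processes frames in batches (a
    memory-management device); the concatenated result is identical to
    unbatched processing.  Returns a flat list of profiles with
    ``frame_index`` set, ordered by frame then ascending cost.
    """
    if batch_size is not None and batch_size < 1:
        raise ValueError("batch_size must be positive")
    snapshots = list(ensemble)
    n = len(snapshots)
    bs = n if batch_size is None else batch_size
    out: list[TunnelProfile] = []
    for lo in range(0, n, bs):
        for snap in snapshots[lo : lo + bs]:
            pt = (
                compute_start_point(snap, start)
                if isinstance(start, StartPointSpec)
                else np.asarray(start, dtype=float)
            )
            for tp in find_tunnels(snap, pt, params):
                tp.frame_index = snap.frame_index
                out.append(tp)
    return out


def profiles_to_table(
    profiles: Sequence[TunnelProfile], replicate_id: str
) -> pd.DataFrame:
    """Serialize profiles to the CAVER-style per-sphere profile table."""
    rows = []
    for tp in profiles:
        if tp.frame_index is None or tp.tunnel_id is None:
            raise ValueError("profiles need frame_index and tunnel_id for serialization")
        for k, (c, r) in enumerate(zip(tp.centers, tp.radii)):
            rows.append(
                (replicate_id, tp.frame_index, tp.tunnel_id, k, c[0], c[1], c[2], r)
            )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def profiles_from_table(table) -> dict[str, list[TunnelProfile]]:
    """Rebuild per-replicate profile lists from a profile table.

    Costs are not stored in the table; within-frame tunnel ids were
    assigned by ascending cost, so they preserve the cheapest-first order.
    """
    out: dict[str, list[TunnelProfile]] = {}
    for (rep, frame, tid), grp in table.groupby(
        ["replicate_id", "frame_index", "tunnel_id"], sort=True
    ):
        grp = grp.sort_values("sphere_index")
        tp = TunnelProfile(
            centers=grp[["x", "y", "z"]].to_numpy(),
            radii=grp["radius"].to_numpy(),
            frame_index=int(frame),
            tunnel_id=int(tid),
        )
        out.setdefault(str(rep), []).append(tp)
    return out
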