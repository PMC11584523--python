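"""Toy structures with gated channels and known ground-truth kinetics.

The generator emulates the statistical structure of an MD tunnel-analysis
study without any molecular physics: a spherical shell of pseudo-atoms
encloses a cavity, straight channels of configurable free radius pierce the
shell, and a ring of *gate* atoms near the inner end of each channel is
displaced radially frame by frame so the channel's minimal free radius
follows a two-state (open/closed) continuous-time Markov process observed
at fixed frame spacing with Gaussian radius noise.

The continuous-time simulation keeps the dwell-time laws exactly
exponential; sampling at the frame spacing then aliases sub-frame
excursions exactly as finite trajectory output does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ATOMIC_MASSES, Atom, Ensemble, Snapshot

__all__ = [
    "Channel",
    "ToyStructureSpec",
    "GatingModel",
    "GroundTruth",
    "ChannelOverlapError",
    "build_toy_structure",
    "simulate_gating",
    "realize_trajectory",
    "generate_study_series",
    "generate_study_ensemble",
    "StudyData",
    "write_ground_truth",
]


class ChannelOverlapError(ValueError):
    """Two channel cylinders intersect within the shell."""


@dataclass(frozen=True)
class Channel:
    """A straight channel through the shell along ``axis`` (unit vector)."""

    axis: tuple[float, float, float]
    free_radius: float

    def unit(self) -> np.ndarray:
        u = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(u)
        if n == 0:
            raise ValueError("channel axis must be a nonzero vector")
        return u / n


@dataclass(frozen=True)
class ToyStructureSpec:
    """Geometry of the toy shell structure (all lengths in Angstrom)."""

    shell_outer_radius: float = 18.0
    shell_thickness: float = 12.0
    cavity_radius: float = 6.0
    lattice_spacing: float = 1.2
    pseudo_atom_radius: float = 1.7
    channels: tuple[Channel, ...] = ()
    gate_depth: float = 1.0  # axial distance of the gate ring beyond the cavity

    def __post_init__(self) -> None:
        if self.cavity_radius + self.shell_thickness > self.shell_outer_radius + 1e-9:
            raise ValueError("cavity_radius + shell_thickness must be <= shell_outer_radius")
        if self.lattice_spacing > self.pseudo_atom_radius:
            raise ValueError(
                "lattice_spacing must not exceed pseudo_atom_radius "
                "(the shell would not be probe-tight)"
            )
        if any(c.free_radius < 0 for c in self.channels):
            raise ValueError("channel free_radius must be non-negative")

    @property
    def shell_inner_radius(self) -> float:
        return self.cavity_radius

    @property
    def shell_outer_extent(self) -> float:
        return self.cavity_radius + self.shell_thickness


@dataclass(frozen=True)
class GatingModel:
    """Two-state Markov gating of a channel bottleneck.

    Rates are in 1/ns; ``r_open``/``r_closed`` are the bottleneck radii of
    the two states and ``noise_sd`` the Gaussian observation noise on the
    radius (truncated at zero).
    """

    k_open: float  # closed -> open rate, 1/ns
    k_close: float  # open -> closed rate, 1/ns
    r_open: float = 1.6
    r_closed: float = 0.2
    noise_sd: float = 0.05  # kept <= r_closed/3 so zero-truncation bias is negligible
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_open < 0 or self.k_close < 0:
            raise ValueError("rates must be non-negative")
        if not (self.r_open > self.r_closed >= 0):
            raise ValueError("need r_open > r_closed >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def stationary_open_fraction(self) -> float:
        total = self.k_open + self.k_close
        if total == 0:
            raise ValueError("stationary distribution undefined for two zero rates")
        return self.k_open / total


@dataclass
class GroundTruth:
    """Latent truth of one simulated channel."""

    true_radius: np.ndarray  # noise-free per-frame radius, A
    state_open: np.ndarray  # bool per frame
    stationary_open_fraction: float
    mean_open_dwell: float  # ns, 1/k_close (inf if k_close == 0)
    open_dwells: np.ndarray  # completed open dwell durations, ns
    closed_dwells: np.ndarray  # completed closed dwell durations, ns


# --------------------------------------------------------------------------
# Structure building
# --------------------------------------------------------------------------

def _build_geometry(spec: ToyStructureSpec):
    """Lattice shell positions plus per-channel gate-ring geometry."""
    outer = spec.shell_outer_extent
    n = int(math.floor(outer / spec.lattice_spacing))
    ax = spec.lattice_spacing * np.arange(-n, n + 1)
    pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    r = np.linalg.norm(pts, axis=1)
    pts = pts[(r >= spec.cavity_radius) & (r <= outer)]

    R = spec.pseudo_atom_radius
    units = [c.unit() for c in spec.channels]
    for (ci, c), (cj, d) in [
        ((i, spec.channels[i]), (j, spec.channels[j]))
        for i in range(len(spec.channels))
        for j in range(i + 1, len(spec.channels))
    ]:
        sep = 2.0 * math.sin(
            0.5 * math.acos(np.clip(np.dot(units[ci], units[cj]), -1, 1))
        ) * spec.cavity_radius
        if sep < c.free_radius + d.free_radius + 2 * R:
            raise ChannelOverlapError(
                f"channels {ci} and {cj} overlap within the shell"
            )

    for c, u in zip(spec.channels, units):
        t = pts @ u
        rho = np.linalg.norm(pts - np.outer(t, u), axis=1)
        carve = (t > 0) & (rho < c.free_radius + R)
        pts = pts[~carve]

    gates = []
    for c, u in zip(spec.channels, units):
        # orthonormal frame perpendicular to the axis
        a = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(a, u)) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(u, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        n_gate = max(8, int(math.ceil(2 * math.pi * (c.free_radius + R) / R)))
        phi = 2 * math.pi * np.arange(n_gate) / n_gate
        dirs = np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2)
        center = (spec.cavity_radius + spec.gate_depth) * u
        gates.append(
            {
                "unit": u,
                "center": center,
                "dirs": dirs,
                "max_radius": c.free_radius,
            }
        )
    return pts, gates


def _gate_positions(gate: dict, free_radius: float, R: float) -> np.ndarray:
    return gate["center"] + (free_radius + R) * gate["dirs"]


def _make_atoms(
    shell_pts: np.ndarray, gate_pts_per_channel: list[np.ndarray], R: float
) -> list[Atom]:
    atoms = []
    serial = 1
    for p in shell_pts:
        atoms.append(
            Atom(serial, "C", "SHL", 1, p, R, ATOMIC_MASSES["C"])
        )
        serial += 1
    for ch, gate_pts in enumerate(gate_pts_per_channel):
        for p in gate_pts:
            atoms.append(
                Atom(serial, "C", "GAT", 2 + ch, p, R, ATOMIC_MASSES["C"])
            )
            serial += 1
    return atoms


def build_toy_structure(spec: ToyStructureSpec) -> Snapshot:
    """Build the toy shell with each channel at its specified free radius.

    The minimal free radius along each channel axis equals the channel's
    ``free_radius`` exactly (a gate ring of pseudo-atoms is placed at that
    radius); the cavity center is at the origin.
    """
    shell_pts, gates = _build_geometry(spec)
    gate_pts = [
        _gate_positions(g, c.free_radius, spec.pseudo_atom_radius)
        for g, c in zip(gates, spec.channels)
    ]
    atoms = _make_atoms(shell_pts, gate_pts, spec.pseudo_atom_radius)
    return Snapshot(frame_index=0, time=0.0, atoms=atoms)


# --------------------------------------------------------------------------
# Gating simulation
# --------------------------------------------------------------------------

def simulate_gating(
    model: GatingModel,
    n_frames: int,
    frame_spacing: float,
    seed: int | None = None,
    initial_state: str | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Simulate two-state gating and sample the bottleneck radius.

    A continuous-time Markov chain with exponential holding times is
    simulated over ``n_frames * frame_spacing`` ns and sampled at the frame
    times; the observed radius is the state radius plus Gaussian noise,
    truncated at zero.  Reproducible given the seed (``model.seed`` unless
    overridden).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if frame_spacing <= 0:
        raise ValueError("frame_spacing must be positive")
    rng = np.random.default_rng(model.seed if seed is None else seed)

    if initial_state is not None:
        if initial_state not in ("open", "closed"):
            raise ValueError("initial_state must be 'open' or 'closed'")
        state = initial_state == "open"
    elif model.k_open + model.k_close > 0:
        state = rng.random() < model.stationary_open_fraction
    else:
        raise ValueError(
            "both rates are zero and no initial state was given"
        )

    total_time = n_frames * frame_spacing
    # simulate past the last frame time so the final sample is well defined
    seg_ends: list[float] = []
    seg_open: list[bool] = []
    open_dwells: list[float] = []
    closed_dwells: list[float] = []
    t = 0.0
    s = state
    while t < total_time:
        rate = model.k_close if s else model.k_open
        if rate == 0:
            t_end = math.inf
        else:
            dwell = rng.exponential(1.0 / rate)
            t_end = t + dwell
            if t_end < total_time:
                (open_dwells if s else closed_dwells).append(dwell)
        seg_ends.append(t_end)
        seg_open.append(s)
        t = t_end
        s = not s

    frame_times = frame_spacing * np.arange(n_frames)
    seg_idx = np.searchsorted(np.asarray(seg_ends), frame_times, side="right")
    state_series = np.asarray(seg_open, dtype=bool)[seg_idx]

    true_radius = np.where(state_series, model.r_open, model.r_closed)
    observed = true_radius + rng.normal(0.0, model.noise_sd, size=n_frames) \
        if model.noise_sd > 0 else true_radius.astype(float).copy()
    np.clip(observed, 0.0, None, out=observed)

    truth = GroundTruth(
        true_radius=true_radius.astype(float),
        state_open=state_series,
        stationary_open_fraction=(
            model.stationary_open_fraction
            if model.k_open + model.k_close > 0
            else float(state)
        ),
        mean_open_dwell=(1.0 / model.k_close if model.k_close > 0 else math.inf),
        open_dwells=np.asarray(open_dwells),
        closed_dwells=np.asarray(closed_dwells),
    )
    return observed, truth


# --------------------------------------------------------------------------
# Trajectory realization
# --------------------------------------------------------------------------

def realize_trajectory(
    spec: ToyStructureSpec,
    series_per_channel: Sequence[np.ndarray],
    seed: int | None = None,
    frame_spacing: float = 0.02,
    replicate_id: str = "r0",
    condition: str = "default",
) -> Ensemble:
    """Turn per-channel radius series into an ensemble of snapshots.

    Per frame, the gate ring of each channel is displaced radially so the
    channel's minimal free radius equals the series value (clamped at 0);
    all other atoms are fixed.  ``seed`` is accepted for interface parity
    and reserved (the displacement is deterministic).
    """
    if len(series_per_channel) != len(spec.channels):
        raise ValueError("one radius series per channel is required")
    series = [np.asarray(s, dtype=float) for s in series_per_channel]
    n_frames = len(series[0])
    if any(len(s) != n_frames for s in series):
        raise ValueError("all series must have equal length")
    for ch, (s, c) in enumerate(zip(series, spec.channels)):
        if np.any(s > c.free_radius + 1e-9):
            raise ValueError(
                f"channel {ch}: requested radius exceeds the geometric "
                f"maximum {c.free_radius} A"
            )

    shell_pts, gates = _build_geometry(spec)
    R = spec.pseudo_atom_radius
    shell_atoms = [
        Atom(i + 1, "C", "SHL", 1, p, R, ATOMIC_MASSES["C"])
        for i, p in enumerate(shell_pts)
    ]
    serial0 = len(shell_atoms) + 1

    snapshots = []
    for f in range(n_frames):
        atoms = list(shell_atoms)
        serial = serial0
        for ch, gate in enumerate(gates):
            target = max(float(series[ch][f]), 0.0)
            for p in _gate_positions(gate, target, R):
                atoms.append(
                    Atom(serial, "C", "GAT", 2 + ch, p, R, ATOMIC_MASSES["C"])
                )
                serial += 1
        snapshots.append(
            Snapshot(frame_index=f, time=f * frame_spacing, atoms=atoms)
        )
    return Ensemble(
        replicate_id=replicate_id,
        condition=condition,
        snapshots=snapshots,
        frame_spacing=frame_spacing,
    )


# --------------------------------------------------------------------------
# Study-level generation
# --------------------------------------------------------------------------

@dataclass
class StudyData:
    """Synthetic study: ensembles (optional) plus per-replicate truth."""

    conditions: tuple[str, str]
    replicate_ids: dict[str, list[str]]  # condition -> replicate ids
    series: dict[tuple[str, str], list[np.ndarray]]  # (cond, rep) -> per-channel
    ground_truth: dict[tuple[str, str], list[GroundTruth]]
    ensembles: list[Ensemble] = dc_field(default_factory=list)
    frame_spacing: float = 0.02


def _resolve_models(
    conditions: Sequence[str],
    models: Mapping[str, Sequence[GatingModel]] | Sequence[GatingModel],
) -> dict[str, list[GatingModel]]:
    if isinstance(models, Mapping):
        return {c: list(models[c]) for c in conditions}
    return {c: list(models) for c in conditions}


def generate_study_series(
    conditions: Sequence[str],
    replicates_per_condition: int,
    models: Mapping[str, Sequence[GatingModel]] | Sequence[GatingModel],
    n_frames: int,
    seed: int,
    frame_spacing: float = 0.02,
) -> StudyData:
    """Simulate gating series for every replicate of a two-condition study.

    Replicates receive independent seeds spawned from ``seed``; conditions
    may carry different gating models to emulate a solvent-model effect.
    """
    if replicates_per_condition < 1:
        raise ValueError("replicates_per_condition must be >= 1")
    conditions = tuple(conditions)
    model_map = _resolve_models(conditions, models)
    n_channels = {len(m) for m in model_map.values()}
    if len(n_channels) != 1:
        raise ValueError("all conditions must have the same number of channels")

    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(conditions) * replicates_per_condition * n_channels.pop()))

    study = StudyData(
        conditions=conditions,  # type: ignore[arg-type]
        replicate_ids={c: [] for c in conditions},
        series={},
        ground_truth={},
        frame_spacing=frame_spacing,
    )
    for cond in conditions:
        for r in range(replicates_per_condition):
            rep_id = f"{cond}-r{r}"
            study.replicate_ids[cond].append(rep_id)
            ser, gts = [], []
            for model in model_map[cond]:
                child = next(children)
                obs, gt = simulate_gating(
                    model,
                    n_frames,
                    frame_spacing,
                    seed=int(child.generate_state(1)[0] % (2**31)),
                )
                ser.append(obs)
                gts.append(gt)
            study.series[(cond, rep_id)] = ser
            study.ground_truth[(cond, rep_id)] = gts
    return study


def generate_study_ensemble(
    conditions: Sequence[str],
    replicates_per_condition: int,
    spec: ToyStructureSpec,
    models: Mapping[str, Sequence[GatingModel]] | Sequence[GatingModel],
    n_frames: int,
    seed: int,
    frame_spacing: float = 0.02,
) -> StudyData:
    """Full synthetic study: gating series realized as snapshot ensembles."""
    study = generate_study_series(
        conditions, replicates_per_condition, models, n_frames, seed, frame_spacing
    )
    for cond in study.conditions:
        for rep_id in study.replicate_ids[cond]:
            study.ensembles.append(
                realize_trajectory(
                    spec,
                    study.series[(cond, rep_id)],
                    frame_spacing=frame_spacing,
                    replicate_id=rep_id,
                    condition=cond,
                )
            )
    return study


def write_ground_truth(study: StudyData, path: str | Path) -> None:
    """Write the ground-truth table (CSV: replicate, frame, channel, state, radius)."""
    rows = []
    for (cond, rep), gts in study.ground_truth.items():
        for ch, gt in enumerate(gts):
            for f in range(len(gt.true_radius)):
                rows.append(
                    (
                        cond,
                        rep,
                        f,
                        ch,
                        "open" if gt.state_open[f] else "closed",
                        gt.true_radius[f],
                    )
                )
    pd.DataFrame(
        rows,
        columns=[
            "condition",
            "replicate_id",
            "frame",
            "channel",
            "true_state",
            "true_radius",
        ],
    ).to_csv(path, index=False)
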