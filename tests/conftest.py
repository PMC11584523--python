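"""Shared fixtures: tiny structures and profile builders."""

from __future__ import annotations

import numpy as np
import pytest

from tunnelgate.io_formats import Atom, Ensemble, Snapshot
from tunnelgate.synthetic_data import Channel, ToyStructureSpec
from tunnelgate.tunnel_detection import TunnelProfile


def make_atom(
    serial=1,
    name="C",
    residue_name="ALA",
    residue_id=1,
    position=(0.0, 0.0, 0.0),
    vdw_radius=1.7,
    mass=12.011,
):
    return Atom(serial, name, residue_name, residue_id,
                np.asarray(position, float), vdw_radius, mass)


def make_snapshot(positions, radii=None, frame_index=0, time=0.0):
    positions = np.asarray(positions, float)
    radii = np.full(len(positions), 1.7) if radii is None else np.asarray(radii)
    atoms = [
        make_atom(serial=i + 1, position=p, vdw_radius=r)
        for i, (p, r) in enumerate(zip(positions, radii))
    ]
    return Snapshot(frame_index=frame_index, time=time, atoms=atoms)


def straight_profile(
    offset=(0.0, 0.0, 0.0),
    direction=(0.0, 0.0, 1.0),
    length=8.0,
    n=5,
    radii=1.0,
    frame_index=0,
    tunnel_id=0,
    cost=1.0,
):
    """A straight-line tunnel spine used as a clustering test object."""
    offset = np.asarray(offset, float)
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    t = np.linspace(0.0, length, n)
    centers = offset + np.outer(t, direction)
    r = np.full(n, radii, dtype=float) if np.isscalar(radii) else np.asarray(radii)
    return TunnelProfile(
        centers=centers, radii=r, cost=cost, frame_index=frame_index,
        tunnel_id=tunnel_id,
    )


@pytest.fixture(scope="session")
def compact_spec():
    """Small sealed shell: cavity free radius 2.3 A (< shell radius)."""
    return ToyStructureSpec(
        shell_outer_radius=10.0, shell_thickness=6.0, cavity_radius=4.0,
        lattice_spacing=1.2, pseudo_atom_radius=1.7,
    )


@pytest.fixture(scope="session")
def one_channel_spec(compact_spec):
    return ToyStructureSpec(
        shell_outer_radius=10.0, shell_thickness=6.0, cavity_radius=4.0,
        lattice_spacing=1.2, pseudo_atom_radius=1.7,
        channels=(Channel((0.0, 0.0, 1.0), 1.5),),
    )


@pytest.fixture(scope="session")
def study_spec():
    """Two antipodal channels wide enough for a noisy open state of 1.6 A."""
    return ToyStructureSpec(
        shell_outer_radius=11.0, shell_thickness=7.0, cavity_radius=4.0,
        lattice_spacing=1.2, pseudo_atom_radius=1.7,
        channels=(Channel((0.0, 0.0, 1.0), 2.0), Channel((0.0, 0.0, -1.0), 2.0)),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
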