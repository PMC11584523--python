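"""Canonical in-memory data model and standard-format I/O.

All lengths are in Angstrom, all times in nanoseconds, residue ids are
1-based (PDB convention).  Van der Waals radii are assigned from a built-in
element table (Bondi radii for the elements occurring in the 20 standard
amino acids, plus hydrogen); the table can be overridden per call so that
alternative radius sets (e.g. the one used by an external tunnel-detection
tool) can be reproduced.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Snapshot",
    "Ensemble",
    "VDW_RADII",
    "ATOMIC_MASSES",
    "PDBParseError",
    "UnknownElementError",
    "ProfileSchemaError",
    "read_pdb_frames",
    "write_pdb_frames",
    "PROFILE_COLUMNS",
    "read_profile_table",
    "write_profile_table",
    "validate_profile_table",
    "read_config",
    "write_config",
]

#: Bondi van der Waals radii (Angstrom) for the elements of the 20 standard
#: amino acids plus hydrogen.  Lookup outside this table raises rather than
#: silently defaulting.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
}

#: Standard atomic masses (Da) for the same elements.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}


class PDBParseError(ValueError):
    """A PDB file could not be parsed into snapshots."""


class UnknownElementError(KeyError):
    """An atom's element is not covered by the active vdW radius table."""


class ProfileSchemaError(ValueError):
    """A tunnel-profile table violates the expected schema."""


@dataclass(frozen=True)
class Atom:
    """One atom of a snapshot.

    ``vdw_radius`` and ``mass`` are stored explicitly so that synthetic
    pseudo-atoms may carry radii that differ from the element table.
    """

    serial: int
    name: str
    residue_name: str
    residue_id: int
    position: np.ndarray  # shape (3,), Angstrom
    vdw_radius: float
    mass: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be positive")
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be positive")


@dataclass
class Snapshot:
    """One trajectory frame: an ordered collection of atoms at a time point."""

    frame_index: int
    time: float  # ns
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        if self.time < 0:
            raise ValueError("time must be non-negative")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a snapshot")

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class Ensemble:
    """An ordered collection of snapshots from one replicate trajectory."""

    replicate_id: str
    condition: str
    snapshots: list[Snapshot]
    frame_spacing: float = 0.02  # ns

    def __post_init__(self) -> None:
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be positive")
        indices = [s.frame_index for s in self.snapshots]
        if indices != list(range(len(indices))):
            raise ValueError("snapshots must be ordered by frame_index without gaps")

    @property
    def n_frames(self) -> int:
        return len(self.snapshots)

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)


# --------------------------------------------------------------------------
# PDB reading / writing
# --------------------------------------------------------------------------

_ELEMENT_FROM_NAME_HINTS = ("H", "C", "N", "O", "S")


def _resolve_element(element: str, atom_name: str) -> str:
    """Resolve the element symbol from the PDB element column or atom name."""
    el = element.strip().upper()
    if el:
        return el.capitalize() if len(el) > 1 else el
    name = atom_name.strip().upper()
    # PDB atom names start with the element for standard residues; strip
    # leading digits used for hydrogens such as "1HB".
    name = name.lstrip("0123456789")
    for hint in _ELEMENT_FROM_NAME_HINTS:
        if name.startswith(hint):
            return hint
    raise UnknownElementError(
        f"cannot resolve element for atom name {atom_name!r}"
    )


def _validate_pdb_text(text: str, source: str) -> None:
    """Light pre-validation producing line-precise errors for ATOM records."""
    n_atoms = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record in ("ATOM", "HETATM"):
            n_atoms += 1
            if len(line) < 54:
                raise PDBParseError(
                    f"{source}, line {lineno}: truncated {record} record"
                )
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"{source}, line {lineno}: malformed {what} coordinate "
                        f"field {line[lo:hi]!r}"
                    ) from None
    if n_atoms == 0:
        raise PDBParseError(f"{source}: no ATOM records")


def _stack_to_snapshots(
    stack: AtomArrayStack,
    serials: np.ndarray,
    vdw_table: Mapping[str, float],
    mass_table: Mapping[str, float],
    frame_spacing: float,
    frame_offset: int,
) -> list[Snapshot]:
    elements = [
        _resolve_element(el, nm)
        for el, nm in zip(stack.element, stack.atom_name)
    ]
    radii = np.empty(len(elements))
    masses = np.empty(len(elements))
    for i, el in enumerate(elements):
        if el not in vdw_table:
            raise UnknownElementError(
                f"element {el!r} of atom {stack.atom_name[i]!r} "
                f"(serial {int(serials[i])}) is not in the vdW radius table"
            )
        radii[i] = vdw_table[el]
        masses[i] = mass_table.get(el, ATOMIC_MASSES.get(el, 12.011))
    snapshots = []
    for m in range(stack.stack_depth()):
        coords = stack.coord[m]
        atoms = [
            Atom(
                serial=int(serials[i]),
                name=str(stack.atom_name[i]),
                residue_name=str(stack.res_name[i]),
                residue_id=int(stack.res_id[i]),
                position=coords[i],
                vdw_radius=float(radii[i]),
                mass=float(masses[i]),
            )
            for i in range(stack.array_length())
        ]
        idx = frame_offset + m
        snapshots.append(Snapshot(frame_index=idx, time=idx * frame_spacing, atoms=atoms))
    return snapshots


def read_pdb_frames(
    path_or_paths: str | Path | Iterable[str | Path],
    *,
    replicate_id: str = "r0",
    condition: str = "default",
    frame_spacing: float = 0.02,
    vdw_table: Mapping[str, float] | None = None,
    mass_table: Mapping[str, float] | None = None,
) -> Ensemble:
    """Read an ensemble of snapshots from PDB file(s).

    ``path_or_paths`` may be a single PDB file (multi-MODEL files yield one
    snapshot per model), a directory (all ``*.pdb`` files in lexicographic
    order), or an iterable of files.  Alternate locations: the first altloc
    wins (logged).  Radii come from the element table; an element outside
    the table raises :class:`UnknownElementError`.
    """
    vdw = dict(vdw_table) if vdw_table is not None else VDW_RADII
    masses = dict(mass_table) if mass_table is not None else ATOMIC_MASSES

    if isinstance(path_or_paths, (str, Path)):
        p = Path(path_or_paths)
        paths = sorted(p.glob("*.pdb")) if p.is_dir() else [p]
        if not paths:
            raise FileNotFoundError(f"no *.pdb files in directory {p}")
    else:
        paths = [Path(p) for p in path_or_paths]
    if not paths:
        raise ValueError("no input paths given")

    snapshots: list[Snapshot] = []
    for path in paths:
        if not path.exists():
            raise FileNotFoundError(path)
        text = path.read_text()
        _validate_pdb_text(text, str(path))
        if "ALTLOC" in text or any(
            line[16:17].strip() for line in text.splitlines()
            if line[:6].strip() in ("ATOM", "HETATM") and len(line) > 17
        ):
            logger.info("%s: alternate locations present; first altloc wins", path)
        try:
            pdb = PDBFile.read(io.StringIO(text))
            stack = pdb.get_structure(
                model=None, altloc="first", extra_fields=["atom_id"]
            )
        except Exception as exc:  # pragma: no cover - biotite internals
            raise PDBParseError(f"{path}: {exc}") from exc
        snapshots.extend(
            _stack_to_snapshots(
                stack, stack.atom_id, vdw, masses, frame_spacing, len(snapshots)
            )
        )
    return Ensemble(
        replicate_id=replicate_id,
        condition=condition,
        snapshots=snapshots,
        frame_spacing=frame_spacing,
    )


def write_pdb_frames(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble to one multi-MODEL PDB file.

    Coordinates are serialized in PDB 8.3 fixed-width columns, so the
    round trip through :func:`read_pdb_frames` preserves them to 1e-3 A.
    """
    if len(ensemble) == 0:
        raise ValueError("cannot write an empty ensemble")
    n_atoms = len(ensemble.snapshots[0])
    if any(len(s) != n_atoms for s in ensemble.snapshots):
        raise ValueError("all snapshots must have the same atom count for PDB output")

    template = ensemble.snapshots[0]
    arr = AtomArray(n_atoms)
    arr.coord = template.positions.astype(np.float32)
    arr.atom_name = np.array([a.name for a in template.atoms])
    arr.res_name = np.array([a.residue_name for a in template.atoms])
    arr.res_id = np.array([a.residue_id for a in template.atoms])
    arr.chain_id = np.array(["A"] * n_atoms)
    arr.element = np.array([_resolve_element("", a.name) for a in template.atoms])
    arr.set_annotation("atom_id", np.array([a.serial for a in template.atoms]))

    stack = AtomArrayStack(len(ensemble), n_atoms)
    for cat in arr.get_annotation_categories():
        stack.set_annotation(cat, arr.get_annotation(cat))
    stack.coord = np.stack(
        [s.positions.astype(np.float32) for s in ensemble.snapshots]
    )
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# --------------------------------------------------------------------------
# Tunnel-profile tables
# --------------------------------------------------------------------------

#: Column order of the CAVER-style per-sphere profile interchange table.
PROFILE_COLUMNS = [
    "replicate_id",
    "frame_index",
    "tunnel_id",
    "sphere_index",
    "x",
    "y",
    "z",
    "radius",
]

_PROFILE_DTYPES = {
    "frame_index": np.int64,
    "tunnel_id": np.int64,
    "sphere_index": np.int64,
    "x": float,
    "y": float,
    "z": float,
    "radius": float,
}


def validate_profile_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and invariants of a profile table; returns the table."""
    missing = [c for c in PROFILE_COLUMNS if c not in table.columns]
    if missing:
        raise ProfileSchemaError(f"missing column(s): {', '.join(missing)}")
    if len(table) and (table["radius"] <= 0).any():
        raise ProfileSchemaError("all sphere radii must be positive")
    for (rep, frame, tid), grp in table.groupby(
        ["replicate_id", "frame_index", "tunnel_id"], sort=False
    ):
        idx = grp["sphere_index"].to_numpy()
        if not np.array_equal(np.sort(idx), np.arange(len(idx))):
            raise ProfileSchemaError(
                f"sphere_index not contiguous from 0 for tunnel {tid} "
                f"in frame {frame} of replicate {rep!r}"
            )
    return table


def read_profile_table(path: str | Path) -> pd.DataFrame:
    """Read a comma-separated tunnel-profile table (see PROFILE_COLUMNS)."""
    table = pd.read_csv(path)
    validate_profile_table(table)
    return table.astype({k: v for k, v in _PROFILE_DTYPES.items()})[PROFILE_COLUMNS]


def write_profile_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a profile table as CSV; round trip with read is the identity."""
    validate_profile_table(table)
    table[PROFILE_COLUMNS].to_csv(path, index=False)


# --------------------------------------------------------------------------
# Flat key=value configuration files
# --------------------------------------------------------------------------

def read_config(path: str | Path) -> dict[str, str]:
    """Read a flat ``key = value`` text config; '#' starts a comment."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}, line {lineno}: expected 'key = value'")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def write_config(config: Mapping[str, str], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{k} = {v}\n" for k, v in config.items())
    )
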