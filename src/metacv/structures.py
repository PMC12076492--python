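"""Structure and trajectory I/O, atom selections, and center-of-mass geometry.

Coordinates are in angstrom throughout.  PDB files are read and written
through :mod:`biotite.structure.io.pdb` (including multi-model files); XYZ
multi-frame files through MDAnalysis.  Residue and chain identifiers are taken
verbatim from the input file — no renumbering is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import mass_of


class StructureError(ValueError):
    """Raised for unreadable, malformed or inconsistent structure input."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus a 3-vector position (A)."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    position: tuple[float, float, float]

    @property
    def key(self) -> tuple[str, int, str]:
        """(chain_id, res_seq, name) — unique within a structure."""
        return (self.chain_id, self.res_seq, self.name)


@dataclass
class Structure:
    """An ordered set of atoms with a chain-to-protomer mapping."""

    atoms: list[AtomRecord]
    protomer_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.protomer_map:
            self.protomer_map = {c: c for c in self.chain_ids()}
        missing = [c for c in self.chain_ids() if c not in self.protomer_map]
        if missing:
            raise StructureError(f"chains {missing} absent from protomer_map")

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, A."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def index_of(self, chain_id: str, res_seq: int, name: str) -> int:
        try:
            return self._index[(chain_id, res_seq, name)]
        except AttributeError:
            object.__setattr__(self, "_index", {a.key: i for i, a in enumerate(self.atoms)})
            return self._index[(chain_id, res_seq, name)]
        except KeyError:
            raise KeyError(f"no atom {chain_id}/{res_seq}/{name} in structure") from None

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with positions replaced by ``coords``."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise StructureError(f"coordinate array shape {coords.shape} != ({self.n_atoms}, 3)")
        atoms = [
            AtomRecord(a.serial, a.name, a.element, a.res_name, a.res_seq, a.chain_id,
                       tuple(float(x) for x in xyz))
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms, dict(self.protomer_map))


@dataclass
class Trajectory:
    """Frames of coordinates (A) over a fixed topology."""

    frames: np.ndarray  # (n_frames, n_atoms, 3)
    topology: Structure
    frame_stride: float = 1.0  # ps between frames

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise StructureError("trajectory needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise StructureError(
                f"frame atom count {self.frames.shape[1]} != topology {self.topology.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass(frozen=True)
class Selection:
    """Declarative atom selection: optional chain, inclusive residue range, atom names.

    Without an explicit ``atom_names`` set the selection resolves to all heavy
    (non-hydrogen) atoms of the matched residues.
    """

    chain_id: str | None = None
    res_range: tuple[int, int] | None = None
    atom_names: frozenset[str] | None = None

    def resolve(self, structure: Structure) -> np.ndarray:
        """Indices of matching atoms; raises if the selection is empty."""
        idx = []
        for i, a in enumerate(structure.atoms):
            if self.chain_id is not None and a.chain_id != self.chain_id:
                continue
            if self.res_range is not None and not (self.res_range[0] <= a.res_seq <= self.res_range[1]):
                continue
            if self.atom_names is not None:
                if a.name not in self.atom_names:
                    continue
            elif a.element.upper() == "H":
                continue
            idx.append(i)
        if not idx:
            raise StructureError(f"selection {self} matched no atoms")
        return np.asarray(idx, dtype=int)


BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


def _guess_element(atom_name: str) -> str:
    stripped = "".join(ch for ch in atom_name if ch.isalpha())
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    if two in {"CL", "BR", "MG", "ZN", "FE", "MN", "NA", "SE"}:
        return two
    return stripped[0].upper()


def _structure_from_atom_array(arr) -> Structure:
    atoms = []
    for i in range(arr.array_length()):
        element = str(arr.element[i]).strip() or _guess_element(str(arr.atom_name[i]))
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name=str(arr.atom_name[i]),
                element=element,
                res_name=str(arr.res_name[i]),
                res_seq=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]) or "A",
                position=tuple(float(x) for x in arr.coord[i]),
            )
        )
    if not atoms:
        raise StructureError("file contains zero atoms")
    return Structure(atoms)


def _find_malformed_pdb_line(path: Path) -> int | None:
    for n, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                return n
    return None


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    return {"pdb": "pdb", "ent": "pdb", "xyz": "xyz"}.get(suffix, "pdb")


def read_structure(path, format: str | None = None,
                   protomer_map: dict[str, str] | None = None) -> Structure:
    """Read a single-model PDB or XYZ file into a :class:`Structure`.

    The chain-to-protomer map defaults to the identity over the chains present.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        import biotite.structure.io.pdb as pdbio

        try:
            pdb_file = pdbio.PDBFile.read(str(path))
            arr = pdb_file.get_structure(model=1)
        except Exception as exc:
            line = _find_malformed_pdb_line(path)
            where = f" at line {line}" if line else ""
            raise StructureError(f"malformed record{where} in {path}: {exc}") from exc
        struct = _structure_from_atom_array(arr)
    elif fmt == "xyz":
        traj = read_trajectory(path, format="xyz")
        struct = traj.topology.with_coords(traj.frames[0])
    else:
        raise StructureError(f"unknown structure format {fmt!r}")
    if protomer_map is not None:
        struct = Structure(struct.atoms, dict(protomer_map))
    return struct


def read_trajectory(path, format: str | None = None, frame_stride: float = 1.0,
                    protomer_map: dict[str, str] | None = None) -> Trajectory:
    """Read a multi-model PDB or multi-frame XYZ file into a :class:`Trajectory`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt in ("pdb", "multi-model-pdb"):
        import biotite.structure.io.pdb as pdbio

        try:
            pdb_file = pdbio.PDBFile.read(str(path))
            stack = pdb_file.get_structure(model=None)
        except Exception as exc:
            raise StructureError(f"could not read trajectory {path}: {exc}") from exc
        topo = _structure_from_atom_array(stack[0])
        frames = np.asarray(stack.coord, dtype=float)
    elif fmt == "xyz":
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                u = mda.Universe(str(path), format="XYZ")
            except Exception as exc:
                raise StructureError(f"could not read trajectory {path}: {exc}") from exc
            names = [str(n) for n in u.atoms.names]
            frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
        atoms = [
            AtomRecord(i + 1, f"{name}{i + 1}", _guess_element(name), "UNK", 1, "A",
                       tuple(float(x) for x in frames[0, i]))
            for i, name in enumerate(names)
        ]
        topo = Structure(atoms)
    else:
        raise StructureError(f"unknown trajectory format {fmt!r}")
    if protomer_map is not None:
        topo = Structure(topo.atoms, dict(protomer_map))
    return Trajectory(frames, topo, frame_stride=frame_stride)


def _atom_array_from_structure(structure: Structure, coords: np.ndarray | None = None):
    import biotite.structure as struc

    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = structure.coords() if coords is None else np.asarray(coords, dtype=float)
    arr.chain_id = np.array([a.chain_id for a in structure.atoms], dtype="U4")
    arr.res_id = np.array([a.res_seq for a in structure.atoms], dtype=int)
    arr.res_name = np.array([a.res_name for a in structure.atoms], dtype="U5")
    arr.atom_name = np.array([a.name for a in structure.atoms], dtype="U6")
    arr.element = np.array([a.element for a in structure.atoms], dtype="U2")
    arr.hetero = np.full(n, False)
    return arr


def write_structure(path, structure: Structure, format: str | None = None) -> None:
    """Write a structure as PDB or single-frame XYZ."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        import biotite.structure.io.pdb as pdbio

        pdb_file = pdbio.PDBFile()
        pdb_file.set_structure(_atom_array_from_structure(structure))
        pdb_file.write(str(path))
    elif fmt == "xyz":
        write_trajectory(path, Trajectory(structure.coords()[None], structure), format="xyz")
    else:
        raise StructureError(f"unknown structure format {fmt!r}")


def write_trajectory(path, traj: Trajectory, format: str | None = None) -> None:
    """Write a trajectory as multi-model PDB or multi-frame XYZ."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt in ("pdb", "multi-model-pdb"):
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdbio

        stack = struc.stack([_atom_array_from_structure(traj.topology, f) for f in traj.frames])
        pdb_file = pdbio.PDBFile()
        pdb_file.set_structure(stack)
        pdb_file.write(str(path))
    elif fmt == "xyz":
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe.empty(traj.topology.n_atoms, trajectory=True)
            u.add_TopologyAttr("names", [a.element for a in traj.topology.atoms])
            with mda.Writer(str(path), traj.topology.n_atoms) as writer:
                for frame in traj.frames:
                    u.atoms.positions = frame
                    writer.write(u.atoms)
    else:
        raise StructureError(f"unknown trajectory format {fmt!r}")


def center_of_mass(frame: np.ndarray, topology: Structure, sel: Selection,
                   masses: dict | None = None) -> np.ndarray:
    """Mass-weighted mean position (A) of a selection in one frame."""
    frame = np.asarray(frame, dtype=float)
    idx = sel.resolve(topology)
    m = np.array([mass_of(topology.atoms[i].element, masses) for i in idx])
    return (frame[idx] * m[:, None]).sum(axis=0) / m.sum()
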