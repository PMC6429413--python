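"""Structures, trajectories, selections and tabular/matrix I/O.

Internal units are Å for lengths and ps for times.  Atom order as read from
file is the canonical index space for every downstream matrix and vector.
PDB parsing and writing are delegated to biotite; element masses come from
the IUPAC standard atomic weights shipped with Biopython.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import atom_weights

from .errors import (
    EmptySelectionError,
    ParseError,
    SelectionError,
    TrajectoryError,
)

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "AtomIndexSet",
    "GeometrySeries",
    "element_mass",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select_atoms",
    "substructure",
    "frames_in_window",
    "write_table",
    "read_table",
    "write_matrix",
    "read_matrix",
]


def element_mass(element: str) -> float:
    """Standard atomic weight (amu) for an element symbol, e.g. ``"C"``, ``"MG"``."""
    key = element.strip().capitalize()
    try:
        mass = atom_weights[key]
    except KeyError:
        raise ParseError(f"unknown element symbol {element!r}; no default mass assigned")
    if not mass > 0:
        raise ParseError(f"non-positive mass for element {element!r}")
    return float(mass)


@dataclass(frozen=True)
class Atom:
    """A single atom: identity, position (Å) and mass (amu)."""

    name: str
    element: str
    residue_index: int  # 1-based, PDB convention
    residue_name: str
    chain_id: str
    coords: np.ndarray
    mass: float

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if not self.mass > 0:
            raise ValueError(f"atom {self.name}: mass must be positive")


class Structure:
    """An ordered collection of atoms.

    The atom order is stable and defines the index space for Hessians,
    covariance matrices and mode vectors built from this structure.
    """

    def __init__(self, atoms: Sequence[Atom]):
        self._atoms = list(atoms)
        self._coords = np.array([a.coords for a in self._atoms], dtype=float).reshape(-1, 3)
        self._masses = np.array([a.mass for a in self._atoms], dtype=float)

    @property
    def atoms(self) -> list[Atom]:
        return self._atoms

    @property
    def n_atoms(self) -> int:
        return len(self._atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array, Å.  A copy; mutate via :meth:`with_coords`."""
        return self._coords.copy()

    @property
    def masses(self) -> np.ndarray:
        return self._masses.copy()

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Same atoms/metadata with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"coords shape {coords.shape} != ({self.n_atoms}, 3)")
        atoms = [
            Atom(a.name, a.element, a.residue_index, a.residue_name, a.chain_id, c, a.mass)
            for a, c in zip(self._atoms, coords)
        ]
        return Structure(atoms)

    # vectorized annotation access used by selections
    def annotation(self, key: str) -> np.ndarray:
        return np.array([getattr(a, key) for a in self._atoms])

    def __len__(self) -> int:
        return self.n_atoms

    def __repr__(self) -> str:
        return f"<Structure with {self.n_atoms} atoms>"


class Trajectory:
    """Time-stamped coordinate frames bound to a :class:`Structure`.

    ``frames`` has shape (F, N, 3) in Å; ``times`` is length F in ps and must
    be strictly increasing when more than one frame is present with a
    positive frame interval.
    """

    def __init__(self, structure: Structure, times: np.ndarray, frames: np.ndarray):
        times = np.asarray(times, dtype=float)
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise TrajectoryError(f"frames must be (F, N, 3); got {frames.shape}")
        if frames.shape[1] != structure.n_atoms:
            raise TrajectoryError(
                f"frames have {frames.shape[1]} atoms but structure has {structure.n_atoms}"
            )
        if times.shape != (frames.shape[0],):
            raise TrajectoryError("times length must equal number of frames")
        if times.size > 1 and np.any(np.diff(times) < 0):
            raise TrajectoryError("frame times must be non-decreasing")
        self.structure = structure
        self.times = times
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def window(self, start: float, end: float, closed: bool = False) -> "Trajectory":
        """Sub-trajectory restricted to a time window (ps).

        ``closed=False`` keeps frames in ``[start, end)``; ``closed=True``
        keeps ``[start, end]``.  Both conventions appear in trajectory
        analyses (a 100-ns window sampled at 1 ps holds 100 001 conformations
        when closed, a 7-ns window at 1 ps holds 7000 snapshots half-open).
        """
        mask = frames_in_window(self.times, start, end, closed=closed)
        if not mask.any():
            raise TrajectoryError(f"window [{start}, {end}{']' if closed else ')'} contains no frames")
        return Trajectory(self.structure, self.times[mask], self.frames[mask])

    def __repr__(self) -> str:
        return f"<Trajectory: {self.n_frames} frames x {self.n_atoms} atoms>"


def frames_in_window(times: np.ndarray, start: float, end: float, closed: bool = False) -> np.ndarray:
    """Boolean mask of frame times inside ``[start, end)`` or ``[start, end]``."""
    times = np.asarray(times, dtype=float)
    if end < start:
        raise TrajectoryError(f"window end {end} < start {start}")
    if closed:
        return (times >= start) & (times <= end)
    return (times >= start) & (times < end)


@dataclass(frozen=True)
class AtomIndexSet:
    """Ordered, duplicate-free atom positions into ``Structure.atoms``."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1:
            raise SelectionError("indices must be one-dimensional")
        if len(np.unique(idx)) != len(idx):
            raise SelectionError("indices contain duplicates")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def validate(self, structure: Structure) -> None:
        if len(self) and (self.indices.min() < 0 or self.indices.max() >= structure.n_atoms):
            raise SelectionError("indices out of range for structure")


@dataclass
class GeometrySeries:
    """A per-frame scalar series (distance, angle, RMSD or projection)."""

    times: np.ndarray
    values: np.ndarray
    kind: str = "distance"  # {"distance", "angle", "rmsd", "projection"}
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("series values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, self.kind: self.values})


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _atoms_from_atom_array(arr) -> list[Atom]:
    atoms = []
    for i in range(arr.array_length()):
        element = str(arr.element[i])
        if not element:
            raise ParseError(f"atom record {i + 1}: missing element symbol")
        atoms.append(
            Atom(
                name=str(arr.atom_name[i]),
                element=element,
                residue_index=int(arr.res_id[i]),
                residue_name=str(arr.res_name[i]),
                chain_id=str(arr.chain_id[i]),
                coords=np.asarray(arr.coord[i], dtype=float),
                mass=element_mass(element),
            )
        )
    return atoms


def _structure_to_atom_array(structure: Structure):
    import biotite.structure as struc

    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = structure.coords
    arr.atom_name = structure.annotation("name")
    arr.res_name = structure.annotation("residue_name")
    arr.res_id = structure.annotation("residue_index").astype(int)
    arr.chain_id = structure.annotation("chain_id")
    arr.element = np.array([a.element.upper() for a in structure.atoms])
    standard = {"ALA", "GLY", "HIS", "SER", "LEU", "VAL", "THR", "CYS", "PRO",
                "ASP", "GLU", "PHE", "ILE", "LYS", "MET", "ASN", "GLN", "ARG",
                "TRP", "TYR"}
    arr.hetero = np.array([a.residue_name not in standard for a in structure.atoms])
    return arr


def read_structure(path: str | os.PathLike, format: str = "pdb") -> Structure:
    """Read a structure file (first model of a PDB) into a :class:`Structure`.

    Atoms keep file order; hetero atoms are retained; masses are assigned
    from the element symbol.
    """
    if format.lower() != "pdb":
        raise ParseError(f"unsupported structure format {format!r}")
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
        if n_models == 0:
            raise ParseError(f"{path}: no ATOM/HETATM records found")
        arr = pdb.get_structure(model=1)
    except ParseError:
        raise
    except Exception as exc:  # biotite raises various exception types
        raise ParseError(f"{path}: failed to parse PDB: {exc}") from exc
    if arr.array_length() == 0:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return Structure(_atoms_from_atom_array(arr))


def write_structure(structure: Structure, path: str | os.PathLike) -> None:
    """Write a structure as a single-model PDB file (coordinates at 10⁻³ Å)."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_structure_to_atom_array(structure))
    pdb.write(str(path))


def read_trajectory(
    path: str | os.PathLike,
    structure: Structure | None = None,
    format: str | None = None,
    frame_dt: float = 1.0,
    time_origin: float = 0.0,
) -> Trajectory:
    """Read a trajectory (multi-model PDB; DCD/XTC via MDAnalysis if installed).

    PDB files carry no time stamps, so frame times are assigned as
    ``time_origin + i * frame_dt`` (ps) in model order.  ``structure`` (when
    given) must match the per-frame atom count.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "pdb"
    format = format.lower()
    if format == "pdb":
        from biotite.structure.io.pdb import PDBFile

        if not path.exists():
            raise ParseError(f"no such file: {path}")
        pdb = PDBFile.read(str(path))
        if pdb.get_model_count() == 0:
            raise ParseError(f"{path}: no models found")
        obj = pdb.get_structure()  # AtomArrayStack (or AtomArray for 1 model)
        coords = np.asarray(obj.coord, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        first = pdb.get_structure(model=1)
        if structure is None:
            structure = Structure(_atoms_from_atom_array(first))
        for f_idx, frame in enumerate(coords):
            if frame.shape[0] != structure.n_atoms:
                raise TrajectoryError(
                    f"frame {f_idx}: {frame.shape[0]} atoms, expected {structure.n_atoms}"
                )
        times = time_origin + frame_dt * np.arange(coords.shape[0])
        return Trajectory(structure, times, coords)
    if format in ("dcd", "xtc"):
        if structure is None:
            raise TrajectoryError(f"{format} trajectories require an explicit structure")
        try:
            import MDAnalysis as mda
        except ImportError as exc:
            raise ParseError("DCD/XTC support requires MDAnalysis") from exc
        import tempfile

        with tempfile.NamedTemporaryFile(suffix=".pdb", delete=False) as tmp:
            top = tmp.name
        try:
            write_structure(structure, top)
            u = mda.Universe(top, str(path))
            frames, times = [], []
            for i, ts in enumerate(u.trajectory):
                if ts.positions.shape[0] != structure.n_atoms:
                    raise TrajectoryError(
                        f"frame {i}: {ts.positions.shape[0]} atoms, expected {structure.n_atoms}"
                    )
                frames.append(ts.positions.astype(float).copy())
                t = float(ts.time) if np.isfinite(ts.time) and ts.time > 0 else time_origin + i * frame_dt
                times.append(t)
        finally:
            os.unlink(top)
        return Trajectory(structure, np.asarray(times), np.asarray(frames))
    raise ParseError(f"unsupported trajectory format {format!r}")


def write_trajectory(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write a trajectory as a multi-model PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    template = _structure_to_atom_array(traj.structure)
    stack = struc.AtomArrayStack(traj.n_frames, traj.n_atoms)
    stack.coord = traj.frames
    for ann in template.get_annotation_categories():
        stack.set_annotation(ann, template.get_annotation(ann))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def substructure(structure: Structure, atom_set: AtomIndexSet) -> Structure:
    """New structure consisting of the selected atoms (in selection order)."""
    atom_set.validate(structure)
    return Structure([structure.atoms[i] for i in atom_set.indices])


# ---------------------------------------------------------------------------
# Atom selection language
# ---------------------------------------------------------------------------
#
# Clauses joined by "and"; each clause is "<keyword> <value> [<value>...]":
#   name CA C O N       atom names
#   resname HIS MG      residue names
#   resid 10:50 221     1-based residue indices or inclusive ranges a:b
#   chain A B           chain identifiers
#   element P MG        element symbols
#   all                 every atom

_KEYWORDS = {"name", "resname", "resid", "chain", "element", "all"}


def _clause_mask(structure: Structure, tokens: list[str]) -> np.ndarray:
    if not tokens:
        raise SelectionError("empty selection clause")
    keyword, values = tokens[0].lower(), tokens[1:]
    n = structure.n_atoms
    if keyword == "all":
        if values:
            raise SelectionError("'all' takes no arguments")
        return np.ones(n, dtype=bool)
    if keyword not in _KEYWORDS:
        raise SelectionError(f"unknown selection keyword {keyword!r}")
    if not values:
        raise SelectionError(f"selection keyword {keyword!r} needs at least one value")
    if keyword == "name":
        names = structure.annotation("name")
        return np.isin(names, values)
    if keyword == "resname":
        return np.isin(structure.annotation("residue_name"), [v.upper() for v in values])
    if keyword == "chain":
        return np.isin(structure.annotation("chain_id"), values)
    if keyword == "element":
        elements = np.array([a.element.upper() for a in structure.atoms])
        return np.isin(elements, [v.upper() for v in values])
    # resid: integers and inclusive ranges
    resids = structure.annotation("residue_index").astype(int)
    mask = np.zeros(n, dtype=bool)
    for v in values:
        if ":" in v:
            lo_s, hi_s = v.split(":", 1)
            try:
                lo, hi = int(lo_s), int(hi_s)
            except ValueError:
                raise SelectionError(f"bad residue range {v!r}")
            mask |= (resids >= lo) & (resids <= hi)
        else:
            try:
                mask |= resids == int(v)
            except ValueError:
                raise SelectionError(f"bad residue index {v!r}")
    return mask


def select_atoms(structure: Structure, selector: str, label: str | None = None) -> AtomIndexSet:
    """Resolve a selection expression to atom indices in structure order.

    Raises :class:`EmptySelectionError` when nothing matches: every
    downstream operation (superposition, Hessians, covariances) is undefined
    on an empty atom set.
    """
    if not selector or not selector.strip():
        raise SelectionError("empty selection expression")
    clauses = [c.strip() for c in selector.split(" and ")]
    mask = np.ones(structure.n_atoms, dtype=bool)
    for clause in clauses:
        mask &= _clause_mask(structure, clause.split())
    indices = np.nonzero(mask)[0]
    if indices.size == 0:
        raise EmptySelectionError(f"selection {selector!r} matched no atoms")
    return AtomIndexSet(indices, label=label if label is not None else selector)


# ---------------------------------------------------------------------------
# Tables and dense matrices
# ---------------------------------------------------------------------------

def write_table(data, path: str | os.PathLike, format: str | None = None) -> None:
    """Write rectangular data (DataFrame, GeometrySeries or 2-D array) as CSV/TSV.

    A header row is always written; floats are kept at full precision so a
    read-back reproduces values exactly.
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    sep = "\t" if format == "tsv" else ","
    if isinstance(data, GeometrySeries):
        df = data.to_frame()
    elif isinstance(data, pd.DataFrame):
        df = data
    else:
        arr = np.atleast_2d(np.asarray(data))
        df = pd.DataFrame(arr, columns=[f"c{i}" for i in range(arr.shape[1])])
    df.to_csv(path, sep=sep, index=False)


def read_table(path: str | os.PathLike, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    sep = "\t" if format == "tsv" else ","
    return pd.read_csv(path, sep=sep)


def write_matrix(matrix: np.ndarray, path: str | os.PathLike) -> None:
    """Write a dense matrix as whitespace-separated text at full precision."""
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.17g")


def read_matrix(path: str | os.PathLike) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        m = np.loadtxt(path, dtype=float)
    except Exception as exc:
        raise ParseError(f"{path}: failed to parse matrix: {exc}") from exc
    return np.atleast_2d(m)
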