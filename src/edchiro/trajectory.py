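"""Trajectory data model, I/O, atom selection, superposition and RMSD.

All coordinates are stored in nanometres.  Ångström appears only at the
format boundary (PDB); XYZ files are read and written in nm by convention
of this package, GRO files are nm by definition of the format.

The in-memory model is deliberately small: a topology is a list of
:class:`AtomRecord` (element, name, molecule id, role, mass, van der Waals
radius) and a trajectory is that topology plus an ordered list of
:class:`Frame` coordinate arrays.  Roles partition the system into
``solute`` (the nanocluster), ``solvent`` (water) and ``ion``; every
downstream stage — covariance analysis, shell extraction, descriptor
computation — selects atoms through this partition.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "TrajectoryError",
    "ParseError",
    "StructuralError",
    "DegeneracyError",
    "EmptySelectionError",
    "read_trajectory",
    "write_trajectory",
    "read_topology",
    "write_topology",
    "select_atoms",
    "superpose",
    "rmsd",
]

ROLES = ("solute", "solvent", "ion")

#: residue / molecule names treated as water when a role column is absent
WATER_RESNAMES = frozenset({"HOH", "SOL", "WAT"})

#: default ion residue names (monatomic counter-ions)
ION_RESNAMES = frozenset({"NA", "NA+", "CL", "CL-", "K", "K+", "MG", "CA"})

_DEFAULT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "Au": 196.967, "Na": 22.990, "Cl": 35.45, "K": 39.098,
}
# van der Waals radii in nm (Bondi; Au metallic)
_DEFAULT_VDW = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180,
    "Au": 0.166, "Na": 0.227, "Cl": 0.175, "K": 0.275,
}


class TrajectoryError(Exception):
    """Base class for trajectory-layer errors."""


class ParseError(TrajectoryError):
    """A file record could not be parsed; the message names the line."""


class StructuralError(TrajectoryError):
    """Frames/topology are mutually inconsistent (e.g. atom-count mismatch)."""


class DegeneracyError(TrajectoryError):
    """A geometric operation received degenerate input (collinear, coincident)."""


class EmptySelectionError(TrajectoryError):
    """A selection that must be non-empty matched no atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology.

    Parameters
    ----------
    element : chemical symbol (``Au``, ``O``, ...)
    name : atom name as given by the source file (``CA``, ``OW``, ...)
    molecule_id : integer id of the molecule the atom belongs to
    role : ``solute`` | ``solvent`` | ``ion``
    mass : atomic mass, amu
    vdw_radius : van der Waals radius, nm
    """

    element: str
    name: str
    molecule_id: int
    role: str
    mass: float
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if not self.mass > 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if not self.vdw_radius > 0:
            raise ValueError(f"vdw_radius must be positive, got {self.vdw_radius}")


def default_atom(element: str, name: str | None = None, molecule_id: int = 0,
                 role: str = "solute") -> AtomRecord:
    """Build an :class:`AtomRecord` with tabulated mass/vdW radius."""
    el = element.capitalize() if len(element) > 1 else element.upper()
    return AtomRecord(
        element=el,
        name=name or el,
        molecule_id=molecule_id,
        role=role,
        mass=_DEFAULT_MASSES.get(el, 12.0),
        vdw_radius=_DEFAULT_VDW.get(el, 0.17),
    )


@dataclass
class Frame:
    """A single configuration: ``(n_atoms, 3)`` coordinates in nm."""

    coordinates: np.ndarray
    box: np.ndarray | None = None  # 3 box lengths, nm
    time: float | None = None      # ps

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructuralError(
                f"coordinates must be (n_atoms, 3), got {self.coordinates.shape}")
        if not np.all(np.isfinite(self.coordinates)):
            raise StructuralError("non-finite coordinate encountered")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """An ordered sequence of frames sharing one topology."""

    topology: list[AtomRecord]
    frames: list[Frame]

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise StructuralError("a trajectory needs at least one frame")
        n = len(self.topology)
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise StructuralError(
                    f"frame {i} has {fr.n_atoms} atoms, topology has {n}")

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinates(self) -> np.ndarray:
        """Stack all frames into an ``(n_frames, n_atoms, 3)`` array (nm)."""
        return np.stack([f.coordinates for f in self.frames])

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def select_atoms(topology: Sequence[AtomRecord], role: str | None = None,
                 element: str | None = None, require_nonempty: bool = False,
                 ) -> np.ndarray:
    """Indices of atoms matching a role and/or element filter.

    Returns sorted unique indices.  With ``require_nonempty=True`` an empty
    result raises :class:`EmptySelectionError` instead of returning ``[]``.
    """
    if role is not None and role not in ROLES:
        raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
    idx = [
        i for i, a in enumerate(topology)
        if (role is None or a.role == role)
        and (element is None or a.element == element)
    ]
    if require_nonempty and not idx:
        raise EmptySelectionError(
            f"selection role={role!r} element={element!r} matched no atoms")
    return np.asarray(idx, dtype=int)


# ---------------------------------------------------------------------------
# superposition / RMSD
# ---------------------------------------------------------------------------

def _check_subset(coords: np.ndarray, subset: np.ndarray) -> None:
    if subset.size < 3:
        raise DegeneracyError(f"superposition subset needs >= 3 atoms, got {subset.size}")
    pts = coords[subset]
    centred = pts - pts.mean(axis=0)
    # rank < 2 means all points on a line (or a point)
    if np.linalg.matrix_rank(centred, tol=1e-10) < 2:
        raise DegeneracyError("superposition subset is collinear or coincident")


def superpose(mobile: np.ndarray, reference: np.ndarray,
              subset: np.ndarray | None = None,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``reference``.

    The optimal proper rotation and translation are computed on ``subset``
    (all atoms when ``None``) and applied to *all* atoms of ``mobile``.

    Returns ``(rotation, translation, transformed)`` such that
    ``transformed = mobile @ rotation.T + translation``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise StructuralError(
            f"shape mismatch: mobile {mobile.shape} vs reference {reference.shape}")
    if subset is None:
        subset = np.arange(mobile.shape[0])
    subset = np.asarray(subset, dtype=int)
    _check_subset(mobile, subset)

    m = mobile[subset]
    r = reference[subset]
    mc = m.mean(axis=0)
    rc = r.mean(axis=0)
    h = (m - mc).T @ (r - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    transformed = mobile @ rot.T + trans
    return rot, trans, transformed


def rmsd(a: np.ndarray, b: np.ndarray, subset: np.ndarray | None = None,
         fit: bool = False) -> float:
    """Root-mean-square deviation between two structures, nm.

    With ``fit=True`` the structures are first optimally superposed on
    ``subset`` (Kabsch).  Symmetric in its arguments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise StructuralError(f"shape mismatch: {a.shape} vs {b.shape}")
    if subset is None:
        subset = np.arange(a.shape[0])
    subset = np.asarray(subset, dtype=int)
    if fit:
        _, _, a = superpose(a, b, subset)
    d = a[subset] - b[subset]
    return float(np.sqrt((d * d).sum() / subset.size))


# ---------------------------------------------------------------------------
# topology side-car (delimited text)
# ---------------------------------------------------------------------------

def write_topology(topology: Sequence[AtomRecord], path: str | Path) -> None:
    """Write the topology side-car: whitespace-delimited text with header."""
    with open(path, "w") as fh:
        fh.write("# index element name molecule_id role mass vdw_radius\n")
        for i, a in enumerate(topology):
            fh.write(f"{i} {a.element} {a.name} {a.molecule_id} "
                     f"{a.role} {a.mass:.6g} {a.vdw_radius:.6g}\n")


def read_topology(path: str | Path) -> list[AtomRecord]:
    records: list[AtomRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ParseError(f"{path}: line {ln}: expected 7 fields, got {len(parts)}")
            try:
                records.append(AtomRecord(
                    element=parts[1], name=parts[2], molecule_id=int(parts[3]),
                    role=parts[4], mass=float(parts[5]), vdw_radius=float(parts[6])))
            except ValueError as exc:
                raise ParseError(f"{path}: line {ln}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# coordinate file I/O
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
    else:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt not in ("xyz", "pdb", "gro"):
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    return fmt


def _guess_role(resname: str) -> str:
    up = resname.upper()
    if up in WATER_RESNAMES:
        return "solvent"
    if up in ION_RESNAMES:
        return "ion"
    return "solute"


def read_trajectory(path: str | Path, format: str | None = None,
                    topology: Sequence[AtomRecord] | str | Path | None = None,
                    ) -> Trajectory:
    """Read a multi-frame XYZ, multi-model PDB or (multi-frame) GRO file.

    Coordinates are converted to nm (PDB Å × 0.1; XYZ is written/read in nm
    by this package's convention; GRO is nm natively).  ``topology`` may be
    a side-car path or a ready list of records; when absent a topology is
    inferred from the file (elements from atom names, solvent/ion roles from
    the residue-name lists, tabulated masses and vdW radii).
    """
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        top, frames = _read_xyz(path)
    elif fmt == "gro":
        top, frames = _read_gro(path)
    else:
        top, frames = _read_pdb(path)
    if topology is not None:
        if not isinstance(topology, (list, tuple)):
            topology = read_topology(topology)
        topology = list(topology)
        if len(topology) != len(top):
            raise StructuralError(
                f"side-car topology has {len(topology)} atoms, file has {len(top)}")
        top = topology
    return Trajectory(topology=top, frames=frames)


def write_trajectory(traj: Trajectory, path: str | Path,
                     format: str | None = None) -> None:
    """Write a trajectory as multi-frame XYZ, multi-model PDB or GRO."""
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        _write_xyz(traj, path)
    elif fmt == "gro":
        _write_gro(traj, path)
    else:
        _write_pdb(traj, path)


# -- XYZ: n_atoms / comment ("time=<ps>") / element x y z  (nm) --------------

def _read_xyz(path: str | Path) -> tuple[list[AtomRecord], list[Frame]]:
    frames: list[Frame] = []
    top: list[AtomRecord] | None = None
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    nlines = len(lines)
    while ln < nlines:
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError:
            raise ParseError(f"{path}: line {ln + 1}: expected atom count, "
                             f"got {lines[ln].strip()!r}")
        if ln + 1 + n >= nlines + 1:
            raise ParseError(f"{path}: line {ln + 1}: truncated frame "
                             f"(need {n} atom lines)")
        comment = lines[ln + 1].strip()
        time = None
        for token in comment.replace(",", " ").split():
            if token.startswith("time="):
                try:
                    time = float(token[5:])
                except ValueError:
                    pass
        elements: list[str] = []
        coords = np.empty((n, 3))
        for i in range(n):
            parts = lines[ln + 2 + i].split()
            if len(parts) < 4:
                raise ParseError(f"{path}: line {ln + 3 + i}: expected "
                                 f"'element x y z', got {lines[ln + 2 + i].rstrip()!r}")
            elements.append(parts[0])
            try:
                coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise ParseError(f"{path}: line {ln + 3 + i}: {exc}") from exc
        if top is None:
            top = [default_atom(e, molecule_id=i) for i, e in enumerate(elements)]
        elif len(elements) != len(top):
            raise StructuralError(
                f"{path}: line {ln + 1}: frame has {len(elements)} atoms, "
                f"first frame had {len(top)}")
        frames.append(Frame(coordinates=coords, time=time))
        ln += 2 + n
    if top is None:
        raise ParseError(f"{path}: no frames found")
    return top, frames


def _write_xyz(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, fr in enumerate(traj.frames):
            fh.write(f"{traj.n_atoms}\n")
            t = fr.time if fr.time is not None else float(k)
            fh.write(f"frame {k} time={t:g}\n")
            for a, xyz in zip(traj.topology, fr.coordinates):
                fh.write(f"{a.element:<3s} {xyz[0]:15.9f} {xyz[1]:15.9f} {xyz[2]:15.9f}\n")


# -- GRO: fixed-column, nm, single- or multi-frame ---------------------------

def _read_gro(path: str | Path) -> tuple[list[AtomRecord], list[Frame]]:
    top: list[AtomRecord] | None = None
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    nlines = len(lines)
    while ln < nlines:
        if not lines[ln].strip():
            ln += 1
            continue
        title = lines[ln].rstrip("\n")
        time = None
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        try:
            n = int(lines[ln + 1].strip())
        except (ValueError, IndexError):
            raise ParseError(f"{path}: line {ln + 2}: expected atom count")
        if ln + 2 + n + 1 > nlines:
            raise ParseError(f"{path}: line {ln + 1}: truncated frame")
        coords = np.empty((n, 3))
        elements: list[str] = []
        names: list[str] = []
        resids: list[int] = []
        resnames: list[str] = []
        for i in range(n):
            line = lines[ln + 2 + i]
            try:
                resids.append(int(line[0:5]))
                resnames.append(line[5:10].strip())
                name = line[10:15].strip()
                names.append(name)
                coords[i] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            except ValueError as exc:
                raise ParseError(f"{path}: line {ln + 3 + i}: {exc}") from exc
            elements.append(_element_from_name(name))
        box_parts = lines[ln + 2 + n].split()
        box = np.array([float(v) for v in box_parts[:3]]) if len(box_parts) >= 3 else None
        if top is None:
            top = [
                default_atom(e, name=nm, molecule_id=rid, role=_guess_role(rn))
                for e, nm, rid, rn in zip(elements, names, resids, resnames)
            ]
        elif n != len(top):
            raise StructuralError(f"{path}: line {ln + 2}: frame has {n} atoms, "
                                  f"first frame had {len(top)}")
        frames.append(Frame(coordinates=coords, box=box, time=time))
        ln += 2 + n + 1
    if top is None:
        raise ParseError(f"{path}: no frames found")
    return top, frames


def _write_gro(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, fr in enumerate(traj.frames):
            t = fr.time if fr.time is not None else float(k)
            fh.write(f"edchiro trajectory t= {t:g}\n{traj.n_atoms}\n")
            for i, (a, xyz) in enumerate(zip(traj.topology, fr.coordinates)):
                resname = {"solvent": "SOL", "ion": "ION"}.get(a.role, "MOL")
                fh.write(f"{(a.molecule_id % 100000):5d}{resname:<5s}"
                         f"{a.name[:5]:>5s}{((i + 1) % 100000):5d}"
                         f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}\n")
            box = fr.box if fr.box is not None else np.zeros(3)
            fh.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")


def _element_from_name(name: str) -> str:
    stripped = name.lstrip("0123456789")
    if not stripped:
        return "C"
    if len(stripped) >= 2 and stripped[:2].capitalize() in _DEFAULT_MASSES:
        return stripped[:2].capitalize()
    return stripped[0].upper()


# -- PDB via MDAnalysis ------------------------------------------------------

def _read_pdb(path: str | Path) -> tuple[list[AtomRecord], list[Frame]]:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # noqa: BLE001 - library raises various types
            raise ParseError(f"{path}: PDB parse failed: {exc}") from exc
        top = []
        for atom in u.atoms:
            el = getattr(atom, "element", "") or _element_from_name(atom.name)
            el = el.capitalize() if len(el) > 1 else el.upper()
            resname = getattr(atom, "resname", "MOL")
            top.append(default_atom(
                el, name=atom.name, molecule_id=int(atom.resid),
                role=_guess_role(resname)))
        frames = []
        for ts in u.trajectory:
            box = None
            if ts.dimensions is not None and np.any(ts.dimensions[:3] > 0):
                box = np.asarray(ts.dimensions[:3], dtype=float) * 0.1
            frames.append(Frame(coordinates=ts.positions.astype(float) * 0.1,
                                box=box, time=float(ts.time)))
    return top, frames


def _write_pdb(traj: Trajectory, path: str | Path) -> None:
    import MDAnalysis as mda

    n = traj.n_atoms
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           trajectory=True)
    resnames = [{"solvent": "SOL", "ion": "ION"}.get(a.role, "MOL")
                for a in traj.topology]
    u.add_TopologyAttr("names", [a.name[:4] for a in traj.topology])
    u.add_TopologyAttr("elements", [a.element for a in traj.topology])
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", [a.molecule_id + 1 for a in traj.topology])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n, multiframe=True) as w:
            for fr in traj.frames:
                u.atoms.positions = fr.coordinates * 10.0  # nm -> Å
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# periodic re-imaging (optional pass; off by default in the pipeline)
# ---------------------------------------------------------------------------

def reimage_molecules(frame: Frame, topology: Sequence[AtomRecord]) -> Frame:
    """Shift whole molecules by box vectors so their centroids fall inside
    the primary box.  Requires ``frame.box``; molecules are keyed on
    ``molecule_id`` and never split."""
    if frame.box is None:
        raise StructuralError("re-imaging needs box lengths")
    coords = frame.coordinates.copy()
    mol_ids = np.array([a.molecule_id for a in topology])
    for mid in np.unique(mol_ids):
        mask = mol_ids == mid
        centroid = coords[mask].mean(axis=0)
        shift = np.floor(centroid / frame.box) * frame.box
        coords[mask] -= shift
    return Frame(coordinates=coords, box=frame.box.copy(), time=frame.time)
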