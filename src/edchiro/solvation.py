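"""Solvation-shell extraction and structural descriptors.

The solvation shell of a non-spherical solute is defined through an
ellipsoidal metric: an ellipsoid is fitted once to the (frozen) solute via
its gyration tensor — semi-axis_k = sqrt(5 λ_k), the uniform-solid-
ellipsoid convention — and each water molecule is ranked by the squared
ellipsoidal distance of its oxygen,

    d² = Σ_k ((x − centre) · axis_k / a_k)² ,

which is 1 exactly on the ellipsoid surface.  The N lowest-d² waters
(molecules kept whole) form the shell; N itself can come from a
site-counting heuristic: (interaction sites per ligand − sites consumed by
intramolecular contacts) × n_ligands, e.g. (9 − 2) × 18 = 126 for a
glutathione-protected Au25 cluster.

Also here: mass-weighted radius of gyration, Shrake–Rupley solvent-
accessible surface area with a deterministic Fibonacci sphere mesh, and a
geometric hydrogen-bond count (donor–acceptor distance + H–donor–acceptor
angle criterion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .trajectory import AtomRecord, DegeneracyError, Frame, select_atoms

__all__ = [
    "EllipsoidModel",
    "ShellSelection",
    "ShellShortageError",
    "fit_ellipsoid",
    "ellipsoidal_sq_distance",
    "select_shell",
    "shell_size_heuristic",
    "radius_of_gyration",
    "sasa",
    "count_hbonds",
]


class ShellShortageError(Exception):
    """Fewer water molecules available than the shell size requested."""


@dataclass
class EllipsoidModel:
    """Centre (nm), orthonormal principal axes (rows), semi-axes a ≥ b ≥ c (nm)."""

    centre: np.ndarray
    axes: np.ndarray        # (3, 3), rows orthonormal
    semi_axes: np.ndarray   # descending, nm

    def __post_init__(self) -> None:
        if np.any(self.semi_axes <= 0):
            raise DegeneracyError(
                f"semi-axes must be positive, got {self.semi_axes}")


@dataclass
class ShellSelection:
    """Ordered water molecule ids and their squared ellipsoidal distances."""

    molecule_ids: np.ndarray
    sq_distances: np.ndarray  # non-decreasing
    atom_indices: np.ndarray  # solute + selected water atoms, original order


def fit_ellipsoid(coordinates: np.ndarray,
                  masses: np.ndarray | None = None) -> EllipsoidModel:
    """Fit the ellipsoid describing a point cloud via its gyration tensor.

    centre = (mass-weighted) centroid; the gyration-tensor eigenvalues λ_k
    give semi-axes sqrt(5 λ_k) (exact for a uniform solid ellipsoid).
    """
    x = np.asarray(coordinates, dtype=float)
    if x.shape[0] < 4:
        raise DegeneracyError("ellipsoid fit needs >= 4 atoms")
    w = np.ones(x.shape[0]) if masses is None else np.asarray(masses, dtype=float)
    centre = np.average(x, axis=0, weights=w)
    d = x - centre
    gyr = (w[:, None] * d).T @ d / w.sum()
    lam, vec = np.linalg.eigh(gyr)          # ascending
    if lam[0] <= 1e-12 * max(lam[-1], 1.0):
        raise DegeneracyError("coplanar or degenerate input: gyration tensor "
                              "has a (near-)zero eigenvalue")
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    axes = vec[:, order].T
    # right-handed, sign-fixed axes for reproducibility
    for row in axes:
        nz = np.flatnonzero(np.abs(row) > 1e-12)
        if nz.size and row[nz[0]] < 0:
            row *= -1.0
    if np.linalg.det(axes) < 0:
        axes[2] *= -1.0
    return EllipsoidModel(centre=centre, axes=axes,
                          semi_axes=np.sqrt(5.0 * lam))


def ellipsoidal_sq_distance(points: np.ndarray,
                            ellipsoid: EllipsoidModel) -> np.ndarray | float:
    """Squared ellipsoidal metric; 1 on the surface, 0 at the centre.

    Accepts a single 3-vector or an (n, 3) array.
    """
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    local = (p - ellipsoid.centre) @ ellipsoid.axes.T
    d2 = ((local / ellipsoid.semi_axes) ** 2).sum(axis=1)
    return float(d2[0]) if single else d2


def shell_size_heuristic(sites_per_ligand: int, intramolecular_sites: int,
                         n_ligands: int) -> int:
    """Shell size from ligand interaction-site counting.

    N = (sites_per_ligand − intramolecular_sites) × n_ligands: sites engaged
    in intramolecular contacts (estimated from the mean intramolecular
    H-bond count per ligand) are unavailable to water.
    """
    if not sites_per_ligand > intramolecular_sites >= 0:
        raise ValueError("need sites_per_ligand > intramolecular_sites >= 0")
    if n_ligands < 1:
        raise ValueError("need at least one ligand")
    n = (sites_per_ligand - intramolecular_sites) * n_ligands
    if n <= 0:
        raise ValueError(f"heuristic produced non-positive shell size {n}")
    return n


def select_shell(frame: Frame, topology: Sequence[AtomRecord],
                 ellipsoid: EllipsoidModel, n: int,
                 oxygen_element: str = "O") -> ShellSelection:
    """Select the ``n`` water molecules closest to the solute in the
    ellipsoidal metric.

    Whole molecules are ranked by their oxygen atom's squared ellipsoidal
    distance; ties break on molecule_id.  The returned atom index set is
    solute atoms plus all atoms of the selected waters, in original order.
    """
    solvent_idx = select_atoms(topology, role="solvent")
    mol_ids = np.array([topology[i].molecule_id for i in solvent_idx])
    is_o = np.array([topology[i].element == oxygen_element for i in solvent_idx])
    o_idx = solvent_idx[is_o]
    o_mols = mol_ids[is_o]
    if len(o_idx) < n:
        raise ShellShortageError(
            f"requested {n} waters but frame has {len(o_idx)}")
    d2 = ellipsoidal_sq_distance(frame.coordinates[o_idx], ellipsoid)
    order = np.lexsort((o_mols, d2))[:n]
    sel_mols = o_mols[order]
    sel_d2 = d2[order]
    solute_idx = select_atoms(topology, role="solute")
    keep = set(sel_mols.tolist())
    water_atoms = np.array([i for i in solvent_idx
                            if topology[i].molecule_id in keep], dtype=int)
    atom_indices = np.sort(np.concatenate([solute_idx, water_atoms]))
    return ShellSelection(molecule_ids=sel_mols, sq_distances=sel_d2,
                          atom_indices=atom_indices)


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def radius_of_gyration(coordinates: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration about the centre of mass, nm."""
    x = np.asarray(coordinates, dtype=float)
    m = np.asarray(masses, dtype=float)
    if x.shape[0] < 1 or np.any(m <= 0):
        raise ValueError("need >= 1 atom with positive masses")
    com = np.average(x, axis=0, weights=m)
    return float(np.sqrt((m * ((x - com) ** 2).sum(axis=1)).sum() / m.sum()))


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere mesh (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(coordinates: np.ndarray, vdw_radii: np.ndarray,
         probe_radius: float = 0.14, n_points: int = 960) -> float:
    """Shrake–Rupley solvent-accessible surface area, nm².

    Each atom's accessible sphere (radius vdW + probe) is sampled with
    ``n_points`` Fibonacci-lattice points; a point is accessible when it
    lies outside every other atom's accessible sphere.  Deterministic.
    """
    if n_points < 16:
        raise ValueError(f"n_points >= 16 required for a meaningful estimate, "
                         f"got {n_points}")
    x = np.asarray(coordinates, dtype=float)
    r = np.asarray(vdw_radii, dtype=float) + probe_radius
    if np.any(r <= probe_radius):
        raise ValueError("vdW radii must be positive")
    n_atoms = x.shape[0]
    mesh = fibonacci_sphere(n_points)
    tree = cKDTree(x)
    r_max = r.max()
    area = 0.0
    for i in range(n_atoms):
        pts = x[i] + r[i] * mesh
        neighbours = [j for j in tree.query_ball_point(x[i], r[i] + r_max)
                      if j != i]
        if neighbours:
            d2 = ((pts[:, None, :] - x[neighbours][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (r[neighbours] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        area += 4.0 * np.pi * r[i] ** 2 * frac
    return float(area)


def count_hbonds(frame: Frame, topology: Sequence[AtomRecord],
                 donors: np.ndarray, acceptors: np.ndarray,
                 donor_hydrogens: dict[int, Sequence[int]],
                 d_max: float = 0.35, angle_max: float = 30.0,
                 scope: str = "intra_solute") -> int:
    """Geometric hydrogen-bond count.

    A donor–acceptor pair is bonded when the heavy-atom distance is
    ≤ ``d_max`` (nm) and, for at least one hydrogen attached to the donor,
    the H–donor–acceptor angle is ≤ ``angle_max`` degrees.  ``scope``
    restricts the pairs counted: ``intra_solute`` (both solute, different
    molecules), ``solute_water`` (one solute, one solvent) or
    ``water_water``.  Donor == acceptor atoms and same-molecule pairs are
    never counted.
    """
    if scope not in ("intra_solute", "solute_water", "water_water"):
        raise ValueError(f"unknown scope {scope!r}")
    coords = frame.coordinates
    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    for d in donors:
        if d not in donor_hydrogens or len(donor_hydrogens[d]) == 0:
            raise ValueError(f"donor atom {d} has no attached hydrogen")
    cos_max = np.cos(np.radians(angle_max))
    count = 0
    acc_tree = cKDTree(coords[acceptors])
    for d in donors:
        near = acc_tree.query_ball_point(coords[d], d_max)
        for ai in near:
            a = int(acceptors[ai])
            if a == d:
                continue
            rec_d, rec_a = topology[d], topology[a]
            if rec_d.molecule_id == rec_a.molecule_id:
                continue
            if scope == "intra_solute":
                if not (rec_d.role == "solute" and rec_a.role == "solute"):
                    continue
            elif scope == "solute_water":
                if {rec_d.role, rec_a.role} != {"solute", "solvent"}:
                    continue
            else:
                if not (rec_d.role == "solvent" and rec_a.role == "solvent"):
                    continue
            da = coords[a] - coords[d]
            nda = np.linalg.norm(da)
            if nda > d_max or nda == 0:
                continue
            for h in donor_hydrogens[int(d)]:
                dh = coords[h] - coords[d]
                ndh = np.linalg.norm(dh)
                if ndh == 0:
                    continue
                if (dh @ da) / (ndh * nda) >= cos_max:
                    count += 1
                    break
    return count


def descriptor_series(traj, subset: np.ndarray | None = None,
                      probe_radius: float = 0.14,
                      sasa_points: int = 240) -> np.ndarray:
    """Per-frame (Rg, SASA) table for the solute subset — the descriptor
    time-series export.  H-bond columns require donor tables and are
    produced by the pipeline layer."""
    if subset is None:
        subset = select_atoms(traj.topology, role="solute")
    masses = np.array([traj.topology[i].mass for i in subset])
    radii = np.array([traj.topology[i].vdw_radius for i in subset])
    out = np.empty((traj.n_frames, 2))
    for k, fr in enumerate(traj.frames):
        x = fr.coordinates[subset]
        out[k, 0] = radius_of_gyration(x, masses)
        out[k, 1] = sasa(x, radii, probe_radius=probe_radius,
                         n_points=sasa_points)
    return out
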