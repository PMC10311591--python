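"""Synthetic-data generators with planted ground truth.

Real inputs to this pipeline — hundreds of nanoseconds of solvated-cluster
MD and per-conformer TDDFT stick spectra — are far beyond desk scale, so
every stage is exercised on generated data whose ground truth is known by
construction:

* :func:`make_planted_trajectory` — frames built as a fixed reference
  structure plus a few orthonormal internal displacement modes whose
  amplitudes are drawn from a Gaussian-basin mixture, plus isotropic noise.
  The planted modes, per-frame basin assignment and exact inter-basin ΔG°
  (−RT ln of occupancy ratios) come back as ground truth.
* :func:`make_solvated_frame` — a solute realizing a requested ellipsoid
  plus rigid 3-site waters whose oxygens sit at assigned squared
  ellipsoidal distances; the distance-sorted molecule ranking is the oracle
  for shell selection.
* :func:`make_stick_spectra` — reproducible labelled rotatory-strength
  sticks, with a solvent-free variant (all water-labelled lines dropped)
  for with/without-shell comparisons.

Every generator is a pure function of its spec and seed (bit-reproducible)
and can emit both standard-format data files and a JSON ground-truth
side-car.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import R_KJ, T_DEFAULT
from .reference import reference_conformers  # noqa: F401  (re-export)
from .solvation import EllipsoidModel
from .chiroptics import StickSpectrum
from .trajectory import AtomRecord, Frame, Trajectory, default_atom

__all__ = [
    "PlantedLandscapeSpec",
    "PlantedShellSpec",
    "make_planted_trajectory",
    "make_solvated_frame",
    "make_stick_spectra",
    "solvent_free_variant",
    "reference_conformers",
]


@dataclass
class PlantedLandscapeSpec:
    """Conditions for a planted-mode, multi-basin trajectory.

    ``basin_centres`` live in mode space (n_basins × n_modes, nm);
    ``occupancies`` must sum to 1; ``widths`` are per-basin Gaussian σ (nm).
    ``mode_variances`` are only used when ``basin_centres`` is None (single
    zero-centred basin per mode).  ``noise`` is the isotropic per-coordinate
    variance (nm²) added on top of the planted modes.
    """

    n_atoms: int = 30
    n_frames: int = 5000
    n_modes: int = 2
    basin_centres: np.ndarray | None = None
    occupancies: Sequence[float] = (1.0,)
    widths: Sequence[float] = (0.06,)
    noise: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancies, dtype=float)
        if not np.isclose(occ.sum(), 1.0):
            raise ValueError(f"occupancies must sum to 1, got {occ.sum()}")
        if np.any(np.asarray(self.widths) < 0):
            raise ValueError("widths must be non-negative")
        if self.basin_centres is not None:
            self.basin_centres = np.atleast_2d(
                np.asarray(self.basin_centres, dtype=float))
            if self.basin_centres.shape != (len(occ), self.n_modes):
                raise ValueError("basin_centres must be (n_basins, n_modes)")


@dataclass
class GroundTruth:
    """Planted facts recorded by :func:`make_planted_trajectory`."""

    modes: np.ndarray              # (n_modes, 3·n_atoms), orthonormal
    basin_of_frame: np.ndarray     # (n_frames,) int
    basin_centres: np.ndarray      # (n_basins, n_modes)
    occupancies: np.ndarray
    expected_delta_g: np.ndarray   # kJ/mol vs the most occupied basin
    reference: np.ndarray          # (n_atoms, 3)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "modes": self.modes.tolist(),
            "basin_of_frame": self.basin_of_frame.tolist(),
            "basin_centres": self.basin_centres.tolist(),
            "occupancies": self.occupancies.tolist(),
            "expected_delta_g": self.expected_delta_g.tolist(),
            "reference": self.reference.tolist(),
        }))


def _rigid_body_basis(reference: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid-body directions (3 translations,
    3 infinitesimal rotations) at a reference structure."""
    n = reference.shape[0]
    centred = reference - reference.mean(axis=0)
    basis = []
    for ax in range(3):
        v = np.zeros((n, 3))
        v[:, ax] = 1.0
        basis.append(v.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        basis.append(np.cross(e, centred).ravel())
    q, _ = np.linalg.qr(np.array(basis).T)
    return q.T  # (6, 3n)


def make_planted_trajectory(spec: PlantedLandscapeSpec,
                            temperature: float = T_DEFAULT,
                            ) -> tuple[Trajectory, GroundTruth]:
    """Generate a trajectory with known internal modes and basin structure.

    Frames are ``reference + Σ_k c_k(t)·mode_k + noise`` with the mode
    amplitudes c(t) drawn from the basin mixture.  Modes are random
    orthonormal 3n-directions projected out of the rigid-body subspace, so
    they are genuine internal motions and survive superposition.
    """
    rng = np.random.default_rng(spec.seed)
    reference = rng.uniform(-0.5, 0.5, size=(spec.n_atoms, 3))
    dim = 3 * spec.n_atoms

    rigid = _rigid_body_basis(reference)
    raw = rng.standard_normal((spec.n_modes, dim))
    raw -= (raw @ rigid.T) @ rigid
    q, _ = np.linalg.qr(raw.T)
    modes = q.T[: spec.n_modes]

    occ = np.asarray(spec.occupancies, dtype=float)
    n_basins = len(occ)
    centres = (spec.basin_centres if spec.basin_centres is not None
               else np.zeros((n_basins, spec.n_modes)))
    widths = np.broadcast_to(np.asarray(spec.widths, dtype=float), (n_basins,))

    basin_of_frame = rng.choice(n_basins, size=spec.n_frames, p=occ)
    amplitudes = (centres[basin_of_frame]
                  + widths[basin_of_frame, None]
                  * rng.standard_normal((spec.n_frames, spec.n_modes)))
    displacements = amplitudes @ modes  # (n_frames, 3n)
    if spec.noise > 0:
        displacements = displacements + (
            np.sqrt(spec.noise) * rng.standard_normal((spec.n_frames, dim)))

    frames = [Frame(coordinates=reference + disp.reshape(-1, 3), time=float(t))
              for t, disp in enumerate(displacements)]
    topology = [default_atom("C", name=f"C{i}", molecule_id=0, role="solute")
                for i in range(spec.n_atoms)]

    rt = R_KJ * temperature
    ref_occ = occ.max()
    expected_dg = -rt * np.log(occ / ref_occ)
    truth = GroundTruth(modes=modes, basin_of_frame=basin_of_frame,
                        basin_centres=np.asarray(centres, dtype=float),
                        occupancies=occ, expected_delta_g=expected_dg,
                        reference=reference)
    return Trajectory(topology=topology, frames=frames), truth


# ---------------------------------------------------------------------------
# solvated frames
# ---------------------------------------------------------------------------

@dataclass
class PlantedShellSpec:
    """Conditions for a single solvated frame with known water ranking."""

    semi_axes: Sequence[float] = (1.2, 1.0, 0.8)  # nm, a >= b >= c
    n_solute_atoms: int = 200
    sq_distances: Sequence[float] = ()            # one per water, >= 0
    seed: int = 0

    def __post_init__(self) -> None:
        sa = np.asarray(self.semi_axes, dtype=float)
        if np.any(sa <= 0) or np.any(np.diff(sa) > 0):
            raise ValueError("semi_axes must be positive and non-increasing")
        if np.any(np.asarray(self.sq_distances) < 0):
            raise ValueError("assigned squared distances must be >= 0")


def make_solvated_frame(spec: PlantedShellSpec,
                        ) -> tuple[Frame, list[AtomRecord], EllipsoidModel,
                                   np.ndarray]:
    """Build one solvated frame with waters at assigned ellipsoidal distances.

    Returns ``(frame, topology, ellipsoid, ranking)`` where ``ellipsoid`` is
    the exact planted model (axis-aligned at the origin) and ``ranking`` is
    the ground-truth molecule-id order (ascending d², ties by molecule id).
    """
    rng = np.random.default_rng(spec.seed)
    a = np.asarray(spec.semi_axes, dtype=float)
    ellipsoid = EllipsoidModel(centre=np.zeros(3), axes=np.eye(3),
                               semi_axes=a.copy())

    # solute: uniform points inside the planted ellipsoid
    pts = []
    while len(pts) < spec.n_solute_atoms:
        cand = rng.uniform(-1.0, 1.0, size=(4 * spec.n_solute_atoms, 3))
        inside = (cand ** 2).sum(axis=1) <= 1.0
        pts.extend(cand[inside])
    solute = np.array(pts[: spec.n_solute_atoms]) * a

    d2 = np.asarray(spec.sq_distances, dtype=float)
    n_waters = len(d2)
    topology = [default_atom("Au", name=f"AU{i}", molecule_id=0, role="solute")
                for i in range(spec.n_solute_atoms)]
    coords = [solute]
    oh = 0.09572  # O-H bond length, nm
    for w in range(n_waters):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        # oxygen at exact ellipsoidal distance sqrt(d2) along direction u
        oxy = np.sqrt(d2[w]) * u * a
        h1 = oxy + oh * _random_unit(rng)
        h2 = oxy + oh * _random_unit(rng)
        coords.append(np.array([oxy, h1, h2]))
        mid = w + 1
        topology.append(default_atom("O", name="OW", molecule_id=mid,
                                     role="solvent"))
        topology.append(default_atom("H", name="HW1", molecule_id=mid,
                                     role="solvent"))
        topology.append(default_atom("H", name="HW2", molecule_id=mid,
                                     role="solvent"))
    frame = Frame(coordinates=np.vstack(coords))
    ranking = np.lexsort((np.arange(1, n_waters + 1), d2)) + 1
    return frame, topology, ellipsoid, np.asarray(ranking, dtype=int)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# stick spectra
# ---------------------------------------------------------------------------

def make_stick_spectra(n_conformers: int, n_lines: int = 40,
                       energy_range: tuple[float, float] = (1.5, 6.0),
                       strength_scale: float = 1.0,
                       labels: Sequence[str] = ("AuNC", "H2O"),
                       water_fraction: float = 0.3,
                       seed: int = 0) -> list[StickSpectrum]:
    """Reproducible labelled stick spectra for ``n_conformers`` conformers.

    Each line gets an (initial, final) fragment-label pair; a line involves
    the solvent fragment with probability ``water_fraction`` on each side.
    Strengths are zero-mean Gaussians of scale ``strength_scale`` (units
    opaque, carried linearly).
    """
    lo, hi = energy_range
    if not hi > lo > 0:
        raise ValueError(f"invalid energy range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    spectra = []
    solvent = labels[1] if len(labels) > 1 else "H2O"
    cluster = labels[0]
    for c in range(n_conformers):
        energies = np.sort(rng.uniform(lo, hi, size=n_lines))
        strengths = strength_scale * rng.standard_normal(n_lines)
        init = [solvent if rng.random() < water_fraction else cluster
                for _ in range(n_lines)]
        fin = [solvent if rng.random() < water_fraction else cluster
               for _ in range(n_lines)]
        spectra.append(StickSpectrum(
            energies=energies, strengths=strengths,
            conformer_id=f"C{c + 1}", initial_labels=init, final_labels=fin))
    return spectra


def solvent_free_variant(sticks: StickSpectrum,
                         solvent_label: str = "H2O") -> StickSpectrum:
    """Drop every line whose initial or final fragment is the solvent —
    the shell-removed counterpart for with/without-solvent comparisons."""
    if sticks.initial_labels is None or sticks.final_labels is None:
        raise ValueError("sticks must be labelled")
    mask = np.array([li != solvent_label and lf != solvent_label
                     for li, lf in zip(sticks.initial_labels,
                                       sticks.final_labels)])
    return StickSpectrum(
        energies=sticks.energies[mask], strengths=sticks.strengths[mask],
        conformer_id=sticks.conformer_id + "-dry",
        initial_labels=[l for l, m in zip(sticks.initial_labels, mask) if m],
        final_labels=[l for l, m in zip(sticks.final_labels, mask) if m])
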