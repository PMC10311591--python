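"""Essential dynamics: covariance analysis of Cartesian fluctuations.

Diagonalizing the covariance matrix of the (aligned, centred) atomic
coordinates of an MD trajectory yields eigenvalues — the mean-square
fluctuations along orthogonal internal directions — and eigenvectors, the
principal directions of internal motion.  A handful of leading eigenpairs
("essential" modes) typically carries most of the fluctuation; projecting
each frame onto the first two gives the essential plane (proj-1, proj-2)
on which conformational landscapes are built.

The covariance is over unweighted Cartesian coordinates.  Because the
number of frames is usually far below 3·n_atoms, the eigensystem is
obtained from an SVD of the centred data matrix rather than by forming
the 3n × 3n covariance explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .trajectory import StructuralError, Trajectory, superpose

__all__ = [
    "CovarianceModel",
    "EssentialProjection",
    "InsufficientDataError",
    "covariance_model",
    "explained_fraction",
    "project",
    "align_frames",
]


class InsufficientDataError(Exception):
    """Raised when a computation needs more frames than were supplied."""


@dataclass
class CovarianceModel:
    """Eigensystem of the coordinate covariance matrix.

    Attributes
    ----------
    mean_structure : (n_sel, 3) array, nm — iteratively refined mean of the
        subset atoms after alignment.
    eigenvalues : descending, nm² — mean-square fluctuation per mode.
    eigenvectors : (n_modes, 3·n_sel) orthonormal rows.
    subset : atom indices (into the full topology) the model was built on.
    n_frames : number of frames used.
    """

    mean_structure: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    subset: np.ndarray
    n_frames: int

    @property
    def trace(self) -> float:
        return float(self.eigenvalues.sum())

    def save(self, path: str | Path) -> None:
        """Serialize to a plain-text key-value container (npz-free)."""
        with open(path, "w") as fh:
            fh.write("# edchiro covariance model v1\n")
            fh.write(f"n_frames {self.n_frames}\n")
            fh.write("subset " + " ".join(map(str, self.subset)) + "\n")
            fh.write("mean_structure "
                     + " ".join(f"{v:.12g}" for v in self.mean_structure.ravel()) + "\n")
            fh.write("eigenvalues "
                     + " ".join(f"{v:.12g}" for v in self.eigenvalues) + "\n")
            for row in self.eigenvectors:
                fh.write("eigenvector " + " ".join(f"{v:.12g}" for v in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "CovarianceModel":
        n_frames = 0
        subset = mean = eigenvalues = None
        vecs: list[np.ndarray] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                key, _, rest = line.partition(" ")
                vals = rest.split()
                if key == "n_frames":
                    n_frames = int(vals[0])
                elif key == "subset":
                    subset = np.array([int(v) for v in vals])
                elif key == "mean_structure":
                    mean = np.array([float(v) for v in vals]).reshape(-1, 3)
                elif key == "eigenvalues":
                    eigenvalues = np.array([float(v) for v in vals])
                elif key == "eigenvector":
                    vecs.append(np.array([float(v) for v in vals]))
        return cls(mean_structure=mean, eigenvalues=eigenvalues,
                   eigenvectors=np.array(vecs), subset=subset, n_frames=n_frames)


@dataclass
class EssentialProjection:
    """Per-frame components on the leading modes: (n_frames, k), nm."""

    components: np.ndarray

    @property
    def labels(self) -> list[str]:
        return [f"proj-{j + 1}" for j in range(self.components.shape[1])]

    def save(self, path: str | Path) -> None:
        header = "frame " + " ".join(self.labels)
        data = np.column_stack([np.arange(len(self.components)), self.components])
        np.savetxt(path, data, header=header,
                   fmt=["%d"] + ["%.9g"] * self.components.shape[1])


def align_frames(traj: Trajectory, subset: np.ndarray,
                 n_passes: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively superpose all frames onto their running mean.

    Pass 0 fits every frame to frame 0; each refinement pass re-fits to the
    mean of the previous pass.  Returns ``(aligned, mean)`` where aligned is
    ``(n_frames, n_sel, 3)`` of the subset atoms and mean is its average.
    """
    coords = traj.coordinates()[:, subset, :]
    ref = coords[0]
    aligned = coords
    for _ in range(n_passes + 1):
        out = np.empty_like(coords)
        for i, frame in enumerate(aligned):
            _, _, out[i] = superpose(frame, ref)
        aligned = out
        ref = aligned.mean(axis=0)
    # final pass so every frame is fitted to the *returned* mean, keeping
    # project() (which fits to mean_structure) exactly consistent
    out = np.empty_like(coords)
    for i, frame in enumerate(aligned):
        _, _, out[i] = superpose(frame, ref)
    return out, ref


def _fix_signs(vectors: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Make each eigenvector's first component of magnitude > tol positive."""
    out = vectors.copy()
    for row in out:
        nz = np.flatnonzero(np.abs(row) > tol)
        if nz.size and row[nz[0]] < 0:
            row *= -1.0
    return out


def covariance_model(traj: Trajectory, subset: np.ndarray | None = None,
                     align: bool = True, n_passes: int = 2) -> CovarianceModel:
    """Build the essential-dynamics eigensystem for a trajectory subset.

    When ``align`` is true every frame is least-squares superposed onto the
    iteratively refined mean (``n_passes`` refinements) before the
    covariance is taken, removing global rotation/translation.
    """
    if traj.n_frames < 2:
        raise InsufficientDataError("covariance needs at least 2 frames")
    if subset is None:
        subset = np.arange(traj.n_atoms)
    subset = np.asarray(subset, dtype=int)

    if align:
        aligned, mean = align_frames(traj, subset, n_passes=n_passes)
    else:
        aligned = traj.coordinates()[:, subset, :]
        mean = aligned.mean(axis=0)

    x = aligned.reshape(traj.n_frames, -1) - mean.ravel()
    # SVD route: eigenvalues of X^T X / n are singular values squared / n
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    eigenvalues = (s * s) / traj.n_frames
    eigenvalues = np.clip(eigenvalues, 0.0, None)
    eigenvectors = _fix_signs(vt)
    return CovarianceModel(mean_structure=mean, eigenvalues=eigenvalues,
                           eigenvectors=eigenvectors, subset=subset,
                           n_frames=traj.n_frames)


def explained_fraction(model: CovarianceModel, k: int) -> float:
    """Fraction of the covariance trace carried by the top-``k`` modes."""
    n = len(model.eigenvalues)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    trace = model.trace
    if trace <= 0:
        raise ZeroDivisionError("covariance trace is zero; fraction undefined")
    return float(model.eigenvalues[:k].sum() / trace)


def project(traj: Trajectory, model: CovarianceModel, k: int = 2,
            ) -> EssentialProjection:
    """Project each frame onto the first ``k`` eigenvectors.

    Frames are superposed onto the stored mean structure, centred, and
    dotted with the modes; column j of the result has variance equal to
    eigenvalue j when the input is the trajectory the model came from.
    """
    if k > len(model.eigenvectors):
        raise ValueError(
            f"k={k} exceeds the {len(model.eigenvectors)} stored eigenvectors")
    coords = traj.coordinates()[:, model.subset, :]
    comps = np.empty((traj.n_frames, k))
    modes = model.eigenvectors[:k]
    mean_flat = model.mean_structure.ravel()
    for i, frame in enumerate(coords):
        _, _, fitted = superpose(frame, model.mean_structure)
        comps[i] = modes @ (fitted.ravel() - mean_flat)
    return EssentialProjection(components=comps)


def reconstruct(model: CovarianceModel, projection: EssentialProjection,
                ) -> np.ndarray:
    """Mean + Σ_j c_j v_j for each frame; inverse of :func:`project` when all
    modes are kept."""
    k = projection.components.shape[1]
    flat = projection.components @ model.eigenvectors[:k] + model.mean_structure.ravel()
    return flat.reshape(len(projection.components), -1, 3)
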