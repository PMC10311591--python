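"""Ensemble chiroptics: Boltzmann weights, Lorentzian broadening, weighted
spectral averaging, fragment-label decomposition, and the Hausdorff
chirality measure.

Electronic circular dichroism (ECD) is handled as discrete stick spectra —
(excitation energy in eV, signed rotatory strength, optional initial/final
fragment labels) — broadened with a unit-area Lorentzian of half-width at
half-maximum ε (default 0.15 eV):

    I(E) = Σ_k R_k · (1/π) · ε / ((E − E_k)² + ε²)   [strength per eV]

so that the integral of each line recovers its rotatory strength and
broadening is linear, hence commutes with ensemble averaging.  Conformer
ensembles are averaged with normalized Boltzmann weights
p_i ∝ exp(−ΔG°_i / RT); restricting to a subset of conformers re-derives
the weights from their ΔG° values rather than rescaling old probabilities.

The Hausdorff chirality measure (HCM) of a structure is the minimal
Hausdorff distance between the point set and its mirror image over all
proper rotations and translations, normalized by the set's diameter;
it vanishes exactly for achiral (e.g. planar) arrangements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .constants import R_KJ, T_DEFAULT
from .trajectory import DegeneracyError

__all__ = [
    "StickSpectrum",
    "BroadenedSpectrum",
    "WeightTable",
    "boltzmann_weights",
    "renormalize_subset",
    "broaden",
    "ensemble_average",
    "decompose_by_labels",
    "hausdorff_chirality_measure",
    "read_sticks",
    "write_sticks",
]

EPSILON_DEFAULT = 0.15  # eV, Lorentzian HWHM


@dataclass
class StickSpectrum:
    """Discrete rotatory-strength lines for one conformer.

    ``energies`` (eV) must be positive; ``strengths`` are signed and carried
    in their input units (e.g. 10⁻⁴⁰ cgs) — the package never converts them.
    ``initial_labels``/``final_labels`` optionally tag each line with the
    fragments (e.g. AuNC, H2O) its initial and final orbitals live on.
    """

    energies: np.ndarray
    strengths: np.ndarray
    conformer_id: str = ""
    initial_labels: list[str] | None = None
    final_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.strengths = np.asarray(self.strengths, dtype=float)
        if self.energies.shape != self.strengths.shape:
            raise ValueError("energies and strengths must have equal length")
        if np.any(self.energies <= 0):
            raise ValueError("excitation energies must be positive")
        if not np.all(np.isfinite(self.strengths)):
            raise ValueError("rotatory strengths must be finite")
        for lab in (self.initial_labels, self.final_labels):
            if lab is not None and len(lab) != len(self.energies):
                raise ValueError("label list length must match line count")

    @property
    def n_lines(self) -> int:
        return len(self.energies)


@dataclass
class BroadenedSpectrum:
    """Continuous signed intensity on a strictly increasing energy grid."""

    grid: np.ndarray       # eV
    intensity: np.ndarray  # strength-units per eV
    hwhm: float            # eV

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.grid.ndim != 1 or len(self.grid) < 2:
            raise ValueError("energy grid needs at least two points")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("energy grid must be strictly increasing")

    def integral(self) -> float:
        """Trapezoidal integral of the intensity over the grid."""
        return float(np.trapezoid(self.intensity, self.grid))

    def save(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([self.grid, self.intensity]),
                   header="energy_eV intensity", fmt="%.9g")


@dataclass
class WeightTable:
    """Conformer labels, ΔG° (kJ/mol) and normalized Boltzmann probabilities."""

    labels: list[str]
    delta_g: np.ndarray
    probabilities: np.ndarray
    temperature: float = T_DEFAULT

    def __getitem__(self, label: str) -> float:
        return float(self.probabilities[self.labels.index(label)])

    def as_dict(self) -> dict[str, float]:
        return {l: float(p) for l, p in zip(self.labels, self.probabilities)}

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# conformer dG_kJ_mol p_norm\n")
            for l, g, p in zip(self.labels, self.delta_g, self.probabilities):
                fh.write(f"{l} {g:.4f} {p:.6f}\n")


def boltzmann_weights(delta_g: Sequence[float],
                      temperature: float = T_DEFAULT,
                      labels: Sequence[str] | None = None) -> WeightTable:
    """Normalized Boltzmann probabilities from standard free energies.

    p_i = exp(−ΔG°_i/RT) / Σ_j exp(−ΔG°_j/RT), R = 8.314 J mol⁻¹ K⁻¹.
    Computed with a max-shift for numerical stability; invariant under a
    constant shift of all ΔG°.
    """
    dg = np.asarray(delta_g, dtype=float)
    if dg.size == 0:
        raise ValueError("empty ΔG° list")
    if not np.all(np.isfinite(dg)):
        raise ValueError("ΔG° values must be finite")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    rt = R_KJ * temperature
    w = np.exp(-(dg - dg.min()) / rt)
    p = w / w.sum()
    if labels is None:
        labels = [f"C{i + 1}" for i in range(dg.size)]
    return WeightTable(labels=list(labels), delta_g=dg, probabilities=p,
                       temperature=temperature)


def renormalize_subset(table: WeightTable, keep: Sequence[str]) -> WeightTable:
    """Restrict to ``keep`` and re-derive weights from the stored ΔG°."""
    if not keep:
        raise ValueError("subset must be non-empty")
    missing = [k for k in keep if k not in table.labels]
    if missing:
        raise KeyError(f"unknown conformer label(s): {missing}")
    idx = [table.labels.index(k) for k in keep]
    return boltzmann_weights(table.delta_g[idx], temperature=table.temperature,
                             labels=[table.labels[i] for i in idx])


# ---------------------------------------------------------------------------
# broadening and averaging
# ---------------------------------------------------------------------------

def broaden(sticks: StickSpectrum, grid: np.ndarray,
            epsilon: float = EPSILON_DEFAULT) -> BroadenedSpectrum:
    """Lorentzian broadening with HWHM ``epsilon``; unit area per unit
    rotatory strength, so Σ R_k is conserved under integration."""
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("energy grid needs at least two points")
    de = grid[:, None] - sticks.energies[None, :]
    lor = (epsilon / np.pi) / (de * de + epsilon * epsilon)
    intensity = lor @ sticks.strengths
    return BroadenedSpectrum(grid=grid, intensity=intensity, hwhm=epsilon)


def ensemble_average(spectra: Sequence[BroadenedSpectrum],
                     weights: WeightTable | Sequence[float],
                     ) -> BroadenedSpectrum:
    """Pointwise Σ_i p_i · spectrum_i on a shared grid."""
    if isinstance(weights, WeightTable):
        p = weights.probabilities
    else:
        p = np.asarray(weights, dtype=float)
    if len(spectra) != len(p):
        raise ValueError(f"{len(spectra)} spectra but {len(p)} weights")
    grid = spectra[0].grid
    hwhm = spectra[0].hwhm
    for s in spectra[1:]:
        if s.grid.shape != grid.shape or not np.allclose(s.grid, grid):
            raise ValueError("spectra are not on a common energy grid")
    total = np.zeros_like(grid)
    for wi, s in zip(p, spectra):
        total += wi * s.intensity
    return BroadenedSpectrum(grid=grid, intensity=total, hwhm=hwhm)


def decompose_by_labels(sticks: StickSpectrum, grid: np.ndarray,
                        epsilon: float = EPSILON_DEFAULT,
                        ) -> dict[tuple[str, str], BroadenedSpectrum]:
    """Partition lines by (initial, final) fragment label and broaden each.

    The component spectra sum to the total spectrum exactly (linearity of
    the Lorentzian).  Raises when any line is unlabelled.
    """
    if sticks.initial_labels is None or sticks.final_labels is None:
        raise ValueError("all lines must carry initial and final labels")
    pairs = list(zip(sticks.initial_labels, sticks.final_labels))
    out: dict[tuple[str, str], BroadenedSpectrum] = {}
    for pair in dict.fromkeys(pairs):  # stable unique order
        mask = np.array([p == pair for p in pairs])
        sub = StickSpectrum(energies=sticks.energies[mask],
                            strengths=sticks.strengths[mask],
                            conformer_id=sticks.conformer_id)
        out[pair] = broaden(sub, grid, epsilon)
    return out


def component_peak_ratios(components: Mapping[tuple[str, str], BroadenedSpectrum],
                          peak_energies: Sequence[float],
                          pair_a: tuple[str, str], pair_b: tuple[str, str],
                          ) -> list[float]:
    """|component_b| / |component_a| intensity ratio at given peak energies —
    the solvent-vs-cluster contribution analysis at labelled peaks."""
    a, b = components[pair_a], components[pair_b]
    out = []
    for e in peak_energies:
        i = int(np.argmin(np.abs(a.grid - e)))
        denom = abs(a.intensity[i])
        out.append(abs(b.intensity[i]) / denom if denom > 0 else np.inf)
    return out


# ---------------------------------------------------------------------------
# Hausdorff chirality measure
# ---------------------------------------------------------------------------

def _hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    d = cdist(a, b)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def _min_hausdorff_over_rotations(q: np.ndarray, m: np.ndarray,
                                  coarse_deg: float,
                                  chunk: int = 4096) -> tuple[float, np.ndarray]:
    """Euler-angle grid search for the rotation of ``m`` minimizing the
    Hausdorff distance to ``q`` (both centred).  Vectorized over rotation
    batches; memory bounded by ``chunk`` · n² distances."""
    step = np.radians(coarse_deg)
    alphas = np.arange(0.0, 2 * np.pi, step)
    betas = np.arange(0.0, np.pi + 1e-12, step)
    gammas = np.arange(0.0, 2 * np.pi, step)
    angles = np.stack(np.meshgrid(alphas, betas, gammas,
                                  indexing="ij"), axis=-1).reshape(-1, 3)
    best = np.inf
    best_angles = np.zeros(3)
    for start in range(0, len(angles), chunk):
        batch = angles[start:start + chunk]
        rots = Rotation.from_euler("zyz", batch).as_matrix()  # (K, 3, 3)
        moved = np.einsum("kij,nj->kni", rots, m)             # (K, n, 3)
        diff = q[None, :, None, :] - moved[:, None, :, :]
        d = np.sqrt((diff * diff).sum(axis=-1))               # (K, n, n)
        h = np.maximum(d.min(axis=2).max(axis=1),
                       d.min(axis=1).max(axis=1))
        k = int(np.argmin(h))
        if h[k] < best:
            best = float(h[k])
            best_angles = batch[k]
    return best, best_angles


def hausdorff_chirality_measure(coordinates: np.ndarray,
                                coarse_deg: float = 15.0,
                                refine: bool = True) -> float:
    """Hausdorff chirality measure in [0, 1).

    The point set and its mirror image are centred on their centroids; the
    Hausdorff distance between them is minimized over proper rotations by a
    coarse Euler-grid search (``coarse_deg`` steps) followed by local
    simplex refinement, then normalized by the set's diameter.  Invariant
    under rigid motion and uniform scaling; 0 for achiral sets.
    """
    q = np.asarray(coordinates, dtype=float)
    if q.shape[0] < 2:
        raise DegeneracyError("HCM needs at least 2 points")
    q = q - q.mean(axis=0)
    diameter = cdist(q, q).max()
    if diameter <= 0:
        raise DegeneracyError("all points coincide; HCM undefined")
    q = q / diameter
    mirror = q * np.array([1.0, 1.0, -1.0])

    best, angles = _min_hausdorff_over_rotations(q, mirror, coarse_deg)
    if refine:
        def objective(ang: np.ndarray) -> float:
            rot = Rotation.from_euler("zyz", ang).as_matrix()
            return _hausdorff(q, mirror @ rot.T)

        res = minimize(objective, angles, method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-12,
                                "maxiter": 2000})
        best = min(best, float(res.fun))
    return best


# ---------------------------------------------------------------------------
# stick-file I/O (delimited text with header)
# ---------------------------------------------------------------------------

def write_sticks(sticks: StickSpectrum, path: str | Path) -> None:
    labelled = sticks.initial_labels is not None and sticks.final_labels is not None
    with open(path, "w") as fh:
        if labelled:
            fh.write("energy_eV R initial_label final_label\n")
            for e, r, li, lf in zip(sticks.energies, sticks.strengths,
                                    sticks.initial_labels, sticks.final_labels):
                fh.write(f"{e:.6f} {r:.9g} {li} {lf}\n")
        else:
            fh.write("energy_eV R\n")
            for e, r in zip(sticks.energies, sticks.strengths):
                fh.write(f"{e:.6f} {r:.9g}\n")


def read_sticks(path: str | Path, conformer_id: str = "") -> StickSpectrum:
    energies: list[float] = []
    strengths: list[float] = []
    init_labels: list[str] = []
    final_labels: list[str] = []
    labelled = False
    with open(path) as fh:
        header = fh.readline().split()
        if not header or header[0] != "energy_eV":
            raise ValueError(f"{path}: expected header starting with 'energy_eV'")
        labelled = "initial_label" in header
        for ln, line in enumerate(fh, 2):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            try:
                energies.append(float(parts[0]))
                strengths.append(float(parts[1]))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {ln}: {exc}") from exc
            if labelled:
                if len(parts) < 4:
                    raise ValueError(f"{path}: line {ln}: missing labels")
                init_labels.append(parts[2])
                final_labels.append(parts[3])
    return StickSpectrum(
        energies=np.array(energies), strengths=np.array(strengths),
        conformer_id=conformer_id or Path(path).stem,
        initial_labels=init_labels if labelled else None,
        final_labels=final_labels if labelled else None)
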