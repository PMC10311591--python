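"""Free-energy landscapes on the essential plane.

A 2-D occupancy histogram of the essential-plane projections is converted
to a standard Gibbs free-energy surface by Boltzmann inversion,

    ΔG°(i) = −R·T · ln( P(i) / P_ref ),

with P(i) the occupancy probability of bin i and P_ref that of the most
populated bin, so the global minimum sits at ΔG° = 0.  Unoccupied bins
carry +inf (rendered at a ceiling, never at 0).  Low-ΔG° connected
regions of the grid are conformational basins; one representative frame
per basin (or more, when distinct density peaks differ structurally by
more than an RMSD threshold) forms the conformer set that downstream
spectral averaging weights by Boltzmann probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .constants import R_KJ
from .essential import EssentialProjection, InsufficientDataError
from .trajectory import Trajectory, rmsd

__all__ = [
    "LandscapeGrid",
    "Basin",
    "Conformer",
    "ConformerSet",
    "free_energy_landscape",
    "find_basins",
    "extract_conformers",
]


@dataclass
class LandscapeGrid:
    """2-D occupancy histogram with per-bin probability and ΔG° (kJ/mol)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray          # (nx, ny) integers
    probability: np.ndarray     # counts / n_frames
    delta_g: np.ndarray         # kJ/mol; +inf where unoccupied
    temperature: float          # K

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    @property
    def x_centres(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centres(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def bin_of(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Bin indices (ix, iy) for points on the essential plane."""
        ix = np.clip(np.searchsorted(self.x_edges, xy[:, 0], side="right") - 1,
                     0, len(self.x_edges) - 2)
        iy = np.clip(np.searchsorted(self.y_edges, xy[:, 1], side="right") - 1,
                     0, len(self.y_edges) - 2)
        return ix, iy

    def save(self, path: str | Path) -> None:
        """Delimited grid export: x-centre, y-centre, count, P, ΔG°."""
        xc, yc = np.meshgrid(self.x_centres, self.y_centres, indexing="ij")
        data = np.column_stack([
            xc.ravel(), yc.ravel(), self.counts.ravel(),
            self.probability.ravel(), self.delta_g.ravel()])
        np.savetxt(path, data, header="x_centre y_centre count P dG_kJ_mol",
                   fmt=["%.9g", "%.9g", "%d", "%.9g", "%.9g"])


@dataclass
class Basin:
    """A connected low-free-energy region of the landscape."""

    label: str
    bins: list[tuple[int, int]]
    probability_mass: float
    min_delta_g: float
    centroid: np.ndarray  # probability-weighted, essential-plane coords (nm)


@dataclass
class Conformer:
    basin_label: str
    frame_index: int
    coordinates: np.ndarray
    delta_g: float
    probability: float


@dataclass
class ConformerSet:
    conformers: list[Conformer]

    def __iter__(self):
        return iter(self.conformers)

    def __len__(self) -> int:
        return len(self.conformers)

    def labels(self) -> list[str]:
        return [c.basin_label for c in self.conformers]

    def report(self) -> list[dict]:
        return [
            {"label": c.basin_label, "frame": int(c.frame_index),
             "dG_kJ_mol": float(c.delta_g), "p": float(c.probability)}
            for c in self.conformers
        ]


def free_energy_landscape(projection: EssentialProjection,
                          n_bins: tuple[int, int] = (50, 50),
                          temperature: float = 300.0,
                          pad_fraction: float = 0.02) -> LandscapeGrid:
    """Histogram the first two projection columns and Boltzmann-invert.

    The grid spans the data range on each axis padded by ``pad_fraction``;
    ΔG° uses R = 8.314 J mol⁻¹ K⁻¹ and the most populated bin as reference.
    """
    comps = projection.components
    if comps.shape[0] < 1:
        raise InsufficientDataError("landscape needs at least one frame")
    if comps.shape[1] < 2:
        raise ValueError("projection must have at least two components")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    x, y = comps[:, 0], comps[:, 1]

    def padded(v: np.ndarray) -> tuple[float, float]:
        lo, hi = float(v.min()), float(v.max())
        span = hi - lo
        pad = pad_fraction * span if span > 0 else max(abs(hi), 1.0) * 1e-6
        return lo - pad, hi + pad

    (x0, x1), (y0, y1) = padded(x), padded(y)
    counts, x_edges, y_edges = np.histogram2d(
        x, y, bins=n_bins, range=[[x0, x1], [y0, y1]])
    counts = counts.astype(int)
    prob = counts / comps.shape[0]
    rt = R_KJ * temperature
    with np.errstate(divide="ignore"):
        delta_g = np.where(counts > 0,
                           -rt * np.log(prob / prob.max()),
                           np.inf)
    delta_g[counts > 0] = np.clip(delta_g[counts > 0], 0.0, None)
    return LandscapeGrid(x_edges=x_edges, y_edges=y_edges, counts=counts,
                         probability=prob, delta_g=delta_g,
                         temperature=temperature)


_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
_STRUCTURE_8 = np.ones((3, 3), dtype=int)


def find_basins(grid: LandscapeGrid, dg_cutoff: float = 2.5,
                connectivity: int = 4) -> list[Basin]:
    """Connected components of occupied bins with ΔG° below ``dg_cutoff``.

    Components are labelled B1, B2, ... by ascending minimum ΔG°, ties
    broken by larger probability mass.  ``connectivity`` is 4 (edges) or
    8 (edges + corners).
    """
    if dg_cutoff <= 0:
        raise ValueError(f"dG cutoff must be positive, got {dg_cutoff}")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = grid.occupied & (grid.delta_g < dg_cutoff)
    structure = _STRUCTURE_4 if connectivity == 4 else _STRUCTURE_8
    labelled, n_comp = ndimage.label(mask, structure=structure)
    basins: list[Basin] = []
    xc, yc = grid.x_centres, grid.y_centres
    for comp in range(1, n_comp + 1):
        sel = labelled == comp
        ii, jj = np.nonzero(sel)
        mass = float(grid.probability[sel].sum())
        min_dg = float(grid.delta_g[sel].min())
        w = grid.probability[sel]
        centroid = np.array([np.average(xc[ii], weights=w),
                             np.average(yc[jj], weights=w)])
        basins.append(Basin(label="", bins=list(zip(ii.tolist(), jj.tolist())),
                            probability_mass=mass, min_delta_g=min_dg,
                            centroid=centroid))
    basins.sort(key=lambda b: (b.min_delta_g, -b.probability_mass))
    for k, b in enumerate(basins):
        b.label = f"B{k + 1}"
    return basins


def inter_basin_free_energy(grid: LandscapeGrid, basins: list[Basin],
                            top_m: int = 5) -> np.ndarray:
    """Robust ΔG° estimate per basin relative to the most populated one.

    Individual bin counts are Poisson-distributed, so a basin's free energy
    read off a single peak bin is noisy; averaging the ``top_m`` most
    probable bins of each basin before Boltzmann inversion suppresses that
    noise while, for basins of comparable width, leaving the inter-basin
    ratio unbiased.  Returns one ΔG° (kJ/mol) per basin, minimum 0.
    """
    peaks = []
    for b in basins:
        ps = np.sort(np.array([grid.probability[ij] for ij in b.bins]))[::-1]
        peaks.append(ps[:top_m].mean())
    peaks = np.asarray(peaks)
    rt = R_KJ * grid.temperature
    return -rt * np.log(peaks / peaks.max())


def _density_peaks(grid: LandscapeGrid, basin: Basin) -> list[tuple[int, int]]:
    """Bins of the basin that are local count maxima (4-neighbour strict-or-
    equal plateau rule), sorted by descending count."""
    counts = grid.counts
    members = set(basin.bins)
    peaks = []
    for (i, j) in basin.bins:
        c = counts[i, j]
        higher = False
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if (ni, nj) in members and counts[ni, nj] > c:
                higher = True
                break
        if not higher:
            peaks.append((i, j))
    peaks.sort(key=lambda ij: (-counts[ij], ij))
    return peaks


def extract_conformers(traj: Trajectory, projection: EssentialProjection,
                       grid: LandscapeGrid, basins: list[Basin],
                       rmsd_threshold: float = 0.17,
                       subset: np.ndarray | None = None,
                       temperature: float | None = None) -> ConformerSet:
    """Pick representative frames per basin, de-duplicated by fitted RMSD.

    The primary representative of a basin is the frame whose essential-plane
    position is nearest (Euclidean) to the basin's probability-weighted
    centroid.  Additional candidates come from distinct density peaks of the
    basin and are retained only when their fitted RMSD to every
    already-retained representative of that basin exceeds
    ``rmsd_threshold`` (nm) — two structurally distinct conformers may then
    share a basin.  Conformer ΔG° is the basin minimum; probabilities are
    Boltzmann weights of those ΔG° values, normalized over the set.
    """
    if not basins:
        raise ValueError("no basins supplied")
    if rmsd_threshold <= 0:
        raise ValueError("rmsd threshold must be positive")
    comps = projection.components[:, :2]
    ix, iy = grid.bin_of(comps)
    conformers: list[Conformer] = []
    for basin in basins:
        members = set(basin.bins)
        in_basin = np.array([(i, j) in members for i, j in zip(ix, iy)])
        frame_idx = np.flatnonzero(in_basin)
        if frame_idx.size == 0:
            raise RuntimeError(
                f"basin {basin.label} has occupied bins but no frames mapped")
        # primary representative: nearest frame to the weighted centroid
        d2 = ((comps[frame_idx] - basin.centroid) ** 2).sum(axis=1)
        order = np.lexsort((frame_idx, d2))
        primary = int(frame_idx[order[0]])
        kept = [primary]
        # secondary candidates from distinct density peaks
        xc, yc = grid.x_centres, grid.y_centres
        for (pi, pj) in _density_peaks(grid, basin)[1:]:
            peak_xy = np.array([xc[pi], yc[pj]])
            d2p = ((comps[frame_idx] - peak_xy) ** 2).sum(axis=1)
            cand = int(frame_idx[np.lexsort((frame_idx, d2p))[0]])
            if cand in kept:
                continue
            distinct = all(
                rmsd(traj.frames[cand].coordinates,
                     traj.frames[k].coordinates, subset=subset, fit=True)
                > rmsd_threshold
                for k in kept)
            if distinct:
                kept.append(cand)
        for m, fi in enumerate(kept):
            suffix = "" if len(kept) == 1 else "-" + "AB"[m] if m < 2 else f"-{m + 1}"
            conformers.append(Conformer(
                basin_label=basin.label + suffix, frame_index=fi,
                coordinates=traj.frames[fi].coordinates.copy(),
                delta_g=basin.min_delta_g, probability=0.0))
    # Boltzmann probabilities over the retained set
    temp = temperature if temperature is not None else grid.temperature
    dg = np.array([c.delta_g for c in conformers])
    w = np.exp(-(dg - dg.min()) / (R_KJ * temp))
    p = w / w.sum()
    for c, pi in zip(conformers, p):
        c.probability = float(pi)
    return ConformerSet(conformers=conformers)


def basin_report(basins: list[Basin], conformers: ConformerSet | None = None,
                 path: str | Path | None = None) -> list[dict]:
    """JSON-serializable basin summary (label, min ΔG°, mass, centroid)."""
    rep = []
    for b in basins:
        entry = {
            "label": b.label,
            "min_dG_kJ_mol": b.min_delta_g,
            "probability_mass": b.probability_mass,
            "centroid": [float(v) for v in b.centroid],
            "n_bins": len(b.bins),
        }
        if conformers is not None:
            entry["representative_frames"] = [
                c.frame_index for c in conformers
                if c.basin_label.startswith(b.label)]
        rep.append(entry)
    if path is not None:
        Path(path).write_text(json.dumps(rep, indent=2))
    return rep
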