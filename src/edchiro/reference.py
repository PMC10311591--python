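"""Reference free-energy and probability tables for the canonical system.

The package's worked example is the glutathione-protected gold nanocluster
[Au25(GSH)18]⁻¹ with an explicit 126-water solvation shell.  Thirteen
solvated-cluster conformers (two per landscape basin B1..B5, one or two
from the split B6 region) carry published standard free energies
ΔG°TOT = ΔG°[Au25(GSH)18]⁻¹ + ΔG°H2O relative to the most stable
conformer B3-1, and normalized Boltzmann probabilities at 300 K.  Three
conformer subsets are used for re-weighted ensemble averages:

  a) the most probable conformer of each solvation landscape (7 conformers),
  b) subset a without the two B6 regions (5 conformers),
  c) only the B3/B4/B5 landscapes' most probable conformers (3 conformers).

These tables are data, bundled so the weighting pipeline has a realistic,
externally checkable input; all probabilities here are reproduced (not
read back) by :func:`edchiro.chiroptics.boltzmann_weights` at 300 K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ReferenceTables", "reference_conformers"]

# label -> ΔG°TOT (kJ/mol), relative to B3-1
_DG_TOT: dict[str, float] = {
    "B1-1": 1.61,
    "B1-2": 0.87,
    "B2-1": 2.05,
    "B2-2": 1.45,
    "B3-1": 0.00,
    "B3-2": 0.98,
    "B4-1": 2.21,
    "B4-2": 2.82,
    "B5-1": 0.81,
    "B5-2": 0.34,
    "B6-A-1": 2.03,
    "B6-B-1": 1.40,
    "B6-B-2": 1.51,
}

# published normalized probabilities at 300 K (2 significant figures)
_P_NORM: dict[str, float] = {
    "B1-1": 0.067, "B1-2": 0.090, "B2-1": 0.057, "B2-2": 0.072,
    "B3-1": 0.13, "B3-2": 0.087, "B4-1": 0.053, "B4-2": 0.041,
    "B5-1": 0.093, "B5-2": 0.11, "B6-A-1": 0.057, "B6-B-1": 0.073,
    "B6-B-2": 0.070,
}

_SUBSETS: dict[str, tuple[str, ...]] = {
    "a": ("B1-2", "B2-2", "B3-1", "B4-1", "B5-2", "B6-A-1", "B6-B-1"),
    "b": ("B1-2", "B2-2", "B3-1", "B4-1", "B5-2"),
    "c": ("B3-1", "B4-1", "B5-2"),
}

# published renormalized probabilities per subset
_SUBSET_P: dict[str, dict[str, float]] = {
    "a": {"B1-2": 0.16, "B2-2": 0.12, "B3-1": 0.22, "B4-1": 0.090,
          "B5-2": 0.19, "B6-A-1": 0.097, "B6-B-1": 0.13},
    "b": {"B1-2": 0.20, "B2-2": 0.16, "B3-1": 0.28, "B4-1": 0.12,
          "B5-2": 0.25},
    "c": {"B3-1": 0.44, "B4-1": 0.18, "B5-2": 0.38},
}


@dataclass(frozen=True)
class ReferenceTables:
    """The 13-conformer reference bundle."""

    labels: tuple[str, ...]
    delta_g_tot: dict[str, float]
    p_norm: dict[str, float]
    subsets: dict[str, tuple[str, ...]]
    subset_p: dict[str, dict[str, float]]
    temperature: float = 300.0


def reference_conformers() -> ReferenceTables:
    """Return the bundled 13-conformer ΔG°/probability tables and subsets."""
    return ReferenceTables(
        labels=tuple(_DG_TOT),
        delta_g_tot=dict(_DG_TOT),
        p_norm=dict(_P_NORM),
        subsets={k: tuple(v) for k, v in _SUBSETS.items()},
        subset_p={k: dict(v) for k, v in _SUBSET_P.items()},
    )
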