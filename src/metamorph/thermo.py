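"""Hyper-rectangle free-energy landscapes and the fold-switch decomposition.

The essential space of a conformer is discretised into a regular grid of
hyper-rectangles of volume delta. From the occupancy histogram one obtains
the cell probabilities ``P_l``, the Landau free energies relative to the
most populated cell

    dG_l = -kB T ln(P_l / P_0),

the accessible volume ``V = N * delta`` over the N populated cells, and the
landscape average ``<exp(-beta dG_l)>_0 = (1/N) sum_l exp(-beta dG_l)``.
For a conformational equilibrium C1 <-> C2 the free-energy change then
splits into a purely entropic accessible-volume term and a landscape term:

    dG_S = -kB T ln(V_C2 / V_C1)
    dG_L = -kB T ln(<exp(-beta dG_l)>_0^C2 / <exp(-beta dG_l)>_0^C1)

with the Landau-minimum offset dA_0 left unresolved (it cancels in
between-variant differences). Between two evolutionary variants the
differences ddG_S, ddG_L and an experimental ddG_exp give an estimate of
ddA_0; within one variant, dG_exp - dG_S - dG_L isolates the combined
dimerization + Landau-minimum offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (DEFAULT_BINS_PER_DIM, DEFAULT_MIN_COUNT,
                        DEFAULT_TEMPERATURE_K, KB)
from .essential import ProjectionSeries
from .exceptions import (DegenerateGridError, EmptyLandscapeError,
                         IncompatibleConformersError, MetamorphError)

__all__ = [
    "EssentialGrid", "LandscapeTable", "ConformerThermo", "TransitionResult",
    "build_grid", "landscape", "conformer_thermo", "transition_terms",
    "occupancy_to_free_energy", "evolution_comparison", "dimer_offset",
    "free_energy_distribution",
]


@dataclass
class EssentialGrid:
    """Regular grid over the essential space.

    ``bin_edges[d]`` is the monotone edge sequence of dimension d (nm);
    ``cell_volume_delta`` is the product of the nominal bin widths (nm^d).
    """

    bin_edges: list[np.ndarray]
    cell_volume_delta: float

    @property
    def n_dims(self) -> int:
        return len(self.bin_edges)

    @property
    def bins_per_dim(self) -> list[int]:
        return [len(e) - 1 for e in self.bin_edges]


@dataclass
class LandscapeTable:
    """Sparse occupancy/probability/free-energy map over grid cells.

    ``cells`` maps a d-tuple of bin indices to ``(count, P_l, dG_l)`` with
    dG_l in kJ/mol relative to the most populated cell ``min_cell``.
    """

    cells: dict[tuple[int, ...], tuple[int, float, float]]
    min_cell: tuple[int, ...]
    p0: float
    temperature_K: float

    @property
    def n_cells_populated(self) -> int:
        return len(self.cells)

    def counts(self) -> np.ndarray:
        return np.array([c for c, _, _ in self.cells.values()])

    def probabilities(self) -> np.ndarray:
        return np.array([p for _, p, _ in self.cells.values()])

    def free_energies(self) -> np.ndarray:
        return np.array([g for _, _, g in self.cells.values()])


@dataclass
class ConformerThermo:
    """Accessible volume and landscape average for one conformer."""

    volume_V: float        # N * delta, nm^d
    landscape_avg: float   # <exp(-beta dG_l)>_0, dimensionless, in (0, 1]
    delta: float           # cell volume, nm^d
    n_cells: int           # N
    n_dims: int
    temperature_K: float


@dataclass
class TransitionResult:
    """Free-energy terms for a C1 -> C2 conformational transition (kJ/mol).

    Convention throughout the package: C1 = Altfold, C2 = Chemfold, so
    negative values favour the chemokine fold. The optional dd* fields are
    filled by :func:`evolution_comparison` for a variant-vs-ancestor pair.
    """

    dG_S: float
    dG_L: float
    temperature_K: float
    ddG_S: float | None = None
    ddG_L: float | None = None
    ddA0_estimate: float | None = None
    dimer_offset: float | None = None


def build_grid(series: ProjectionSeries, bins_per_dim: int = DEFAULT_BINS_PER_DIM
               ) -> EssentialGrid:
    """Equal-width grid spanning the sample range of each dimension.

    The outermost edges are widened by 1e-9 nm so extreme samples always
    bin inside; ``cell_volume_delta`` uses the nominal (unpadded) width.
    """
    if series.n_frames < 1 or series.n_modes < 1:
        raise MetamorphError("empty projection series")
    if bins_per_dim < 2:
        raise MetamorphError("need at least 2 bins per dimension")
    edges, delta = [], 1.0
    for d in range(series.n_modes):
        lo, hi = float(series.values[:, d].min()), float(series.values[:, d].max())
        if hi <= lo:
            raise DegenerateGridError(f"dimension {d} has zero sample range")
        e = np.linspace(lo, hi, bins_per_dim + 1)
        e[0] -= 1e-9
        e[-1] += 1e-9
        edges.append(e)
        delta *= (hi - lo) / bins_per_dim
    return EssentialGrid(edges, delta)


def _digitize(series: ProjectionSeries, grid: EssentialGrid) -> np.ndarray:
    idx = np.empty((series.n_frames, grid.n_dims), dtype=np.int64)
    for d, edges in enumerate(grid.bin_edges):
        i = np.searchsorted(edges, series.values[:, d], side="right") - 1
        if (i < 0).any() or (i >= len(edges) - 1).any():
            raise MetamorphError(f"samples fall outside the grid in dimension {d}")
        idx[:, d] = i
    return idx


def landscape(series: ProjectionSeries, grid: EssentialGrid,
              temperature_K: float = DEFAULT_TEMPERATURE_K,
              min_count: int = DEFAULT_MIN_COUNT) -> LandscapeTable:
    """Occupancy counts, probabilities and relative free energies per cell.

    Cells with fewer than ``min_count`` frames are dropped; probabilities
    are renormalised over the kept cells. The reference cell is the most
    populated one (ties broken by the lexicographically smallest index
    tuple) so dG_l >= 0 with equality at the reference.
    """
    idx = _digitize(series, grid)
    uniq, counts = np.unique(idx, axis=0, return_counts=True)
    keep = counts >= min_count
    uniq, counts = uniq[keep], counts[keep]
    if counts.size == 0:
        raise EmptyLandscapeError(
            f"no grid cell reaches min_count={min_count}")
    # lexicographic order makes the argmax tie-break deterministic
    order = np.lexsort(uniq.T[::-1])
    uniq, counts = uniq[order], counts[order]
    probs = counts / counts.sum()
    i0 = int(np.argmax(probs))  # first (lexicographically smallest) maximum
    p0 = float(probs[i0])
    kt = KB * temperature_K
    dg = -kt * np.log(probs / p0)
    cells = {tuple(int(v) for v in uniq[i]): (int(counts[i]), float(probs[i]), float(dg[i]))
             for i in range(len(counts))}
    return LandscapeTable(cells, tuple(int(v) for v in uniq[i0]), p0, temperature_K)


def conformer_thermo(table: LandscapeTable, grid: EssentialGrid) -> ConformerThermo:
    """Accessible volume V = N delta and landscape average over the table."""
    n = table.n_cells_populated
    beta_dg = table.free_energies() / (KB * table.temperature_K)
    avg = float(np.mean(np.exp(-beta_dg)))
    return ConformerThermo(
        volume_V=n * grid.cell_volume_delta,
        landscape_avg=avg,
        delta=grid.cell_volume_delta,
        n_cells=n,
        n_dims=grid.n_dims,
        temperature_K=table.temperature_K,
    )


def transition_terms(thermo_c1: ConformerThermo, thermo_c2: ConformerThermo
                     ) -> TransitionResult:
    """Entropic and landscape free-energy terms for C1 -> C2."""
    if thermo_c1.n_dims != thermo_c2.n_dims:
        raise IncompatibleConformersError(
            f"essential dimensionality differs: {thermo_c1.n_dims} vs {thermo_c2.n_dims}")
    if abs(thermo_c1.temperature_K - thermo_c2.temperature_K) > 1e-9:
        raise IncompatibleConformersError("conformers analysed at different temperatures")
    kt = KB * thermo_c1.temperature_K
    dg_s = -kt * np.log(thermo_c2.volume_V / thermo_c1.volume_V)
    dg_l = -kt * np.log(thermo_c2.landscape_avg / thermo_c1.landscape_avg)
    return TransitionResult(float(dg_s), float(dg_l), thermo_c1.temperature_K)


def occupancy_to_free_energy(chemfold_fraction: float,
                             temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Experimental Altfold -> Chemfold free energy from the Chemfold fraction.

    dG_exp = -kB T ln(f / (1 - f)); f = 0.5 gives exactly 0. Computed as a
    log difference so swapping f and 1 - f negates the result exactly.
    """
    if not 0.0 < chemfold_fraction < 1.0:
        raise ValueError(f"fraction must lie strictly in (0, 1), got {chemfold_fraction}")
    f = chemfold_fraction
    return float(-KB * temperature_K * (np.log(f) - np.log(1.0 - f)))


def evolution_comparison(result_variant: TransitionResult,
                         result_ancestor: TransitionResult,
                         ddG_exp: float | None = None) -> TransitionResult:
    """Variant-minus-ancestor differences of the transition terms.

    Returns a new result carrying ddG_S, ddG_L and, when an experimental
    ddG_exp is supplied, the Landau-minimum difference estimate
    ddA0 = ddG_exp - ddG_S - ddG_L.
    """
    if abs(result_variant.temperature_K - result_ancestor.temperature_K) > 1e-9:
        raise IncompatibleConformersError("results computed at different temperatures")
    dd_s = result_variant.dG_S - result_ancestor.dG_S
    dd_l = result_variant.dG_L - result_ancestor.dG_L
    dda0 = None if ddG_exp is None else ddG_exp - dd_s - dd_l
    return TransitionResult(result_variant.dG_S, result_variant.dG_L,
                            result_variant.temperature_K,
                            ddG_S=dd_s, ddG_L=dd_l, ddA0_estimate=dda0)


def dimer_offset(dG_exp: float, result: TransitionResult) -> float:
    """Combined -dG_Dim + dA_0 offset: dG_exp - dG_S - dG_L (kJ/mol)."""
    return dG_exp - result.dG_S - result.dG_L


def free_energy_distribution(table: LandscapeTable, hist_bin_kJmol: float = 1.0
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Unit-mass histogram of cell free energies dG_l over populated cells.

    Returns ``(edges, masses)`` with bins of width ``hist_bin_kJmol``
    starting at 0; masses sum to 1 (each populated cell counts once).
    """
    if hist_bin_kJmol <= 0:
        raise ValueError("histogram bin width must be positive")
    if table.n_cells_populated == 0:
        raise EmptyLandscapeError("empty landscape table")
    dg = table.free_energies()
    n_bins = max(int(np.floor(dg.max() / hist_bin_kJmol)) + 1, 1)
    edges = np.arange(n_bins + 1) * hist_bin_kJmol
    counts, _ = np.histogram(dg, bins=edges)
    return edges, counts / counts.sum()
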