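"""Model/Results objects wrapping the full two-conformer analysis.

:class:`FoldSwitchModel` is built from the Altfold and Chemfold ensembles of
one protein variant and owns the analysis settings (atom selection,
essential dimensionality, grid resolution, temperature). Its :meth:`fit`
runs superposition -> covariance -> eigendecomposition -> projection ->
gaussianity -> grid -> landscape -> conformer thermodynamics for each
conformer and returns a :class:`FoldSwitchResults` carrying the per-conformer
artifacts, the Altfold -> Chemfold transition terms and a text summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import essential as ed
from . import thermo as th
from .constants import (DEFAULT_BINS_PER_DIM, DEFAULT_MIN_COUNT,
                        DEFAULT_N_ESSENTIAL, DEFAULT_TEMPERATURE_K)
from .thermo import TransitionResult
from .trajectory import Trajectory, select_atoms

__all__ = ["ConformerFit", "FoldSwitchModel", "FoldSwitchResults"]


@dataclass
class ConformerFit:
    """All per-conformer analysis artifacts."""

    basis: ed.EssentialBasis
    projections: ed.ProjectionSeries
    gaussianity: ed.GaussianityReport
    grid: th.EssentialGrid
    table: th.LandscapeTable
    thermo: th.ConformerThermo


class FoldSwitchModel:
    """Two-conformer (Altfold/Chemfold) conformational-thermodynamics model.

    Parameters
    ----------
    altfold, chemfold
        Trajectories of the two folds of one variant (C1 = Altfold,
        C2 = Chemfold).
    selection
        Atom-name filter applied before analysis; default Calpha only.
    n_essential
        Essential dimensionality when ``dim_mode="fixed"``.
    dim_mode, epsilon
        ``"fixed"`` or ``"threshold"``; threshold mode picks the smallest d
        with all later gaussianity deviations below ``epsilon``.
    bins_per_dim, min_count, temperature_K
        Grid resolution, populated-cell criterion, and temperature.
    superpose
        Remove rigid-body motion before the covariance step (skip only for
        trajectories generated without rigid noise).
    """

    def __init__(self, altfold: Trajectory, chemfold: Trajectory, *,
                 selection: str | None = "CA",
                 n_essential: int = DEFAULT_N_ESSENTIAL,
                 dim_mode: str = "fixed", epsilon: float = 3e-3,
                 bins_per_dim: int = DEFAULT_BINS_PER_DIM,
                 min_count: int = DEFAULT_MIN_COUNT,
                 temperature_K: float = DEFAULT_TEMPERATURE_K,
                 superpose: bool = True, gauss_bins: int = 50):
        self.altfold = altfold
        self.chemfold = chemfold
        self.selection = selection
        self.n_essential = n_essential
        self.dim_mode = dim_mode
        self.epsilon = epsilon
        self.bins_per_dim = bins_per_dim
        self.min_count = min_count
        self.temperature_K = temperature_K
        self.superpose = superpose
        self.gauss_bins = gauss_bins

    @classmethod
    def from_files(cls, altfold_path, chemfold_path, format="pdb", **kwargs):
        from .trajectory import read_trajectory
        return cls(read_trajectory(altfold_path, format),
                   read_trajectory(chemfold_path, format), **kwargs)

    def _fit_conformer(self, traj: Trajectory, d: int | None) -> tuple[ConformerFit, int]:
        if self.selection is not None:
            traj = select_atoms(traj, name_filter=self.selection)
        if self.superpose:
            traj, mean = ed.superpose(traj)
        else:
            mean = traj.coords.mean(axis=0)
        cov = ed.covariance(traj)
        basis = ed.eigendecompose(cov, mean)
        n_report = min(max(self.n_essential + 14, 20), basis.eigenvalues.size)
        proj_all = ed.project(traj, basis, np.arange(n_report))
        report = ed.gaussianity_deviation(proj_all, self.gauss_bins)
        if d is None:
            d = ed.select_essential_dim(report, self.dim_mode,
                                        k=self.n_essential, epsilon=self.epsilon)
        series = ed.ProjectionSeries(proj_all.values[:, :d], proj_all.mode_indices[:d])
        grid = th.build_grid(series, self.bins_per_dim)
        table = th.landscape(series, grid, self.temperature_K, self.min_count)
        thermo = th.conformer_thermo(table, grid)
        return ConformerFit(basis, series, report, grid, table, thermo), d

    def fit(self) -> "FoldSwitchResults":
        alt, d = self._fit_conformer(self.altfold, None)
        # both conformers must share d so the volumes carry the same units
        if self.dim_mode == "threshold":
            chem_probe, d_chem = self._fit_conformer(self.chemfold, None)
            d = max(d, d_chem)
            alt, _ = self._fit_conformer(self.altfold, d)
        chem, _ = self._fit_conformer(self.chemfold, d)
        transition = th.transition_terms(alt.thermo, chem.thermo)
        return FoldSwitchResults(self, alt, chem, transition, d)


@dataclass
class FoldSwitchResults:
    """Fitted per-conformer artifacts plus the transition decomposition."""

    model: FoldSwitchModel
    altfold: ConformerFit
    chemfold: ConformerFit
    transition: TransitionResult
    essential_dim: int

    @property
    def dG_S(self) -> float:
        return self.transition.dG_S

    @property
    def dG_L(self) -> float:
        return self.transition.dG_L

    def conformer_table(self) -> pd.DataFrame:
        rows = []
        for name, fit in (("Altfold", self.altfold), ("Chemfold", self.chemfold)):
            t = fit.thermo
            rows.append({"conformer": name, "n_cells": t.n_cells,
                         "delta_nm_d": t.delta, "volume_nm_d": t.volume_V,
                         "landscape_avg": t.landscape_avg})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        t = self.transition
        lines = [
            "Fold-switch conformational thermodynamics (Altfold -> Chemfold)",
            "=" * 64,
            f"essential dimensionality d = {self.essential_dim}, "
            f"T = {self.model.temperature_K:g} K, "
            f"{self.model.bins_per_dim} bins/dim",
            "",
            self.conformer_table().to_string(index=False,
                                             float_format=lambda v: f"{v:.6g}"),
            "",
            f"dG_S (accessible volume) = {t.dG_S:8.3f} kJ/mol",
            f"dG_L (landscape)         = {t.dG_L:8.3f} kJ/mol",
            f"dG_S + dG_L              = {t.dG_S + t.dG_L:8.3f} kJ/mol",
        ]
        return "\n".join(lines)
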