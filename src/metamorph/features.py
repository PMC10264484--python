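"""Per-residue structural descriptors: RMSF and backbone H-bond occupancy."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientDataError, UnsupportedTopologyError
from .trajectory import Trajectory

__all__ = ["RMSFProfile", "HBondResult", "rmsf", "hbond_probability"]


@dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation (nm) about the time mean."""

    values: np.ndarray
    residue_ids: np.ndarray
    mean: float
    above_mean: np.ndarray  # residues fluctuating above the profile average

    def as_table(self):
        import pandas as pd
        return pd.DataFrame({"residue_id": self.residue_ids, "rmsf_nm": self.values,
                             "above_mean": self.above_mean})


def rmsf(aligned: Trajectory, drift_tol: float = 1e-3) -> RMSFProfile:
    """RMSF per atom: sqrt of the time-mean squared 3-D displacement.

    Expects a superposed trajectory; residual rigid drift (centroid motion
    between the first and second half above ``drift_tol`` nm) triggers a
    warning, not an error. Isotropic per-coordinate jitter of width sigma
    yields RMSF = sigma * sqrt(3).
    """
    if aligned.n_frames < 2:
        raise InsufficientDataError("RMSF needs at least 2 frames")
    half = aligned.n_frames // 2
    drift = np.linalg.norm(aligned.coords[:half].mean(axis=(0, 1))
                           - aligned.coords[half:].mean(axis=(0, 1)))
    if drift > drift_tol:
        warnings.warn(f"net rigid drift {drift:.2e} nm suggests the trajectory "
                      "was not superposed")
    mean = aligned.coords.mean(axis=0)
    sq = np.mean(np.sum((aligned.coords - mean) ** 2, axis=2), axis=0)
    values = np.sqrt(sq)
    profile_mean = float(values.mean())
    return RMSFProfile(values, aligned.residue_ids.copy(), profile_mean,
                       values > profile_mean)


@dataclass
class HBondResult:
    """Backbone N-H...O occupancy between two residues, both directions."""

    p_forward: float   # donor residue N-H -> acceptor residue O
    p_backward: float  # acceptor residue N-H -> donor residue O
    p_either: float    # at least one of the two bonds present
    n_frames: int


def _backbone_atom(traj: Trajectory, residue: int, name: str) -> np.ndarray:
    mask = (traj.residue_ids == residue) & (np.asarray(traj.atom_names, dtype=str) == name)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise UnsupportedTopologyError(
            f"residue {residue} lacks a backbone {name} atom "
            "(Calpha-only trajectories cannot evaluate hydrogen bonds)")
    return traj.coords[:, idx[0]]


def _bond_present(n: np.ndarray, h: np.ndarray, o: np.ndarray,
                  distance_cutoff_nm: float, angle_cutoff_deg: float) -> np.ndarray:
    d_no = np.linalg.norm(o - n, axis=1)
    v1 = n - h
    v2 = o - h
    cosang = np.sum(v1 * v2, axis=1) / (np.linalg.norm(v1, axis=1)
                                        * np.linalg.norm(v2, axis=1))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return (d_no <= distance_cutoff_nm) & (angle >= angle_cutoff_deg)


def hbond_probability(traj: Trajectory, donor_residue: int, acceptor_residue: int,
                      distance_cutoff_nm: float = 0.35,
                      angle_cutoff_deg: float = 150.0) -> HBondResult:
    """Fraction of frames with a backbone N-H...O hydrogen bond.

    A bond is counted when the N...O distance is at most
    ``distance_cutoff_nm`` and the N-H...O angle (at the hydrogen) is at
    least ``angle_cutoff_deg`` — the conventional geometric criterion. Both
    directional pairs between the two residues are evaluated; ``p_either``
    counts frames where at least one direction satisfies the criterion.
    """
    results = {}
    for label, (don, acc) in (("forward", (donor_residue, acceptor_residue)),
                              ("backward", (acceptor_residue, donor_residue))):
        n = _backbone_atom(traj, don, "N")
        h = _backbone_atom(traj, don, "H")
        o = _backbone_atom(traj, acc, "O")
        results[label] = _bond_present(n, h, o, distance_cutoff_nm, angle_cutoff_deg)
    either = results["forward"] | results["backward"]
    f = traj.n_frames
    return HBondResult(float(results["forward"].mean()),
                       float(results["backward"].mean()),
                       float(either.mean()), f)
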