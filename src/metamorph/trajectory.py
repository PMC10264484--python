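"""Trajectory container and I/O.

A :class:`Trajectory` holds Cartesian coordinates for a sequence of frames
together with minimal per-atom metadata. Internal length units are always
nanometres; PDB files (ångström) are converted on read/write.

Two plain-text formats are supported as the tested contract:

``pdb``
    Multi-model PDB, one MODEL/ENDMDL block per frame (read and written
    through :mod:`biotite`).
``matrix``
    One frame per row, ``3 * n_atoms`` whitespace-separated coordinate
    values in nm, ordered x1 y1 z1 x2 y2 z2 ...
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import MetamorphError, SelectionError, TrajectoryFormatError

__all__ = ["Trajectory", "read_trajectory", "write_trajectory", "select_atoms"]

_NM_PER_ANGSTROM = 0.1


@dataclass
class Trajectory:
    """Coordinates (frames x atoms x 3, nm) plus per-atom metadata.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in nm.
    atom_names
        Per-atom label, e.g. ``"CA"``, ``"N"``, ``"O"``, ``"H"``.
    residue_ids
        Per-atom 1-based residue index.
    residue_names
        Per-atom 3-letter residue code.
    frame_stride_ps
        Optional time spacing between saved frames, ps.
    """

    coords: np.ndarray
    atom_names: np.ndarray | None = None
    residue_ids: np.ndarray | None = None
    residue_names: np.ndarray | None = None
    frame_stride_ps: float | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise MetamorphError(
                f"coords must have shape (frames, atoms, 3), got {self.coords.shape}"
            )
        n_frames, n_atoms, _ = self.coords.shape
        if n_frames < 1 or n_atoms < 1:
            raise MetamorphError("trajectory needs at least one frame and one atom")
        if not np.isfinite(self.coords).all():
            raise MetamorphError("coordinates contain non-finite values")
        if self.atom_names is None:
            self.atom_names = np.array(["CA"] * n_atoms)
        else:
            self.atom_names = np.asarray(self.atom_names, dtype=object)
        if self.residue_ids is None:
            self.residue_ids = np.arange(1, n_atoms + 1)
        else:
            self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if self.residue_names is None:
            self.residue_names = np.array(["ALA"] * n_atoms)
        else:
            self.residue_names = np.asarray(self.residue_names, dtype=object)
        for name, arr in (("atom_names", self.atom_names),
                          ("residue_ids", self.residue_ids),
                          ("residue_names", self.residue_names)):
            if len(arr) != n_atoms:
                raise MetamorphError(f"{name} has length {len(arr)}, expected {n_atoms}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def flat(self) -> np.ndarray:
        """Coordinates reshaped to ``(n_frames, 3 * n_atoms)``."""
        return self.coords.reshape(self.n_frames, 3 * self.n_atoms)

    def slice_frames(self, key) -> "Trajectory":
        return Trajectory(self.coords[key], self.atom_names, self.residue_ids,
                          self.residue_names, self.frame_stride_ps)


def select_atoms(traj: Trajectory, name_filter: str | list[str] | None = None,
                 residue_range: tuple[int, int] | None = None) -> Trajectory:
    """Subset atoms by name and/or 1-based inclusive residue range.

    Frame count and ordering are preserved. Raises
    :class:`~metamorph.exceptions.SelectionError` on an empty selection.
    """
    mask = np.ones(traj.n_atoms, dtype=bool)
    if name_filter is not None:
        names = [name_filter] if isinstance(name_filter, str) else list(name_filter)
        mask &= np.isin(np.asarray(traj.atom_names, dtype=str), names)
    if residue_range is not None:
        lo, hi = residue_range
        mask &= (traj.residue_ids >= lo) & (traj.residue_ids <= hi)
    if not mask.any():
        raise SelectionError(
            f"selection name={name_filter!r} residues={residue_range!r} matched no atoms"
        )
    return Trajectory(traj.coords[:, mask], traj.atom_names[mask],
                      traj.residue_ids[mask], traj.residue_names[mask],
                      traj.frame_stride_ps)


def read_trajectory(path: str | Path, format: str = "pdb") -> Trajectory:
    """Read a trajectory from a multi-model PDB or a plain matrix file.

    Matrix files carry no atom metadata; atoms default to CA with
    consecutive residue numbering, overridable via a JSON sidecar
    ``<path>.meta.json`` holding ``atom_names``/``residue_ids``/
    ``residue_names`` lists.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "pdb":
        return _read_pdb(path)
    if format == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown trajectory format {format!r}")


def _read_pdb(path: Path) -> Trajectory:
    import biotite.structure.io.pdb as pdbio

    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise TrajectoryFormatError(f"cannot parse PDB {path}: {exc}") from exc
    coords_nm = np.asarray(stack.coord, dtype=float) * _NM_PER_ANGSTROM
    if coords_nm.ndim == 2:  # single model
        coords_nm = coords_nm[None]
    return Trajectory(
        coords_nm,
        atom_names=np.asarray(stack.atom_name, dtype=object),
        residue_ids=np.asarray(stack.res_id, dtype=int),
        residue_names=np.asarray(stack.res_name, dtype=object),
    )


def _read_matrix(path: Path) -> Trajectory:
    try:
        data = np.loadtxt(str(path), dtype=float, ndmin=2)
    except ValueError as exc:
        raise TrajectoryFormatError(f"non-numeric entry in matrix file {path}: {exc}") from exc
    if data.shape[1] % 3 != 0:
        raise TrajectoryFormatError(
            f"matrix file {path} has {data.shape[1]} columns, not a multiple of 3"
        )
    n_atoms = data.shape[1] // 3
    meta = {}
    sidecar = path.with_name(path.name + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Trajectory(
        data.reshape(data.shape[0], n_atoms, 3),
        atom_names=np.asarray(meta["atom_names"], dtype=object) if "atom_names" in meta else None,
        residue_ids=np.asarray(meta["residue_ids"], dtype=int) if "residue_ids" in meta else None,
        residue_names=np.asarray(meta["residue_names"], dtype=object) if "residue_names" in meta else None,
    )


def write_trajectory(traj: Trajectory, path: str | Path, format: str = "pdb",
                     write_sidecar: bool = True) -> Path:
    """Write a trajectory; round-trips exactly (matrix) or to PDB precision.

    PDB coordinate fields have 3 decimals in Å, so the round-trip error is
    bounded by 5e-5 nm per coordinate.
    """
    path = Path(path)
    if traj.n_frames < 1:
        raise MetamorphError("refusing to write an empty trajectory")
    if format == "pdb":
        _write_pdb(traj, path)
    elif format == "matrix":
        np.savetxt(str(path), traj.flat(), fmt="%.17g")
        if write_sidecar:
            sidecar = path.with_name(path.name + ".meta.json")
            sidecar.write_text(json.dumps({
                "atom_names": [str(a) for a in traj.atom_names],
                "residue_ids": [int(r) for r in traj.residue_ids],
                "residue_names": [str(r) for r in traj.residue_names],
            }))
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    return path


def _write_pdb(traj: Trajectory, path: Path) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    n_frames, n_atoms = traj.n_frames, traj.n_atoms
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = traj.coords / _NM_PER_ANGSTROM
    stack.atom_name = np.asarray(traj.atom_names, dtype="U6")
    stack.res_id = traj.residue_ids
    stack.res_name = np.asarray(traj.residue_names, dtype="U5")
    stack.chain_id = np.full(n_atoms, "A", dtype="U4")
    # infer element from the first letter of the atom name (backbone atoms only)
    stack.element = np.array([str(a)[0] for a in traj.atom_names], dtype="U2")
    stack.hetero = np.zeros(n_atoms, dtype=bool)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
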