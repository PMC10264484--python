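"""Orchestrate the two-variant x two-conformer study from one config.

The config is a single declarative YAML document naming, for each variant
(e.g. XCL1 and an ancestor), the Altfold and Chemfold trajectories plus the
experimental Chemfold fraction, and globally the analysis settings. Running
the study produces plot-ready TSV tables (eigenvalue spectra, gaussianity
scores, free-energy distributions, RMSF profiles), per-variant transition
terms, and the between-variant comparison, together with a manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import essential as ed
from . import thermo as th
from .constants import (DEFAULT_BINS_PER_DIM, DEFAULT_MIN_COUNT,
                        DEFAULT_N_ESSENTIAL, DEFAULT_TEMPERATURE_K)
from .exceptions import StudyError
from .features import rmsf
from .model import FoldSwitchModel
from .trajectory import read_trajectory, select_atoms

__all__ = ["SystemConfig", "VariantConfig", "StudyConfig", "run_study"]

CONFORMER_NAMES = ("altfold", "chemfold")


@dataclass
class SystemConfig:
    """One trajectory: a variant in one fold state."""

    path: str
    format: str = "matrix"
    selection: str | None = "CA"
    residue_offset: int = 0  # shift to a shared residue numbering


@dataclass
class VariantConfig:
    conformers: dict[str, SystemConfig]
    chemfold_fraction: float | None = None

    def __post_init__(self):
        missing = [c for c in CONFORMER_NAMES if c not in self.conformers]
        if missing:
            raise StudyError(f"variant is missing conformer(s): {', '.join(missing)}",
                             system=",".join(missing), stage="config")


@dataclass
class StudyConfig:
    variants: dict[str, VariantConfig]
    temperature_K: float = DEFAULT_TEMPERATURE_K
    n_essential: int = DEFAULT_N_ESSENTIAL
    dim_mode: str = "fixed"
    epsilon: float = 3e-3
    bins_per_dim: int = DEFAULT_BINS_PER_DIM
    min_count: int = DEFAULT_MIN_COUNT
    ddG_exp: float | None = None
    superpose: bool = True

    def __post_init__(self):
        if self.temperature_K <= 0:
            raise StudyError("temperature must be positive", stage="config")
        if len(self.variants) != 2:
            raise StudyError(
                f"the comparison needs exactly two variants, got {len(self.variants)}",
                stage="config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        variants = {}
        for name, v in raw.pop("variants", {}).items():
            conformers = {c: SystemConfig(**s) for c, s in v.pop("conformers", {}).items()}
            variants[name] = VariantConfig(conformers=conformers, **v)
        return cls(variants=variants, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: StudyConfig, out_dir: str | Path) -> dict:
    """Run the full study; returns the manifest dict (also written to disk).

    Any stage failure raises a :class:`StudyError` naming the system and
    stage; outputs produced up to that point stay on disk, listed in the
    partial manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": [], "inputs": {}, "log": []}

    def _emit(rel: str, writer):
        path = out / rel
        writer(path)
        manifest["outputs"].append(rel)

    def _log(system, stage, msg):
        manifest["log"].append({"system": system, "stage": stage, "message": msg})

    results = {}
    try:
        for vname, variant in config.variants.items():
            trajs = {}
            for cname in CONFORMER_NAMES:
                sys_name = f"{vname}-{cname}"
                sc = variant.conformers[cname]
                stage = "read"
                try:
                    p = Path(sc.path)
                    trajs[cname] = read_trajectory(p, sc.format)
                    manifest["inputs"][sys_name] = {"path": str(p), "sha256": _sha256(p)}
                    _log(sys_name, stage, f"{trajs[cname].n_frames} frames, "
                                          f"{trajs[cname].n_atoms} atoms")
                except StudyError:
                    raise
                except Exception as exc:
                    raise StudyError(f"stage '{stage}' failed for system "
                                     f"'{sys_name}': {exc}",
                                     system=sys_name, stage=stage) from exc

            stage = "fit"
            try:
                sel = variant.conformers["altfold"].selection
                model = FoldSwitchModel(
                    trajs["altfold"], trajs["chemfold"], selection=sel,
                    n_essential=config.n_essential, dim_mode=config.dim_mode,
                    epsilon=config.epsilon, bins_per_dim=config.bins_per_dim,
                    min_count=config.min_count, temperature_K=config.temperature_K,
                    superpose=config.superpose)
                res = model.fit()
                results[vname] = res
                _log(vname, stage, f"d={res.essential_dim}, dG_S={res.dG_S:.4f}, "
                                   f"dG_L={res.dG_L:.4f}")
            except StudyError:
                raise
            except Exception as exc:
                raise StudyError(f"stage '{stage}' failed for system '{vname}': {exc}",
                                 system=vname, stage=stage) from exc

            stage = "report"
            try:
                for cname, fit in (("altfold", res.altfold), ("chemfold", res.chemfold)):
                    sys_name = f"{vname}-{cname}"
                    n_spec = min(20, fit.basis.eigenvalues.size)
                    _emit(f"{sys_name}.eigenvalues.tsv", lambda p, f=fit, n=n_spec:
                          pd.DataFrame({"mode": np.arange(1, n + 1),
                                        "eigenvalue_nm2": f.basis.eigenvalues[:n]}
                                       ).to_csv(p, sep="\t", index=False))
                    _emit(f"{sys_name}.gaussianity.tsv", lambda p, f=fit:
                          pd.DataFrame({"mode": f.gaussianity.mode_indices + 1,
                                        "deviation": f.gaussianity.deviation}
                                       ).to_csv(p, sep="\t", index=False))
                    edges, masses = th.free_energy_distribution(fit.table)
                    _emit(f"{sys_name}.dG_distribution.tsv",
                          lambda p, e=edges, m=masses:
                          pd.DataFrame({"dG_low_kJmol": e[:-1], "dG_high_kJmol": e[1:],
                                        "mass": m}).to_csv(p, sep="\t", index=False))
                    # RMSF on the superposed Calpha trajectory, shared numbering
                    sc = variant.conformers[cname]
                    traj = trajs[cname]
                    if sc.selection is not None:
                        traj = select_atoms(traj, name_filter=sc.selection)
                    aligned, _ = ed.superpose(traj)
                    prof = rmsf(aligned)
                    tab = prof.as_table()
                    tab["residue_id"] = tab["residue_id"] + sc.residue_offset
                    _emit(f"{sys_name}.rmsf.tsv",
                          lambda p, t=tab: t.to_csv(p, sep="\t", index=False))
                _emit(f"{vname}.conformers.tsv",
                      lambda p, r=res: r.conformer_table().to_csv(p, sep="\t", index=False))
                _emit(f"{vname}.transition.json", lambda p, r=res: p.write_text(json.dumps(
                    {"dG_S": r.dG_S, "dG_L": r.dG_L,
                     "temperature_K": r.transition.temperature_K,
                     "essential_dim": r.essential_dim}, indent=2)))
            except StudyError:
                raise
            except Exception as exc:
                raise StudyError(f"stage '{stage}' failed for system '{vname}': {exc}",
                                 system=vname, stage=stage) from exc

        stage = "compare"
        try:
            (name_a, res_a), (name_b, res_b) = results.items()
            comparison = th.evolution_comparison(res_a.transition, res_b.transition,
                                                 config.ddG_exp)
            comp = {"variant": name_a, "ancestor": name_b,
                    "ddG_S": comparison.ddG_S, "ddG_L": comparison.ddG_L,
                    "ddG_S_plus_ddG_L": comparison.ddG_S + comparison.ddG_L,
                    "ddG_exp": config.ddG_exp,
                    "ddA0_estimate": comparison.ddA0_estimate,
                    "per_variant": {}}
            for vname, res in results.items():
                frac = config.variants[vname].chemfold_fraction
                entry = {"dG_S": res.dG_S, "dG_L": res.dG_L}
                if frac is not None:
                    dg_exp = th.occupancy_to_free_energy(frac, config.temperature_K)
                    entry["dG_exp"] = dg_exp
                    entry["dimer_offset"] = th.dimer_offset(dg_exp, res.transition)
                comp["per_variant"][vname] = entry
            offs = [v.get("dimer_offset") for v in comp["per_variant"].values()
                    if "dimer_offset" in v]
            if offs:
                comp["dimer_offset_mean"] = float(np.mean(offs))
            _emit("comparison.json",
                  lambda p: p.write_text(json.dumps(comp, indent=2)))
            manifest["comparison"] = comp
        except StudyError:
            raise
        except Exception as exc:
            raise StudyError(f"stage '{stage}' failed: {exc}", stage=stage) from exc
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return manifest
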