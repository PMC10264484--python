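import numpy as np
import pytest

from metamorph import SyntheticSpec, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_backbone_trajectory(n_residues: int, n_frames: int = 3,
                             seed: int = 0) -> Trajectory:
    """Backbone (N, CA, C, O) trajectory with mild jitter, for selection tests."""
    rng = np.random.default_rng(seed)
    names, res_ids, res_names = [], [], []
    base = []
    for r in range(1, n_residues + 1):
        for k, name in enumerate(("N", "CA", "C", "O")):
            names.append(name)
            res_ids.append(r)
            res_names.append("ALA")
            base.append([0.38 * r + 0.08 * k, 0.1 * (k % 2), 0.0])
    base = np.asarray(base)
    coords = base[None] + 0.01 * rng.standard_normal((n_frames, len(base), 3))
    return Trajectory(coords, np.array(names, dtype=object),
                      np.array(res_ids), np.array(res_names, dtype=object))


@pytest.fixture
def box_spec_pair():
    """Two-conformer uniform-box specs whose thermodynamics are known exactly."""
    common = dict(n_atoms=10, constraint_sigmas=[0.02] * 5, basis_seed=7)
    c1 = SyntheticSpec(n_frames=20_000, sample_seed=11,
                       essential_modes=["uniform(0,1)", "uniform(0,0.5)"], **common)
    c2 = SyntheticSpec(n_frames=20_000, sample_seed=13,
                       essential_modes=["uniform(0,2.5)", "uniform(0,2)"], **common)
    return c1, c2
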