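"""Essential dynamics: superposition, covariance, modes, gaussianity."""

import warnings

import numpy as np
import pytest
from scipy.stats import norm

from metamorph import (GaussianityReport, ProjectionSeries, SyntheticSpec,
                       Trajectory, covariance, eigendecompose,
                       gaussianity_deviation, generate_basis,
                       generate_trajectory, mode_components, project,
                       select_essential_dim, superpose)
from metamorph.exceptions import (InsufficientDataError, MetamorphError,
                                  SuperpositionError)
from metamorph.synthetic import helix_mean_structure, _random_rotation


def _rigidly_scrambled(structure, n_frames, seed):
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        rot = _random_rotation(rng, np.pi)
        trans = rng.uniform(-1, 1, size=3)
        frames.append(structure @ rot.T + trans)
    return Trajectory(np.stack(frames))


class TestSuperpose:
    def test_pure_rigid_motion_removed_exactly(self):
        structure = helix_mean_structure(12)
        traj = _rigidly_scrambled(structure, 20, seed=3)
        aligned, mean = superpose(traj)
        rmsd = np.sqrt(np.mean(np.sum((aligned.coords - mean) ** 2, axis=2),
                               axis=(0, 1)))
        assert rmsd < 1e-9

    def test_idempotent_on_aligned_input(self):
        spec = SyntheticSpec(n_atoms=8, n_frames=500,
                             essential_modes=["gaussian(0.1)"], basis_seed=1,
                             sample_seed=2)
        traj, _ = generate_trajectory(spec)
        once, _ = superpose(traj)
        twice, _ = superpose(once)
        assert np.abs(twice.coords - once.coords).max() < 1e-10

    def test_collinear_reference_rejected(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        traj = Trajectory(np.stack([line, line + 0.1]))
        with pytest.raises(SuperpositionError):
            superpose(traj)

    def test_single_frame_rejected(self):
        with pytest.raises(InsufficientDataError):
            superpose(Trajectory(helix_mean_structure(5)[None]))


class TestCovariance:
    def test_mirrored_pair_has_rank_one(self):
        base = helix_mean_structure(5)
        delta = np.random.default_rng(0).standard_normal(base.shape) * 0.1
        traj = Trajectory(np.stack([base + delta, base - delta]))
        c = covariance(traj)
        assert np.linalg.matrix_rank(c, tol=1e-10) <= 1

    def test_trace_equals_total_mean_square_fluctuation(self):
        spec = SyntheticSpec(n_atoms=6, n_frames=300,
                             essential_modes=["uniform(0,1)"], sample_seed=8)
        traj, _ = generate_trajectory(spec)
        c = covariance(traj)
        x = traj.flat()
        msf = np.mean(np.sum((x - x.mean(axis=0)) ** 2, axis=1))
        assert np.trace(c) == pytest.approx(msf, rel=1e-10)

    def test_planted_variances_on_basis_diagonal(self):
        spec = SyntheticSpec(n_atoms=8, n_frames=30_000,
                             essential_modes=["gaussian(0.2)", "gaussian(0.1)"],
                             constraint_sigmas=[0.01] * 4,
                             basis_seed=5, sample_seed=6)
        traj, truth = generate_trajectory(spec)
        basis = generate_basis(8, 5)
        c = covariance(traj)
        diag = np.diag(basis.T @ c @ basis)[:2]
        assert np.abs(diag / truth.planted_eigenvalues[:2] - 1).max() < 0.05

    def test_single_frame_rejected(self):
        with pytest.raises(InsufficientDataError):
            covariance(Trajectory(np.zeros((1, 4, 3)) + helix_mean_structure(4)))


class TestEigendecompose:
    def test_identity_covariance(self):
        basis = eigendecompose(np.eye(9))
        assert np.allclose(basis.eigenvalues, 1.0)
        assert np.abs(basis.eigenvectors.T @ basis.eigenvectors - np.eye(9)).max() < 1e-8

    def test_spectral_reconstruction(self, rng):
        a = rng.standard_normal((12, 12))
        c = a @ a.T / 12
        basis = eigendecompose(c)
        rec = basis.eigenvectors @ np.diag(basis.eigenvalues) @ basis.eigenvectors.T
        assert np.abs(rec - c).max() < 1e-8
        assert (np.diff(basis.eigenvalues) <= 1e-12).all()

    def test_sign_convention(self, rng):
        a = rng.standard_normal((9, 9))
        basis = eigendecompose(a @ a.T)
        for k in range(9):
            v = basis.eigenvectors[:, k]
            assert v[np.argmax(np.abs(v))] > 0

    def test_asymmetric_input_rejected(self):
        c = np.eye(6)
        c[0, 1] = 1e-3
        with pytest.raises(MetamorphError):
            eigendecompose(c)


class TestProject:
    @pytest.fixture
    def fitted(self):
        spec = SyntheticSpec(n_atoms=6, n_frames=2_000,
                             essential_modes=["uniform(0,1)", "gaussian(0.2)"],
                             constraint_sigmas=[0.01] * 3, sample_seed=21)
        traj, _ = generate_trajectory(spec)
        mean = traj.coords.mean(axis=0)
        basis = eigendecompose(covariance(traj), mean)
        return traj, basis

    def test_mean_structure_projects_to_zero(self, fitted):
        traj, basis = fitted
        series = project(Trajectory(basis.mean_structure[None]), basis)
        assert np.abs(series.values).max() < 1e-10

    def test_column_variance_equals_eigenvalue(self, fitted):
        traj, basis = fitted
        series = project(traj, basis)
        var = series.values.var(axis=0)
        assert np.abs(var - basis.eigenvalues).max() < 1e-8

    def test_distinct_modes_uncorrelated(self, fitted):
        traj, basis = fitted
        series = project(traj, basis, [0, 1, 2])
        x = series.values - series.values.mean(axis=0)
        cross = x.T @ x / len(x)
        off = cross - np.diag(np.diag(cross))
        assert np.abs(off).max() < 1e-8

    def test_out_of_range_mode_index(self, fitted):
        traj, basis = fitted
        with pytest.raises(IndexError):
            project(traj, basis, [99])


def _series(samples):
    return ProjectionSeries(np.asarray(samples)[:, None], np.array([0]))


class TestGaussianity:
    def test_gaussian_null_scores_near_noise_floor(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 0.3, size=100_000)
        rep = gaussianity_deviation(_series(x), n_bins=50)
        assert rep.deviation[0] < 1e-3

    def test_uniform_matches_closed_form_bin_masses(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(-1, 1, size=200_000)
        rep = gaussianity_deviation(_series(x), n_bins=50)
        mu, sigma = x.mean(), x.std()
        edges = np.linspace(mu - 4 * sigma, mu + 4 * sigma, 51)
        uniform_mass = np.diff(np.clip(edges, -1, 1)) / 2
        gauss_mass = np.diff(norm.cdf(edges, mu, sigma))
        expected = np.mean(np.abs(uniform_mass - gauss_mass))
        assert rep.deviation[0] == pytest.approx(expected, abs=1e-3)

    def test_symmetric_mixture_matches_quadrature_oracle(self):
        rng = np.random.default_rng(9)
        s, m = 0.05, 0.15  # components at +-3 sigma
        comp = rng.integers(0, 2, size=200_000)
        x = rng.normal(np.where(comp, m, -m), s)
        rep = gaussianity_deviation(_series(x), n_bins=50)
        mu, sigma = x.mean(), x.std()
        edges = np.linspace(mu - 4 * sigma, mu + 4 * sigma, 51)
        mix_mass = 0.5 * np.diff(norm.cdf(edges, -m, s)) + \
            0.5 * np.diff(norm.cdf(edges, m, s))
        gauss_mass = np.diff(norm.cdf(edges, mu, sigma))
        expected = np.mean(np.abs(mix_mass - gauss_mass))
        assert expected > 5e-3  # clearly non-Gaussian
        assert rep.deviation[0] == pytest.approx(expected, abs=1e-3)

    def test_deviation_shrinks_with_more_frames(self):
        # null (Gaussian) score decreases with sampling, averaged over seeds
        small, large = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            small.append(gaussianity_deviation(
                _series(rng.normal(size=1_000)), 50).deviation[0])
            large.append(gaussianity_deviation(
                _series(rng.normal(size=30_000)), 50).deviation[0])
        assert np.mean(large) < np.mean(small)

    def test_zero_variance_mode_warns_and_scores_zero(self):
        with pytest.warns(UserWarning):
            rep = gaussianity_deviation(_series(np.ones(200)), 20)
        assert rep.deviation[0] == 0.0

    def test_too_few_frames_rejected(self):
        with pytest.raises(InsufficientDataError):
            gaussianity_deviation(_series(np.arange(50.0)), 10)


class TestSelectDim:
    def test_fixed_ignores_scores(self):
        rep = GaussianityReport(np.full(10, 1e-4), np.arange(10))
        assert select_essential_dim(rep, "fixed", k=6) == 6

    def test_threshold_finds_score_gap(self):
        dev = np.array([0.02, 0.015, 0.01, 1e-4, 2e-4, 1e-4])
        rep = GaussianityReport(dev, np.arange(6))
        assert select_essential_dim(rep, "threshold", epsilon=3e-3) == 3

    def test_all_gaussian_defaults_to_one_with_warning(self):
        rep = GaussianityReport(np.full(8, 1e-5), np.arange(8))
        with pytest.warns(UserWarning):
            assert select_essential_dim(rep, "threshold", epsilon=3e-3) == 1


class TestModeComponents:
    def test_unit_mass(self):
        basis = eigendecompose(np.eye(15))
        comp = mode_components(basis, 0)
        assert np.sum(comp ** 2) == pytest.approx(1.0, abs=1e-10)

    def test_single_atom_mode(self):
        c = np.zeros((9, 9))
        c[3, 3] = 1.0  # atom 1 (0-based), x-component
        basis = eigendecompose(c)
        comp = mode_components(basis, 0)
        assert comp[1] == pytest.approx(1.0, abs=1e-10)
        assert comp[[0, 2]].max() < 1e-10

    def test_out_of_range(self):
        basis = eigendecompose(np.eye(9))
        with pytest.raises(IndexError):
            mode_components(basis, 9)


def test_spectrum_invariant_under_global_rigid_transform():
    spec = SyntheticSpec(n_atoms=8, n_frames=2_000,
                         essential_modes=["uniform(0,0.6)"],
                         constraint_sigmas=[0.01] * 4, sample_seed=17)
    traj, _ = generate_trajectory(spec)
    rng = np.random.default_rng(1)
    rot = _random_rotation(rng, np.pi)
    moved = Trajectory(traj.coords @ rot.T + np.array([1.0, -2.0, 0.5]))
    e1 = eigendecompose(covariance(superpose(traj)[0])).eigenvalues
    e2 = eigendecompose(covariance(superpose(moved)[0])).eigenvalues
    assert np.abs(e1 - e2).max() < 1e-8
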