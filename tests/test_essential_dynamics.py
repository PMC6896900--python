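"""PCA mode recovery, projections (Parseval), and KDE landscapes."""

import numpy as np
import pytest

from nucdyn.errors import InputError
from nucdyn.essential_dynamics import (
    arrow_norms,
    compute_modes,
    estimate_landscape,
    export_mode_arrows,
    project,
)
from nucdyn.structure_io import AnalysisWindow, TrajectoryEnsemble, Trial
from nucdyn.topology import AtomSite, ComplexTopology, SelectionMask


def bead_ensemble(frames_arrays, n_beads):
    atoms = [
        AtomSite(i + 1, "C1'", "C", "I", i + 1, "DA", np.zeros(3))
        for i in range(n_beads)
    ]
    topo = ComplexTopology([("I", "DNA-I")], atoms)
    trials = [
        Trial(10.0 * np.arange(1, fr.shape[0] + 1), fr) for fr in frames_arrays
    ]
    return TrajectoryEnsemble(topo, trials, 10.0)


def injected_mode_ensemble(
    n_beads=20, n_frames=5000, amp=3.0, sigma=0.3, period=100, seed=0
):
    """X(tau) = base + amp*sin(w tau)*u + noise, u a unit 3N vector."""
    rng = np.random.default_rng(seed)
    base = rng.normal(scale=10.0, size=(n_beads, 3))
    u = rng.normal(size=3 * n_beads)
    u /= np.linalg.norm(u)
    phases = np.sin(2 * np.pi * np.arange(n_frames) / period)
    frames = (
        base.reshape(-1)[None]
        + amp * phases[:, None] * u[None]
        + rng.normal(scale=sigma, size=(n_frames, 3 * n_beads))
    ).reshape(n_frames, n_beads, 3)
    return bead_ensemble([frames], n_beads), u


class TestComputeModes:
    def test_static_ensemble_all_eigenvalues_zero(self):
        base = np.arange(12, dtype=float).reshape(4, 3)
        frames = np.repeat(base[None], 5, axis=0)
        ens = bead_ensemble([frames], 4)
        res = compute_modes(ens, SelectionMask(np.arange(4), "custom"), AnalysisWindow.full())
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-10)

    def test_injected_mode_recovered(self):
        amp, sigma = 3.0, 0.3
        ens, u = injected_mode_ensemble(amp=amp, sigma=sigma)
        res = compute_modes(ens, SelectionMask(np.arange(20), "custom"), AnalysisWindow.full())
        assert abs(res.eigenvectors[0] @ u) > 0.99
        expected_l1 = amp**2 / 2.0 + sigma**2
        assert res.eigenvalues[0] == pytest.approx(expected_l1, rel=0.10)

    def test_matches_brute_force_eigendecomposition(self):
        rng = np.random.default_rng(1)
        frames = rng.normal(size=(6, 4, 3))
        ens = bead_ensemble([frames], 4)
        res = compute_modes(ens, SelectionMask(np.arange(4), "custom"), AnalysisWindow.full())
        x = frames.reshape(6, 12)
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc / 6.0
        evals_o = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(res.eigenvalues, evals_o, atol=1e-10)
        for j in range(12):
            resid = cov @ res.eigenvectors[j] - res.eigenvalues[j] * res.eigenvectors[j]
            assert np.linalg.norm(resid) < 1e-8

    def test_eigenvectors_orthonormal_and_variance_complete(self):
        rng = np.random.default_rng(2)
        frames = rng.normal(size=(50, 5, 3))
        ens = bead_ensemble([frames], 5)
        res = compute_modes(ens, SelectionMask(np.arange(5), "custom"), AnalysisWindow.full())
        gram = res.eigenvectors @ res.eigenvectors.T
        np.testing.assert_allclose(gram, np.eye(15), atol=1e-8)
        x = frames.reshape(50, 15)
        total_var = np.sum(np.var(x, axis=0))
        assert res.total_variance == pytest.approx(total_var, rel=1e-6)

    def test_frame_and_trial_order_invariance(self):
        rng = np.random.default_rng(3)
        fr_a = rng.normal(size=(30, 4, 3))
        fr_b = rng.normal(size=(30, 4, 3))
        mask = SelectionMask(np.arange(4), "custom")
        res1 = compute_modes(bead_ensemble([fr_a, fr_b], 4), mask, AnalysisWindow.full())
        res2 = compute_modes(bead_ensemble([fr_b, fr_a[::-1].copy()], 4), mask, AnalysisWindow.full())
        np.testing.assert_allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-10)

    def test_mean_centering_invariance(self):
        rng = np.random.default_rng(4)
        frames = rng.normal(size=(40, 3, 3))
        mask = SelectionMask(np.arange(3), "custom")
        res1 = compute_modes(bead_ensemble([frames], 3), mask, AnalysisWindow.full())
        res2 = compute_modes(
            bead_ensemble([frames + np.array([5.0, -2.0, 9.0])], 3),
            mask,
            AnalysisWindow.full(),
        )
        np.testing.assert_allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-9)


class TestProject:
    def test_mean_frame_projects_to_zero_and_unit_mode_scale(self):
        rng = np.random.default_rng(5)
        frames = rng.normal(size=(20, 4, 3))
        ens = bead_ensemble([frames], 4)
        mask = SelectionMask(np.arange(4), "custom")
        res = compute_modes(ens, mask, AnalysisWindow.full())
        mean_frame = res.mean_structure[None]
        ens_mean = bead_ensemble([np.repeat(mean_frame, 2, axis=0)], 4)
        proj = project(ens_mean, res, (1, 2))
        np.testing.assert_allclose(proj.values[0], 0.0, atol=1e-10)
        # frame = mean + 2.5 v1 projects to exactly (2.5, 0)
        shifted = res.mean_structure.reshape(-1) + 2.5 * res.eigenvectors[0]
        ens_shift = bead_ensemble([np.repeat(shifted.reshape(1, 4, 3), 2, axis=0)], 4)
        proj2 = project(ens_shift, res, (1, 2))
        np.testing.assert_allclose(proj2.values[0][:, 0], 2.5, atol=1e-10)
        np.testing.assert_allclose(proj2.values[0][:, 1], 0.0, atol=1e-10)

    def test_parseval_completeness_with_all_modes(self):
        rng = np.random.default_rng(6)
        frames = rng.normal(size=(25, 3, 3))
        ens = bead_ensemble([frames], 3)
        mask = SelectionMask(np.arange(3), "custom")
        res = compute_modes(ens, mask, AnalysisWindow.full())
        proj = project(ens, res, tuple(range(1, 10)))
        x = frames.reshape(25, 9)
        mean = res.mean_structure.reshape(-1)
        direct = np.sum((x - mean) ** 2, axis=1)
        via_modes = np.sum(proj.values[0] ** 2, axis=1)
        np.testing.assert_allclose(via_modes, direct, rtol=1e-6)

    def test_mode_out_of_range_raises(self):
        rng = np.random.default_rng(7)
        frames = rng.normal(size=(10, 2, 3))
        ens = bead_ensemble([frames], 2)
        res = compute_modes(ens, SelectionMask(np.arange(2), "custom"), AnalysisWindow.full())
        with pytest.raises(InputError):
            project(ens, res, (7,))


class TestLandscape:
    def test_moment_recovery_from_known_gaussian(self):
        rng = np.random.default_rng(8)
        mean = np.array([1.0, -2.0])
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        samples = rng.multivariate_normal(mean, cov, size=10_000)
        ls = estimate_landscape(samples, grid_size=(160, 160))
        assert ls.integral() == pytest.approx(1.0, abs=0.02)
        g1, g2 = np.meshgrid(ls.s1, ls.s2, indexing="ij")
        w = ls.density / ls.density.sum()
        m1 = np.sum(w * g1)
        m2 = np.sum(w * g2)
        assert m1 == pytest.approx(mean[0], abs=0.05 * np.sqrt(cov[0, 0]))
        assert m2 == pytest.approx(mean[1], abs=0.05 * np.sqrt(cov[1, 1]))
        v1 = np.sum(w * (g1 - m1) ** 2)
        # KDE inflates variance by the squared bandwidth; accept 5%
        assert v1 == pytest.approx(cov[0, 0], rel=0.05)

    def test_identical_points_give_delta_like_peak(self):
        samples = np.tile([[0.5, 0.5]], (10, 1))
        with pytest.warns(UserWarning):
            ls = estimate_landscape(samples)
        imax = np.unravel_index(np.argmax(ls.density), ls.density.shape)
        assert ls.s1[imax[0]] == pytest.approx(0.5, abs=1e-3)
        assert ls.s2[imax[1]] == pytest.approx(0.5, abs=1e-3)

    def test_density_negligible_far_from_disc_support(self):
        rng = np.random.default_rng(9)
        r = np.sqrt(rng.uniform(0, 1, 4000))
        th = rng.uniform(0, 2 * np.pi, 4000)
        samples = np.column_stack([r * np.cos(th), r * np.sin(th)])
        ls = estimate_landscape(samples, grid_size=(120, 120))
        g1, g2 = np.meshgrid(ls.s1, ls.s2, indexing="ij")
        bw = (ls.s1[-1] - 1.0) / 3.0  # margin is 3 bandwidths past the support
        outside = np.sqrt(g1**2 + g2**2) > 1.0 + 3 * bw
        if np.any(outside):
            assert ls.density[outside].max() < 0.01 * ls.density.max()

    def test_single_point_input_rejected(self):
        with pytest.raises(InputError):
            estimate_landscape(np.array([[1.0, 2.0]]))


class TestModeArrows:
    def test_unit_mode_norms_and_orthogonality(self):
        rng = np.random.default_rng(10)
        frames = rng.normal(size=(30, 4, 3))
        ens = bead_ensemble([frames], 4)
        res = compute_modes(ens, SelectionMask(np.arange(4), "custom"), AnalysisWindow.full())
        arrows = export_mode_arrows(res, (1, 2), scale=1.0)
        assert np.sum(arrow_norms(arrows[1]) ** 2) == pytest.approx(1.0, abs=1e-10)
        assert arrows[1].reshape(-1) @ arrows[2].reshape(-1) == pytest.approx(0.0, abs=1e-10)

    def test_arrows_concentrate_on_injected_arm(self):
        rng = np.random.default_rng(11)
        n_beads, n_frames = 30, 2000
        base = rng.normal(scale=10.0, size=(n_beads, 3))
        u = np.zeros((n_beads, 3))
        u[:6] = rng.normal(size=(6, 3))  # "arm" = first 6 beads
        u = u.reshape(-1) / np.linalg.norm(u)
        phases = np.sin(2 * np.pi * np.arange(n_frames) / 80)
        frames = (
            base.reshape(-1)[None]
            + 4.0 * phases[:, None] * u[None]
            + rng.normal(scale=0.2, size=(n_frames, 3 * n_beads))
        ).reshape(n_frames, n_beads, 3)
        ens = bead_ensemble([frames], n_beads)
        res = compute_modes(ens, SelectionMask(np.arange(n_beads), "custom"), AnalysisWindow.full())
        arrows = export_mode_arrows(res, (1,))[1]
        norms2 = arrow_norms(arrows) ** 2
        assert norms2[:6].sum() / norms2.sum() > 0.8
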