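"""Kabsch superposition against brute-force and closed-form oracles."""

import numpy as np
import pytest

from nucdyn.errors import DegenerateGeometryError, InputError
from nucdyn.structure_io import TrajectoryEnsemble, Trial
from nucdyn.superposition import align_ensemble, kabsch_superpose, structure_rmsd
from nucdyn.topology import AtomSite, ComplexTopology, SelectionMask


def random_rotation(rng):
    """Uniform random rotation from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quaternion_grid_min_rmsd(a, b, n_orientations=100_000, seed=0):
    """Brute-force oracle: minimum RMSD over a random quaternion grid.

    For centered sets, rmsd^2(R) = (|a|^2 + |b|^2 - 2 tr(R M)) / n with
    M = sum_i a_i b_i^T, so the grid scan reduces to one einsum.
    """
    rng = np.random.default_rng(seed)
    q = rng.normal(size=(n_orientations, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    rots = np.empty((n_orientations, 3, 3))
    rots[:, 0, 0] = 1 - 2 * (y * y + z * z)
    rots[:, 0, 1] = 2 * (x * y - w * z)
    rots[:, 0, 2] = 2 * (x * z + w * y)
    rots[:, 1, 0] = 2 * (x * y + w * z)
    rots[:, 1, 1] = 1 - 2 * (x * x + z * z)
    rots[:, 1, 2] = 2 * (y * z - w * x)
    rots[:, 2, 0] = 2 * (x * z - w * y)
    rots[:, 2, 1] = 2 * (y * z + w * x)
    rots[:, 2, 2] = 1 - 2 * (x * x + y * y)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    m = b0.T @ a0  # tr(R_ab M) over rotated a
    const = np.sum(a0 * a0) + np.sum(b0 * b0)
    tr = np.einsum("nij,ij->n", rots, m.T)
    best = (const - 2.0 * tr.max()) / a.shape[0]
    return float(np.sqrt(max(best, 0.0)))


class TestKabsch:
    def test_identity_on_equal_inputs(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(8, 3))
        res = kabsch_superpose(coords, coords)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(res.translation, 0.0, atol=1e-12)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_exact_recovery_of_rigid_motion(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(scale=4.0, size=(10, 3))
        rot90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = ref @ rot90.T + np.array([5.0, 0.0, 0.0])
        res = kabsch_superpose(moved, ref)
        assert res.rmsd < 1e-9
        np.testing.assert_allclose(res.apply(moved), ref, atol=1e-9)

    def test_rotation_is_proper_orthonormal(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(size=(6, 3))
            b = rng.normal(size=(6, 3))
            res = kabsch_superpose(a, b)
            np.testing.assert_allclose(
                res.rotation.T @ res.rotation, np.eye(3), atol=1e-8
            )
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_never_beaten_by_quaternion_grid_oracle(self):
        # the SVD solution is the global optimum, so the grid can never do better
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = rng.normal(size=(6, 3))
            b = rng.normal(size=(6, 3))
            kab = kabsch_superpose(a, b).rmsd
            grid = quaternion_grid_min_rmsd(a, b, n_orientations=20_000, seed=int(rng.integers(1 << 31)))
            assert kab <= grid + 1e-9

    def test_symmetry_and_rigid_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(7, 3))
        b = rng.normal(size=(7, 3))
        r_ab = kabsch_superpose(a, b).rmsd
        r_ba = kabsch_superpose(b, a).rmsd
        assert r_ab == pytest.approx(r_ba, abs=1e-8)
        rot = random_rotation(rng)
        a_moved = a @ rot.T + np.array([1.0, -2.0, 3.0])
        assert kabsch_superpose(a_moved, b).rmsd == pytest.approx(r_ab, abs=1e-8)

    def test_mask_duplication_equals_correspondence_duplication(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        mask_dup = np.array([0, 0, 1, 2, 3, 4])
        res_dup_mask = kabsch_superpose(a, b, mask_dup)
        a2 = np.vstack([a[0], a])
        b2 = np.vstack([b[0], b])
        res_dup_rows = kabsch_superpose(a2, b2)
        np.testing.assert_allclose(res_dup_mask.rotation, res_dup_rows.rotation, atol=1e-10)
        assert res_dup_mask.rmsd == pytest.approx(res_dup_rows.rmsd, abs=1e-10)

    def test_degenerate_inputs_raise(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line + 1.0)
        two = np.array([[0.0, 0, 0], [1.0, 1, 1]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(two, two)
        with pytest.raises(InputError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestStructureRmsd:
    def test_self_rmsd_zero(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(size=(6, 3))
        assert structure_rmsd(coords, coords) == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_four_point_procrustes(self):
        # unit square vs the same square stretched along x by factor 2:
        # the optimal rotation is the identity; centered residuals are
        # (+-0.5, 0, 0), so rmsd = 0.5
        square = np.array(
            [[0.0, 0, 0], [1.0, 0, 0], [1.0, 1, 0], [0.0, 1, 0]]
        )
        stretched = np.array(
            [[0.0, 0, 0], [2.0, 0, 0], [2.0, 1, 0], [0.0, 1, 0]]
        )
        assert structure_rmsd(stretched, square) == pytest.approx(0.5, abs=1e-12)

    def test_separate_fit_and_measure_masks(self):
        rng = np.random.default_rng(7)
        ref = rng.normal(scale=3.0, size=(8, 3))
        rot = random_rotation(rng)
        moved = ref @ rot.T + 2.0
        moved[6:] += np.array([3.0, 4.0, 0.0])  # deform the measured subset only
        fit = np.arange(6)
        measure = np.array([6, 7])
        r = structure_rmsd(moved, ref, fit, measure)
        assert r == pytest.approx(5.0, abs=1e-6)


def _micro_ensemble(frames, topo_atoms=None):
    n = frames.shape[1]
    atoms = [
        AtomSite(i + 1, "CA", "C", "A", 45 + i, "ALA", np.zeros(3)) for i in range(n)
    ]
    topo = ComplexTopology([("A", "H3")], atoms)
    times = 10.0 * np.arange(1, frames.shape[0] + 1)
    return TrajectoryEnsemble(topo, [Trial(times, frames)], 10.0)


class TestAlignEnsemble:
    def test_static_ensemble_unchanged(self):
        rng = np.random.default_rng(8)
        base = rng.normal(scale=5.0, size=(6, 3))
        frames = np.repeat(base[None], 4, axis=0)
        ens = _micro_ensemble(frames)
        mask = SelectionMask(np.arange(6))
        aligned = align_ensemble(ens, "whole_complex", fit_mask=mask)
        np.testing.assert_allclose(
            aligned.trials[0].coordinates, frames, atol=1e-10
        )

    def test_rigid_motions_removed(self):
        rng = np.random.default_rng(9)
        base = rng.normal(scale=5.0, size=(6, 3))
        frames = np.empty((5, 6, 3))
        frames[0] = base
        for f in range(1, 5):
            frames[f] = base @ random_rotation(rng).T + rng.normal(size=3)
        ens = _micro_ensemble(frames)
        aligned = align_ensemble(ens, "whole_complex", fit_mask=SelectionMask(np.arange(6)))
        for f in range(5):
            np.testing.assert_allclose(aligned.trials[0].coordinates[f], base, atol=1e-6)

    def test_stored_transforms_reproduce_aligned_frames(self):
        rng = np.random.default_rng(10)
        base = rng.normal(scale=5.0, size=(6, 3))
        frames = base[None] + rng.normal(scale=0.3, size=(4, 6, 3))
        ens = _micro_ensemble(frames)
        aligned = align_ensemble(ens, "whole_complex", fit_mask=SelectionMask(np.arange(6)))
        for f in range(4):
            redo = frames[f] @ aligned.rotations[0][f].T + aligned.translations[0][f]
            np.testing.assert_allclose(
                redo, aligned.trials[0].coordinates[f], atol=1e-6
            )

    def test_core_fit_preserves_internal_deformation_elsewhere(self):
        # fit on atoms 0..5; atoms 6..7 carry an internal deformation that the
        # per-frame oracle fit must leave intact
        rng = np.random.default_rng(11)
        base = rng.normal(scale=5.0, size=(8, 3))
        frames = np.empty((4, 8, 3))
        deform = np.zeros((4, 8, 3))
        for f in range(4):
            deform[f, 6:] = rng.normal(scale=2.0, size=(2, 3))
            rot = random_rotation(rng)
            frames[f] = (base + deform[f]) @ rot.T + rng.normal(size=3)
        ens = _micro_ensemble(frames)
        fit_mask = SelectionMask(np.arange(6))
        aligned = align_ensemble(
            ens, "histone_core_only", reference=base, fit_mask=fit_mask
        )
        for f in range(4):
            got = aligned.trials[0].coordinates[f]
            # oracle: superpose frame onto base with the same mask
            res = kabsch_superpose(frames[f], base, fit_mask)
            np.testing.assert_allclose(got, res.apply(frames[f]), atol=1e-9)
            # fitted subset returns to base, deformed subset keeps its offset size
            np.testing.assert_allclose(got[:6], base[:6], atol=1e-6)
            assert np.linalg.norm(got[6:] - base[6:]) == pytest.approx(
                np.linalg.norm(deform[f, 6:]), rel=1e-6
            )
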