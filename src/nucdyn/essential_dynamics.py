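"""Essential dynamics: coordinate PCA of DNA C1' atoms and KDE landscapes.

The stacked coordinate vector X(tau) = (x_1, ..., x_N) of the N C1' atoms
(after histone-core alignment) is mean-centered over the analysis window
pooled across trials; the symmetric eigendecomposition of its covariance
yields collective deformation modes v_j with variances lambda_j.  Frame
projections S(tau, j) = (X(tau) - <X>) . v_j trace each trajectory in mode
space, and a 2-D Gaussian kernel density over (S_1, S_2) gives the
probability-density landscape whose negative log is a free-energy surface up
to kT.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from nucdyn.errors import InputError
from nucdyn.structure_io import AnalysisWindow, TrajectoryEnsemble, resolve_window
from nucdyn.superposition import AlignedEnsemble
from nucdyn.topology import SelectionMask, mask_labels_for_atoms

logger = logging.getLogger(__name__)


@dataclass
class EssentialDynamicsResult:
    """Mean structure, eigenvectors (rows, unit 3N-vectors) and eigenvalues (A^2)."""

    mean_structure: np.ndarray  # (N, 3)
    eigenvectors: np.ndarray  # (3N, 3N), row j = v_j, descending eigenvalue
    eigenvalues: np.ndarray  # (3N,), descending
    n_atoms: int
    mask_indices: np.ndarray = field(default=None)  # type: ignore[assignment]
    labels: list[tuple[str, int]] = field(default_factory=list)

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


@dataclass
class ProjectionSeries:
    """Per-trial, per-frame mode displacements S(tau, mode) in A."""

    modes: tuple[int, ...]  # 1-based mode numbers
    times: list[np.ndarray]
    values: list[np.ndarray]  # per trial: (frames, len(modes))

    def pooled(self, frame_sets: list[np.ndarray] | None = None) -> np.ndarray:
        """Stack all trials' values, optionally restricted to window frames."""
        if frame_sets is None:
            return np.concatenate(self.values, axis=0)
        return np.concatenate(
            [v[f] for v, f in zip(self.values, frame_sets)], axis=0
        )

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for k, (t, v) in enumerate(zip(self.times, self.values)):
            d = {"trial": k, "time_ps": t}
            for j, m in enumerate(self.modes):
                d[f"S{m}"] = v[:, j]
            rows.append(pd.DataFrame(d))
        return pd.concat(rows, ignore_index=True)


def _window_coords(
    ensemble, mask: SelectionMask, window: AnalysisWindow | None
) -> tuple[TrajectoryEnsemble, np.ndarray]:
    if isinstance(ensemble, AlignedEnsemble):
        ens = ensemble.ensemble
    elif isinstance(ensemble, TrajectoryEnsemble):
        ens = ensemble
    else:
        raise InputError("expected an AlignedEnsemble or TrajectoryEnsemble")
    frame_sets = resolve_window(ens, window)
    idx = mask.indices
    stacked = np.concatenate(
        [
            trial.coordinates[frames][:, idx, :]
            for trial, frames in zip(ens.trials, frame_sets)
        ],
        axis=0,
    )
    return ens, stacked


def compute_modes(
    aligned: AlignedEnsemble | TrajectoryEnsemble,
    dna_c1p_mask: SelectionMask,
    window: AnalysisWindow | None = None,
) -> EssentialDynamicsResult:
    """Eigendecomposition of the pooled positional covariance of masked atoms.

    Covariance is taken over the window frames of all trials together
    (population normalization, so the eigenvalue sum equals the total
    positional variance).  Eigenvector signs are fixed so each vector's
    largest-magnitude component is positive; within numerically degenerate
    eigenvalues the ordering is by eigenvalue then by first differing
    component, which is arbitrary but stable.
    """
    if len(dna_c1p_mask) == 0:
        raise InputError("mask selects no atoms")
    ens, coords = _window_coords(aligned, dna_c1p_mask, window)
    n_frames, n_atoms = coords.shape[0], coords.shape[1]
    if n_frames == 0:
        raise InputError("window selects no frames")
    if n_frames < 3 * n_atoms:
        warnings.warn(
            f"covariance from {n_frames} frames for {3 * n_atoms} coordinates "
            "is rank-deficient; trailing modes are noise",
            stacklevel=2,
        )
    x = coords.reshape(n_frames, 3 * n_atoms)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = (xc.T @ xc) / n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order].T  # rows are eigenvectors
    # deterministic sign: largest-|component| positive
    for j in range(evecs.shape[0]):
        k = int(np.argmax(np.abs(evecs[j])))
        if evecs[j, k] < 0:
            evecs[j] = -evecs[j]
    return EssentialDynamicsResult(
        mean_structure=mean.reshape(n_atoms, 3),
        eigenvectors=evecs,
        eigenvalues=evals,
        n_atoms=n_atoms,
        mask_indices=dna_c1p_mask.indices.copy(),
        labels=mask_labels_for_atoms(ens.topology, dna_c1p_mask),
    )


def project(
    aligned: AlignedEnsemble | TrajectoryEnsemble,
    result: EssentialDynamicsResult,
    modes: tuple[int, ...] = (1, 2),
) -> ProjectionSeries:
    """S(tau, mode) = (X(tau) - <X>) . v_mode for every frame of every trial.

    All frames are projected (trajectories are drawn over the landscape in
    full), not only the window the covariance was built from.  Modes are
    1-based.
    """
    if isinstance(aligned, AlignedEnsemble):
        ens = aligned.ensemble
    else:
        ens = aligned
    n_modes = result.eigenvectors.shape[0]
    for m in modes:
        if not 1 <= m <= n_modes:
            raise InputError(f"mode {m} out of range 1..{n_modes}")
    idx = result.mask_indices
    mean = result.mean_structure.reshape(-1)
    vecs = result.eigenvectors[[m - 1 for m in modes]]  # (k, 3N)
    times, values = [], []
    for trial in ens.trials:
        x = trial.coordinates[:, idx, :].reshape(trial.n_frames, -1)
        values.append((x - mean) @ vecs.T)
        times.append(trial.frame_times.copy())
    return ProjectionSeries(modes=tuple(modes), times=times, values=values)


@dataclass
class FreeEnergyLandscape:
    """Gridded probability density over the first two mode displacements."""

    s1: np.ndarray  # (n1,) grid centers, A
    s2: np.ndarray  # (n2,)
    density: np.ndarray  # (n1, n2)
    bandwidth: str
    degenerate: bool = False

    def neg_log(self, floor: float = 1e-300) -> np.ndarray:
        return -np.log(np.maximum(self.density, floor))

    def integral(self) -> float:
        ds1 = self.s1[1] - self.s1[0] if self.s1.size > 1 else 1.0
        ds2 = self.s2[1] - self.s2[0] if self.s2.size > 1 else 1.0
        return float(self.density.sum() * ds1 * ds2)

    def density_at(self, s1: float, s2: float) -> float:
        i = int(np.clip(np.searchsorted(self.s1, s1), 0, self.s1.size - 1))
        j = int(np.clip(np.searchsorted(self.s2, s2), 0, self.s2.size - 1))
        return float(self.density[i, j])

    def to_dataframe(self):
        import pandas as pd

        g1, g2 = np.meshgrid(self.s1, self.s2, indexing="ij")
        return pd.DataFrame(
            {"s1": g1.ravel(), "s2": g2.ravel(), "density": self.density.ravel()}
        )


def estimate_landscape(
    samples: np.ndarray,
    bandwidth_rule: str = "scott",
    grid_size: tuple[int, int] = (128, 128),
    margin_bandwidths: float = 3.0,
) -> FreeEnergyLandscape:
    """2-D Gaussian KDE over (S1, S2) samples pooled across trials.

    The grid covers the samples with a margin of ``margin_bandwidths`` kernel
    widths so the density integrates to ~1 on the grid.  If all samples
    coincide (zero spread) a delta-like peak at that point is returned with a
    warning rather than an error.
    """
    from scipy.stats import gaussian_kde

    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2:
        raise InputError("samples must have shape (n, 2)")
    if samples.shape[0] < 2:
        raise InputError("need at least 2 sample points")
    spread = samples.std(axis=0)
    if np.all(spread == 0):
        warnings.warn("all projection samples identical; returning a delta-like peak")
        c = samples[0]
        eps = 1e-3
        s1 = np.linspace(c[0] - eps, c[0] + eps, grid_size[0])
        s2 = np.linspace(c[1] - eps, c[1] + eps, grid_size[1])
        density = np.zeros(grid_size)
        density[grid_size[0] // 2, grid_size[1] // 2] = 1.0
        ds = (s1[1] - s1[0]) * (s2[1] - s2[0])
        return FreeEnergyLandscape(s1, s2, density / ds, bandwidth_rule, degenerate=True)

    if bandwidth_rule not in ("scott", "silverman"):
        raise InputError(f"unknown bandwidth rule {bandwidth_rule!r}")
    kde = gaussian_kde(samples.T, bw_method=bandwidth_rule)
    bw = np.sqrt(np.diag(kde.covariance))
    lo = samples.min(axis=0) - margin_bandwidths * bw
    hi = samples.max(axis=0) + margin_bandwidths * bw
    s1 = np.linspace(lo[0], hi[0], grid_size[0])
    s2 = np.linspace(lo[1], hi[1], grid_size[1])
    g1, g2 = np.meshgrid(s1, s2, indexing="ij")
    density = kde(np.vstack([g1.ravel(), g2.ravel()])).reshape(grid_size)
    return FreeEnergyLandscape(s1, s2, density, bandwidth_rule)


def export_mode_arrows(
    result: EssentialDynamicsResult, modes: tuple[int, ...] = (1, 2), scale: float = 1.0
) -> dict[int, np.ndarray]:
    """Per-atom displacement 3-vectors of each mode (v_j reshaped N x 3, scaled)."""
    out: dict[int, np.ndarray] = {}
    for m in modes:
        if not 1 <= m <= result.eigenvectors.shape[0]:
            raise InputError(f"mode {m} out of range")
        out[m] = scale * result.eigenvectors[m - 1].reshape(result.n_atoms, 3)
    return out


def arrow_norms(arrows: np.ndarray) -> np.ndarray:
    return np.linalg.norm(arrows, axis=1)
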