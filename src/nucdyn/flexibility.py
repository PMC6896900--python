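"""RMSD time series and per-nucleotide RMSF from an aligned ensemble.

RMSD here is measured against the initial frame after alignment:
rmsd(t) = sqrt(mean_atoms |x(t) - x(0)|^2).  RMSF is the root-mean-square
fluctuation of each DNA C1' atom about its time-averaged position,
rmsf_i = sqrt(<|x_i - <x_i>|^2>), pooled over the analysis window of all
trials by default (per-trial profiles behind a flag, as per-trajectory
curves are also commonly plotted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nucdyn.errors import InputError
from nucdyn.structure_io import AnalysisWindow, TrajectoryEnsemble, resolve_window
from nucdyn.superposition import AlignedEnsemble
from nucdyn.topology import SelectionMask, mask_labels_for_atoms


def _trials_of(ensemble):
    if isinstance(ensemble, AlignedEnsemble):
        return ensemble.ensemble
    if isinstance(ensemble, TrajectoryEnsemble):
        return ensemble
    raise InputError("expected an AlignedEnsemble or TrajectoryEnsemble")


@dataclass
class RMSDSeries:
    """Per-trial (time, rmsd) series for one atom group."""

    group: str
    times: list[np.ndarray]  # per trial, ps
    values: list[np.ndarray]  # per trial, A

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for k, (t, v) in enumerate(zip(self.times, self.values)):
            rows.append(
                pd.DataFrame(
                    {"trial": k, "time_ps": t, "group": self.group, "rmsd_A": v}
                )
            )
        return pd.concat(rows, ignore_index=True)


def rmsd_series(
    aligned: AlignedEnsemble | TrajectoryEnsemble,
    measure_mask: SelectionMask | np.ndarray,
    group: str = "all",
    reference: np.ndarray | None = None,
) -> RMSDSeries:
    """RMSD of each frame against the reference (default: the trial's first frame).

    No further fitting happens here: the ensemble is expected to be aligned
    already (or alignment deliberately disabled for raw-displacement checks).
    """
    ens = _trials_of(aligned)
    idx = (
        measure_mask.indices
        if isinstance(measure_mask, SelectionMask)
        else np.asarray(measure_mask, dtype=np.intp)
    )
    if idx.size == 0:
        raise InputError("measure mask is empty")
    times, values = [], []
    for trial in ens.trials:
        ref = trial.coordinates[0] if reference is None else np.asarray(reference)
        diff = trial.coordinates[:, idx, :] - ref[idx]
        rmsd = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
        times.append(trial.frame_times.copy())
        values.append(rmsd)
    return RMSDSeries(group=group, times=times, values=values)


@dataclass
class RMSFProfile:
    """Per-atom RMSF (A) keyed by (chain_id, residue_index).

    ``values`` has shape (n_atoms,) when pooled over trials, else
    (n_trials, n_atoms) with one profile per trial.
    """

    labels: list[tuple[str, int]]
    values: np.ndarray
    window: str
    pooled: bool

    def to_dataframe(self):
        import pandas as pd

        chains = [c for c, _ in self.labels]
        resids = [r for _, r in self.labels]
        if self.pooled:
            return pd.DataFrame(
                {"chain": chains, "residue_index": resids, "rmsf_A": self.values}
            )
        rows = []
        for k in range(self.values.shape[0]):
            rows.append(
                pd.DataFrame(
                    {
                        "trial": k,
                        "chain": chains,
                        "residue_index": resids,
                        "rmsf_A": self.values[k],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def rmsf_profile(
    aligned: AlignedEnsemble | TrajectoryEnsemble,
    window: AnalysisWindow | None,
    dna_c1p_mask: SelectionMask,
    pooled: bool = True,
) -> RMSFProfile:
    """RMSF of each masked atom about its mean over the window.

    When ``pooled`` the mean structure and second moment are computed over the
    window frames of all trials together; otherwise each trial gets its own
    mean and profile.
    """
    ens = _trials_of(aligned)
    if len(dna_c1p_mask) == 0:
        raise InputError("mask is empty")
    frame_sets = resolve_window(ens, window)
    idx = dna_c1p_mask.indices
    labels = mask_labels_for_atoms(ens.topology, dna_c1p_mask)
    window_str = (window or AnalysisWindow.latter_half()).describe()

    if pooled:
        stacked = np.concatenate(
            [
                trial.coordinates[frames][:, idx, :]
                for trial, frames in zip(ens.trials, frame_sets)
            ],
            axis=0,
        )
        mean = stacked.mean(axis=0)
        rmsf = np.sqrt(np.mean(np.sum((stacked - mean) ** 2, axis=2), axis=0))
        return RMSFProfile(labels=labels, values=rmsf, window=window_str, pooled=True)

    profiles = []
    for trial, frames in zip(ens.trials, frame_sets):
        sub = trial.coordinates[frames][:, idx, :]
        mean = sub.mean(axis=0)
        profiles.append(np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0)))
    return RMSFProfile(
        labels=labels, values=np.stack(profiles), window=window_str, pooled=False
    )
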