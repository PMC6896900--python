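"""Least-squares rigid-body superposition and ensemble alignment.

Two alignment conventions are supported, matching how nucleosome trajectories
are analysed: (i) fit on all heavy atoms except the histone tails
(``whole_complex``) to remove global translation/rotation of the complex, and
(ii) fit on histone-core heavy atoms only (``histone_core_only``) so that DNA
deformation relative to the histone core is retained.  Fits are unweighted
and solve the orthogonal Procrustes problem by SVD with the proper-rotation
(det = +1) correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from nucdyn.errors import DegenerateGeometryError, InputError
from nucdyn.structure_io import TrajectoryEnsemble, Trial
from nucdyn.topology import RegionTable, SelectionMask, make_selection

Convention = Literal["whole_complex", "histone_core_only"]

_CONVENTION_MASK_LABEL = {
    "whole_complex": "align_all_no_tails",
    "histone_core_only": "align_histone_core_only",
}


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform ``x -> x @ rotation.T + translation`` and its RMSD (A)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _check_nondegenerate(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateGeometryError(
            f"superposition needs >= 3 atoms, got {coords.shape[0]}"
        )
    centered = coords - coords.mean(axis=0)
    # collinear point sets leave the rotation about the line undetermined
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise DegenerateGeometryError("masked atoms are collinear")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    mask: SelectionMask | np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    The returned transform is the global optimum of the unweighted orthogonal
    Procrustes problem over the masked atoms; a reflection solution
    (det = -1) is corrected by flipping the smallest singular direction.
    RMSD is evaluated over the masked atoms after the transform.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mask is None:
        idx = np.arange(mobile.shape[0])
    elif isinstance(mask, SelectionMask):
        idx = mask.indices
    else:
        idx = np.asarray(mask, dtype=np.intp)
    if mobile.shape != reference.shape:
        raise InputError(
            f"coordinate sets differ in shape: {mobile.shape} vs {reference.shape}"
        )
    a = mobile[idx]
    b = reference[idx]
    if a.shape != b.shape:
        raise InputError("mask selects different atom counts in the two sets")
    _check_nondegenerate(a)
    _check_nondegenerate(b)

    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    a0 = a - ca
    b0 = b - cb
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, d])
    rot = vt.T @ np.diag(diag) @ u.T
    translation = cb - rot @ ca
    moved = a @ rot.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=translation, rmsd=rmsd)


@dataclass
class AlignedEnsemble:
    """An ensemble after per-frame superposition under one convention.

    ``rotations``/``translations`` store the per-frame transforms, per trial,
    so raw frames can be re-transformed and the alignment audited.
    """

    ensemble: TrajectoryEnsemble
    convention: str
    references: list[np.ndarray]
    fit_mask: SelectionMask
    rotations: list[np.ndarray]
    translations: list[np.ndarray]

    @property
    def topology(self):
        return self.ensemble.topology

    @property
    def trials(self) -> list[Trial]:
        return self.ensemble.trials


def align_ensemble(
    ensemble: TrajectoryEnsemble,
    convention: Convention = "whole_complex",
    reference: np.ndarray | None = None,
    region_table: RegionTable | None = None,
    fit_mask: SelectionMask | None = None,
) -> AlignedEnsemble:
    """Superpose every frame of every trial onto a reference.

    The convention selects the fit mask (whole complex minus tails, or histone
    core only); the resulting transform is applied to *all* atoms of the
    frame.  When ``reference`` is None each trial is aligned onto its own
    initial frame, the natural reference for RMSD-against-start analyses.
    """
    if fit_mask is None:
        if region_table is None:
            region_table = RegionTable()
        label = _CONVENTION_MASK_LABEL.get(convention)
        if label is None:
            raise InputError(f"unknown alignment convention {convention!r}")
        fit_mask = make_selection(ensemble.topology, region_table, label)
    fit_mask.validate(ensemble.topology.n_atoms)

    aligned_trials: list[Trial] = []
    references: list[np.ndarray] = []
    all_rots: list[np.ndarray] = []
    all_trans: list[np.ndarray] = []
    for k, trial in enumerate(ensemble.trials):
        ref = trial.coordinates[0] if reference is None else np.asarray(reference)
        references.append(ref)
        out = np.empty_like(trial.coordinates)
        rots = np.empty((trial.n_frames, 3, 3))
        trans = np.empty((trial.n_frames, 3))
        for f in range(trial.n_frames):
            try:
                res = kabsch_superpose(trial.coordinates[f], ref, fit_mask)
            except DegenerateGeometryError as exc:
                raise DegenerateGeometryError(
                    f"trial {k}, frame {f}: {exc}"
                ) from exc
            out[f] = res.apply(trial.coordinates[f])
            rots[f] = res.rotation
            trans[f] = res.translation
        aligned_trials.append(Trial(trial.frame_times.copy(), out))
        all_rots.append(rots)
        all_trans.append(trans)
    new_ensemble = TrajectoryEnsemble(
        ensemble.topology, aligned_trials, ensemble.sampling_interval
    )
    return AlignedEnsemble(
        ensemble=new_ensemble,
        convention=convention,
        references=references,
        fit_mask=fit_mask,
        rotations=all_rots,
        translations=all_trans,
    )


def structure_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    fit_mask: SelectionMask | np.ndarray | None = None,
    measure_mask: SelectionMask | np.ndarray | None = None,
) -> float:
    """RMSD (A) between two structures: superpose on ``fit_mask``, measure on
    ``measure_mask`` (defaults to the fit mask)."""
    res = kabsch_superpose(coords_a, coords_b, fit_mask)
    if measure_mask is None:
        return res.rmsd
    idx = (
        measure_mask.indices
        if isinstance(measure_mask, SelectionMask)
        else np.asarray(measure_mask, dtype=np.intp)
    )
    moved = res.apply(np.asarray(coords_a, dtype=float))
    diff = moved[idx] - np.asarray(coords_b, dtype=float)[idx]
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def export_transforms_tsv(path, aligned: AlignedEnsemble) -> None:
    """Per-frame transforms as TSV: trial, frame, 9 rotation entries, 3 translation."""
    import pandas as pd

    rows = []
    for k, (rots, trans) in enumerate(zip(aligned.rotations, aligned.translations)):
        for f in range(rots.shape[0]):
            rows.append([k, f, *rots[f].ravel(), *trans[f]])
    cols = (
        ["trial", "frame"]
        + [f"r{i}{j}" for i in range(3) for j in range(3)]
        + ["tx", "ty", "tz"]
    )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
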