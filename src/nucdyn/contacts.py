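"""Nucleotide x amino-acid contact-frequency matrices.

A nucleotide (C1') and an amino acid (CA) are in contact in a frame when
their Euclidean distance is strictly less than the cutoff (default 10 A;
a pair at exactly the cutoff is a non-contact).  Frequency is the fraction
of pooled window frames in contact.  Distances are rigid-invariant, so raw
(unaligned) coordinates are used.  A KD-tree engine prunes the pair search
but is bit-equivalent to the all-pairs loop: candidate pairs are re-tested
with the same strict comparison on the same floating-point distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from nucdyn.errors import InputError, WindowError
from nucdyn.structure_io import AnalysisWindow, TrajectoryEnsemble, resolve_window
from nucdyn.topology import (
    RegionTable,
    SelectionMask,
    mask_labels_for_atoms,
)


@dataclass
class ContactFrequencyMatrix:
    """Contact frequencies in [0,1]: rows nucleotides, columns amino acids."""

    row_labels: list[tuple[str, int]]  # (chain_id, residue_index) of nucleotides
    col_labels: list[tuple[str, int]]  # of amino acids
    values: np.ndarray  # (n_rows, n_cols)
    cutoff: float
    window: str
    trials_pooled: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise InputError("matrix shape disagrees with label counts")

    def to_dataframe(self, long: bool = True):
        import pandas as pd

        if long:
            rows = []
            for i, (nc, nr) in enumerate(self.row_labels):
                for j, (ac, ar) in enumerate(self.col_labels):
                    rows.append((nc, nr, ac, ar, self.values[i, j]))
            return pd.DataFrame(
                rows, columns=["nuc_chain", "nuc_res", "aa_chain", "aa_res", "frequency"]
            )
        index = pd.MultiIndex.from_tuples(self.row_labels, names=["nuc_chain", "nuc_res"])
        cols = pd.MultiIndex.from_tuples(self.col_labels, names=["aa_chain", "aa_res"])
        return pd.DataFrame(self.values, index=index, columns=cols)


def _frame_contacts(
    nuc: np.ndarray, aa: np.ndarray, cutoff: float, engine: str
) -> np.ndarray:
    """Boolean (n_nuc, n_aa) contact matrix for one frame."""
    if engine == "brute":
        diff = nuc[:, None, :] - aa[None, :, :]
        dist = np.sqrt(np.sum(diff * diff, axis=2))
        return dist < cutoff
    if engine == "kdtree":
        from scipy.spatial import cKDTree

        out = np.zeros((nuc.shape[0], aa.shape[0]), dtype=bool)
        tree = cKDTree(aa)
        # query slightly beyond the cutoff, then apply the same strict test
        # on the same arithmetic as the brute path to stay bit-equivalent
        lists = tree.query_ball_point(nuc, r=cutoff * (1 + 1e-9))
        for i, cand in enumerate(lists):
            if not cand:
                continue
            cand = np.asarray(cand, dtype=np.intp)
            diff = nuc[i][None, :] - aa[cand]
            dist = np.sqrt(np.sum(diff * diff, axis=1))
            out[i, cand[dist < cutoff]] = True
        return out
    raise InputError(f"unknown contact engine {engine!r}")


def contact_frequency(
    ensemble: TrajectoryEnsemble,
    dna_c1p_mask: SelectionMask,
    ca_mask: SelectionMask,
    cutoff: float = 10.0,
    window: AnalysisWindow | None = None,
    engine: Literal["kdtree", "brute"] = "kdtree",
) -> ContactFrequencyMatrix:
    """Pooled contact frequency over the window frames of all trials."""
    if len(dna_c1p_mask) == 0 or len(ca_mask) == 0:
        raise InputError("contact masks must be non-empty")
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    frame_sets = resolve_window(ensemble, window)
    total = sum(len(f) for f in frame_sets)
    if total == 0:
        raise WindowError("window selects no frames")
    counts = np.zeros((len(dna_c1p_mask), len(ca_mask)), dtype=np.int64)
    ni, ai = dna_c1p_mask.indices, ca_mask.indices
    for trial, frames in zip(ensemble.trials, frame_sets):
        for f in frames:
            counts += _frame_contacts(
                trial.coordinates[f, ni, :], trial.coordinates[f, ai, :], cutoff, engine
            )
    freq = counts / float(total)
    return ContactFrequencyMatrix(
        row_labels=mask_labels_for_atoms(ensemble.topology, dna_c1p_mask),
        col_labels=mask_labels_for_atoms(ensemble.topology, ca_mask),
        values=freq,
        cutoff=cutoff,
        window=(window or AnalysisWindow.latter_half()).describe(),
    )


TailKind = Literal["N", "C", "all"]


def tail_ranges_for(
    region_table: RegionTable, role: str, kind: TailKind = "all"
) -> tuple[tuple[int, int], ...]:
    """Resolve a histone tail selection to residue ranges.

    ``"N"`` is the first (N-terminal) tail range, ``"C"`` the last (the H2A
    C-terminal tail), ``"all"`` every tail range of the role.
    """
    ranges = region_table.tail_ranges(role)
    if not ranges:
        raise InputError(f"role {role!r} has no tail ranges")
    if kind == "N":
        return (ranges[0],)
    if kind == "C":
        if len(ranges) < 2:
            raise InputError(f"role {role!r} has no C-terminal tail range")
        return (ranges[-1],)
    return ranges


def tail_contact_submatrix(
    matrix: ContactFrequencyMatrix,
    region_table: RegionTable,
    tails: Sequence[tuple[str, str, TailKind]],
    row_ranges: Sequence[tuple[str, int, int]] | None = None,
) -> ContactFrequencyMatrix:
    """Restrict columns to histone-tail residues (and rows, optionally).

    ``tails`` lists (chain_id, role, tail_kind) triples, e.g.
    ``("C", "H2A", "C")`` for the H2A C-terminal tail on chain C.
    ``row_ranges`` optionally restricts nucleotides to (chain_id, lo, hi).
    """
    col_keep: list[int] = []
    for j, (chain, res) in enumerate(matrix.col_labels):
        for tchain, role, kind in tails:
            if chain != tchain:
                continue
            if any(lo <= res <= hi for lo, hi in tail_ranges_for(region_table, role, kind)):
                col_keep.append(j)
                break
    if row_ranges is None:
        row_keep = list(range(len(matrix.row_labels)))
    else:
        row_keep = [
            i
            for i, (chain, res) in enumerate(matrix.row_labels)
            if any(chain == rc and lo <= res <= hi for rc, lo, hi in row_ranges)
        ]
    if not col_keep or not row_keep:
        raise InputError("tail restriction selects an empty submatrix")
    return ContactFrequencyMatrix(
        row_labels=[matrix.row_labels[i] for i in row_keep],
        col_labels=[matrix.col_labels[j] for j in col_keep],
        values=matrix.values[np.ix_(row_keep, col_keep)],
        cutoff=matrix.cutoff,
        window=matrix.window,
        trials_pooled=matrix.trials_pooled,
    )


def matrix_difference(
    a: ContactFrequencyMatrix, b: ContactFrequencyMatrix
) -> ContactFrequencyMatrix:
    """Elementwise a - b over the shared row/column labels (order of ``a``)."""
    brow = {lab: i for i, lab in enumerate(b.row_labels)}
    bcol = {lab: j for j, lab in enumerate(b.col_labels)}
    rows = [(i, brow[lab]) for i, lab in enumerate(a.row_labels) if lab in brow]
    cols = [(j, bcol[lab]) for j, lab in enumerate(a.col_labels) if lab in bcol]
    if not rows or not cols:
        raise InputError("contact matrices share no row/column labels")
    ai = np.array([i for i, _ in rows])
    bi = np.array([i for _, i in rows])
    aj = np.array([j for j, _ in cols])
    bj = np.array([j for _, j in cols])
    diff = a.values[np.ix_(ai, aj)] - b.values[np.ix_(bi, bj)]
    return ContactFrequencyMatrix(
        row_labels=[a.row_labels[i] for i in ai],
        col_labels=[a.col_labels[j] for j in aj],
        values=diff,
        cutoff=a.cutoff,
        window=f"diff({a.window},{b.window})",
        trials_pooled=a.trials_pooled and b.trials_pooled,
    )
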