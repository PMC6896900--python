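"""Alpha-helix assignment from backbone hydrogen bonds and occupancy profiles.

Hydrogen bonds are scored with the classic electrostatic dipole-dipole model
of backbone N-H...O=C interactions:

    E = q1 * q2 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * f
      = 0.084 * 332 * (...)   kcal/mol

with a bond declared when E < -0.5 kcal/mol.  Amide hydrogens are always
reconstructed from backbone geometry (N-H of length 1.0 A along the bisector
opposite the C(i-1)-N-CA angle), ignoring any explicit hydrogens, so the
assignment is deterministic across force fields.  A minimal alpha-helix
spans residues i..i+3 when consecutive turns exist, i.e. hydrogen bonds
CO(i-1)->NH(i+3+... ) -- concretely turn(k) := bond from CO of residue k to
NH of residue k+4, and residues i..i+3 are helical when turn(i-1) and
turn(i) both hold.  Only the alpha class is assigned; 3-10/pi helices and
strands are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from nucdyn.errors import InputError
from nucdyn.structure_io import AnalysisWindow, TrajectoryEnsemble, resolve_window
from nucdyn.topology import ComplexTopology

logger = logging.getLogger(__name__)

#: coupling constant of the hydrogen-bond energy model, kcal*A/mol
HBOND_COUPLING = 0.084 * 332.0
#: energy threshold below which an N-H...O=C pair counts as bonded, kcal/mol
HBOND_ENERGY_CUTOFF = -0.5
#: reconstructed amide N-H bond length, A
NH_BOND_LENGTH = 1.0
#: minimal sequence separation between donor and acceptor residues
MIN_SEQ_SEPARATION = 2


@dataclass(frozen=True)
class HBond:
    """A backbone hydrogen bond: CO of ``acceptor`` to N-H of ``donor``."""

    donor: tuple[str, int]  # (chain_id, residue_index) providing N-H
    acceptor: tuple[str, int]  # providing C=O
    energy: float  # kcal/mol


def reconstruct_amide_hydrogen(
    n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray
) -> np.ndarray:
    """Place the amide H on the bisector opposite the C(i-1)-N-CA angle, 1.0 A."""
    u = n - c_prev
    v = n - ca
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    h_dir = u + v
    norm = np.linalg.norm(h_dir)
    if norm < 1e-8:
        raise InputError("degenerate backbone geometry at amide hydrogen")
    return n + NH_BOND_LENGTH * h_dir / norm


def backbone_hbond_energy(
    n: np.ndarray, h: np.ndarray, c: np.ndarray, o: np.ndarray
) -> float:
    """Electrostatic N-H...O=C energy in kcal/mol (negative = attractive)."""
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 1e-6:
        raise InputError("coincident atoms in hydrogen-bond geometry")
    return float(HBOND_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


def _chain_backbone(
    topology: ComplexTopology, coords: np.ndarray, chain_id: str
) -> tuple[list[int], dict[int, dict[str, np.ndarray]]]:
    """Ordered residue list and backbone coordinates of one protein chain.

    Residues missing any of N/CA/C/O are skipped with a log entry.
    """
    on_chain = topology.chain_id == chain_id
    residues = sorted(int(r) for r in np.unique(topology.residue_index[on_chain]))
    backbone: dict[int, dict[str, np.ndarray]] = {}
    kept: list[int] = []
    for res in residues:
        sel = on_chain & (topology.residue_index == res)
        entry: dict[str, np.ndarray] = {}
        for name in ("N", "CA", "C", "O"):
            hits = np.flatnonzero(sel & (topology.atom_name == name))
            if hits.size:
                entry[name] = coords[hits[0]]
        if len(entry) == 4:
            backbone[res] = entry
            kept.append(res)
        else:
            logger.debug("chain %s residue %s lacks full backbone; skipped", chain_id, res)
    return kept, backbone


def chain_hbonds(
    topology: ComplexTopology, coords: np.ndarray, chain_id: str
) -> list[HBond]:
    """All intra-chain backbone hydrogen bonds (energy < threshold)."""
    residues, backbone = _chain_backbone(topology, coords, chain_id)
    bonds: list[HBond] = []
    for pos_d, res_d in enumerate(residues):
        if pos_d == 0:
            continue  # first residue has no reconstructable amide H
        res_prev = residues[pos_d - 1]
        if res_prev != res_d - 1:
            continue  # chain break
        don = backbone[res_d]
        h = reconstruct_amide_hydrogen(don["N"], don["CA"], backbone[res_prev]["C"])
        for res_a in residues:
            if abs(res_a - res_d) < MIN_SEQ_SEPARATION:
                continue
            acc = backbone[res_a]
            e = backbone_hbond_energy(don["N"], h, acc["C"], acc["O"])
            if e < HBOND_ENERGY_CUTOFF:
                bonds.append(
                    HBond(donor=(chain_id, res_d), acceptor=(chain_id, res_a), energy=e)
                )
    return bonds


def assign_helix(
    coords: np.ndarray, topology: ComplexTopology, chain_ids: list[str] | None = None
) -> dict[tuple[str, int], bool]:
    """Per-residue alpha-helix booleans for one frame.

    A residue is helical iff it lies in a minimal helix i..i+3 supported by
    two consecutive turns: turn(k) = H-bond from CO of residue k to N-H of
    residue k+4, helix at i..i+3 when turn(i-1) and turn(i).  Chains shorter
    than five residues are all false.
    """
    if chain_ids is None:
        chain_ids = topology.histone_chain_ids or [
            cid for cid, role in topology.chains if role not in ("DNA-I", "DNA-J")
        ]
    out: dict[tuple[str, int], bool] = {}
    for cid in chain_ids:
        residues, backbone = _chain_backbone(topology, coords, cid)
        for res in residues:
            out[(cid, res)] = False
        if len(residues) < 5:
            continue
        bonds = chain_hbonds(topology, coords, cid)
        turn = {
            acc_res
            for (_, don_res), (_, acc_res) in (
                (b.donor, b.acceptor) for b in bonds
            )
            if don_res - acc_res == 4
        }
        resset = set(residues)
        for i in sorted(turn):
            if (i - 1) in turn:
                for r in range(i, i + 4):
                    if r in resset:
                        out[(cid, r)] = True
    return out


@dataclass
class HelixOccupancy:
    """Fraction of window frames each residue is alpha-helical."""

    labels: list[tuple[str, int]]
    values: np.ndarray  # in [0,1]
    window: str

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chain": [c for c, _ in self.labels],
                "residue_index": [r for _, r in self.labels],
                "occupancy": self.values,
            }
        )


def helix_occupancy(
    ensemble: TrajectoryEnsemble,
    window: AnalysisWindow | None = None,
    chain_ids: list[str] | None = None,
) -> HelixOccupancy:
    """Helix occurrence ratio per residue over the pooled window of all trials.

    With equal per-trial frame counts, pooling before or after the ratio is
    identical; the pooled count/total form is used.
    """
    frame_sets = resolve_window(ensemble, window)
    total = sum(len(f) for f in frame_sets)
    counts: dict[tuple[str, int], int] = {}
    for trial, frames in zip(ensemble.trials, frame_sets):
        for f in frames:
            assignment = assign_helix(trial.coordinates[f], ensemble.topology, chain_ids)
            for key, helical in assignment.items():
                counts[key] = counts.get(key, 0) + int(helical)
    labels = sorted(counts)
    values = np.array([counts[k] / total for k in labels], dtype=float)
    return HelixOccupancy(
        labels=labels,
        values=values,
        window=(window or AnalysisWindow.latter_half()).describe(),
    )
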