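"""Synthetic nucleosome-like structures and trajectory ensembles.

This is a statistical emulator of the all-atom runs, not an MD engine: DNA is
two strands of one-bead-per-nucleotide (atom name C1') on a left-handed
superhelix, histones are eight chains of one-bead-per-residue (atom name CA)
clustered at the canonical dimer positions with disordered tails appended.
Dynamics are composed of closed-form ingredients so every downstream analysis
has an exact oracle:

* a sinusoidal "breathing" mode pushing the DNA arm adjacent to a deleted
  dimer outward (amplitude per bead, period in frames);
* for H2A/H2B-type deletions, a slow drift of the fluctuation center along
  the same mode (the cloud leaves the initial conformation);
* for H3/H4-type deletions with ``tail_invasion`` on, the adjacent H2A
  C-terminal tail relocates into the vacated patch and pins the DNA arm
  (breathing suppressed, no drift) - contacts gain, fluctuations stay flat;
* isotropic per-coordinate Gaussian noise and an optional slow rigid wobble
  of the whole complex to exercise the alignment stage.

Identical spec + seed gives bitwise-identical output (RNG seeded per
(seed, trial)).  A separate ideal-geometry peptide builder provides all-atom
backbones (N, CA, C, O) at prescribed phi/psi for secondary-structure tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from nucdyn.errors import InputError, TopologyError
from nucdyn.structure_io import (
    TrajectoryEnsemble,
    Trial,
    write_structure,
    write_text_trajectory,
)
from nucdyn.topology import (
    AtomSite,
    ComplexTopology,
    ModelVariant,
    RegionTable,
    build_variant,
)

#: DNA-bead parameter ranges (strand-I residue indices, 147 bp) each dimer contacts.
DIMER_PATCHES: dict[str, tuple[int, int]] = {
    "H3/H4": (-39, 0),
    "H2A/H2B": (40, 73),
    "H3'/H4'": (1, 39),
    "H2A'/H2B'": (-73, -40),
}


def dimer_patch_ranges(dna_bp: int) -> dict[str, tuple[int, int]]:
    """Dimer contact-patch residue ranges, scaled from the 147-bp layout."""
    half = (dna_bp - 1) // 2
    scale = half / 73.0
    return {
        dimer: (round(lo * scale), round(hi * scale))
        for dimer, (lo, hi) in DIMER_PATCHES.items()
    }

_VARIANT_PATCH = {
    ModelVariant.DEL_H3_H4: "H3/H4",
    ModelVariant.DEL_H2A_H2B: "H2A/H2B",
    ModelVariant.DEL_H3p_H4p: "H3'/H4'",
    ModelVariant.DEL_H2Ap_H2Bp: "H2A'/H2B'",
}

#: which H2A chain's C-terminal tail invades when an H3/H4 dimer is deleted
_INVADING_H2A = {
    ModelVariant.DEL_H3_H4: "G",  # H2A' is adjacent to the H3/H4 patch
    ModelVariant.DEL_H3p_H4p: "C",
}

_H2A_CHAIN_ROLE = {"C": "H2A", "G": "H2A'"}


@dataclass(frozen=True)
class SyntheticSpec:
    """Geometry and dynamics parameters of the emulator.

    Defaults emulate the study conditions: a 147-bp nucleosome on the
    canonical superhelix (radius 41.9 A, pitch 25.9 A, 1.65 turns), histone
    bead counts matching the core/tail residue table, 10 independent trials
    of 100 ns sampled every 10 ps.  ``breathing_amplitude`` is the peak
    outward displacement of each affected arm bead (A); ``noise_sigma`` is
    the per-coordinate thermal noise (A).
    """

    dna_bp: int = 147
    radius: float = 41.9
    pitch: float = 25.9
    turns: float = 1.65
    region_table: RegionTable = field(default_factory=RegionTable)
    breathing_extent_bp: int = 20
    breathing_amplitude: float = 4.0
    breathing_period_frames: int = 200
    noise_sigma: float = 0.5
    drift_amplitude: float = 60.0  # along the unit 3N mode, H2A/H2B deletions
    ramp_fraction: float = 0.1
    tail_invasion: bool = True
    wobble_deg: float = 5.0
    wobble_translation: float = 2.0
    n_trials: int = 10
    n_frames: int = 10000
    sampling_interval: float = 10.0  # ps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dna_bp < 2 or self.n_trials < 1 or self.n_frames < 1:
            raise InputError("counts must be positive")
        if self.turns <= 0:
            raise InputError("superhelix must have a positive number of turns")
        if self.breathing_amplitude < 0 or self.noise_sigma < 0:
            raise InputError("amplitude and noise must be non-negative")
        if not 0 < self.breathing_extent_bp <= self.dna_bp:
            raise InputError("breathing extent must be within the DNA length")


@dataclass
class SyntheticGroundTruth:
    """Exact oracle values for the generated dynamics."""

    mode: np.ndarray | None = None  # unit 3N vector over C1' beads (mask order)
    mode_amplitude: float = 0.0  # amplitude along the unit mode, A
    affected_labels: list[tuple[str, int]] = field(default_factory=list)
    expected_rmsf: np.ndarray | None = None  # per C1' bead, A
    c1p_labels: list[tuple[str, int]] = field(default_factory=list)
    drift: float = 0.0  # along the unit mode, A
    invading_labels: list[tuple[str, int]] = field(default_factory=list)
    patch_dna_labels: list[tuple[str, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# structure generation
# ---------------------------------------------------------------------------


def _superhelix_point(frac: float, radius: float, pitch: float, turns: float,
                      phase: float = 0.0, dz: float = 0.0) -> np.ndarray:
    """Point on a left-handed superhelix; frac in [0,1] runs along the path."""
    theta = -2.0 * math.pi * turns * (frac - 0.5) + phase
    z = pitch * turns * (frac - 0.5) + dz
    return np.array([radius * math.cos(theta), radius * math.sin(theta), z])


def _lattice_ball(n: int, spacing: float = 2.5) -> np.ndarray:
    """n points of a cubic lattice closest to the origin (compact, spacing-exact)."""
    if n == 1:
        return np.zeros((1, 3))
    m = max(1, math.ceil((n ** (1 / 3)) / 2) + 1)
    grid = np.arange(-m, m + 1)
    pts = spacing * np.array(
        [(x, y, z) for x in grid for y in grid for z in grid], dtype=float
    )
    order = np.argsort(np.einsum("ij,ij->i", pts, pts), kind="stable")
    return pts[order[:n]]


def _dna_fracs(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Residue indices and path fractions of strand I."""
    half = (spec.dna_bp - 1) // 2
    res = np.arange(spec.dna_bp) - half
    frac = (np.arange(spec.dna_bp)) / (spec.dna_bp - 1)
    return res, frac


def generate_structure(
    spec: SyntheticSpec,
) -> tuple[ComplexTopology, np.ndarray, SyntheticGroundTruth]:
    """Build the canonical bead complex and its reference coordinates.

    DNA strand I carries residues -half..half along the superhelix; strand J
    is antiparallel (its residue j sits near strand I's residue -j) with a
    small angular/axial offset.  Each histone chain gets core beads in a
    compact ball at its dimer position plus tail beads extending along the
    superhelix axis, with residue numbering following the core/tail table.
    """
    res_i, frac_i = _dna_fracs(spec)
    atoms: list[AtomSite] = []
    chains: list[tuple[str, str]] = []
    positions: list[np.ndarray] = []
    atom_id = 1

    def add_atom(name: str, element: str, cid: str, res: int, resname: str,
                 pos: np.ndarray) -> None:
        nonlocal atom_id
        atoms.append(AtomSite(atom_id, name, element, cid, int(res), resname, pos))
        positions.append(pos)
        atom_id += 1

    # histone chains A..H at the four dimer positions
    dimer_chains = {
        "H3/H4": (("A", "H3"), ("B", "H4")),
        "H2A/H2B": (("C", "H2A"), ("D", "H2B")),
        "H3'/H4'": (("E", "H3'"), ("F", "H4'")),
        "H2A'/H2B'": (("G", "H2A'"), ("H", "H2B'")),
    }
    patches = dimer_patch_ranges(spec.dna_bp)
    patch_center: dict[str, np.ndarray] = {}
    for dimer, (lo, hi) in patches.items():
        sel = (res_i >= lo) & (res_i <= hi)
        pts = np.array([
            _superhelix_point(f, spec.radius, spec.pitch, spec.turns)
            for f in frac_i[sel]
        ])
        patch_center[dimer] = pts.mean(axis=0)

    for dimer in ("H3/H4", "H2A/H2B", "H3'/H4'", "H2A'/H2B'"):
        center = patch_center[dimer].copy()
        center[:2] *= 0.6  # pull the cluster inward toward the axis
        for which, (cid, role) in enumerate(dimer_chains[dimer]):
            # offsets chosen off-lattice so the two balls cannot clash
            base = center + np.array(
                [1.25 * which, 0.0, 4.375 * (1 if which else -1)]
            )
            table = spec.region_table
            core_lo, core_hi = table.core[role.rstrip("'")]
            n_core = core_hi - core_lo + 1
            ball = _lattice_ball(n_core) + base
            bead_of: dict[int, np.ndarray] = {
                core_lo + m: ball[m] for m in range(n_core)
            }
            # disordered tails wind helically around their own cluster,
            # advancing along z away from the partner chain, so they stay
            # clear of the DNA shell and of the other clusters
            z_sign = 1.0 if which else -1.0
            wind_r, d_phi, dz = 9.5, 2.0 * math.asin(1.75 / 9.5), 1.5
            for tlo, thi in table.tail_ranges(role):
                n_tail = thi - tlo + 1
                phase0 = 0.0 if thi < core_lo else math.pi  # N vs C tail lane
                for m in range(n_tail):
                    ang = phase0 + (m + 1) * d_phi
                    bead_of[tlo + m] = base + np.array(
                        [
                            wind_r * math.cos(ang),
                            wind_r * math.sin(ang),
                            z_sign * (2.0 + dz * (m + 1)),
                        ]
                    )
            for res in sorted(bead_of):
                add_atom("CA", "C", cid, res, "ALA", bead_of[res])
            chains.append((cid, role))

    # DNA strands I and J
    for k in range(spec.dna_bp):
        pos = _superhelix_point(frac_i[k], spec.radius, spec.pitch, spec.turns)
        add_atom("C1'", "C", "I", res_i[k], "DA", pos)
    chains.append(("I", "DNA-I"))
    for k in range(spec.dna_bp):
        # strand J residue j pairs strand I residue -j
        frac = frac_i[spec.dna_bp - 1 - k]
        pos = _superhelix_point(frac, spec.radius, spec.pitch, spec.turns,
                                phase=0.25, dz=3.0)
        add_atom("C1'", "C", "J", res_i[k], "DT", pos)
    chains.append(("J", "DNA-J"))

    coords = np.array(positions)
    # reject geometrically impossible specs
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=1.0)
    if pairs:
        i, j = sorted(pairs)[0]
        raise TopologyError(
            f"{len(pairs)} bead pairs closer than 1 A (first: "
            f"{atoms[i].chain_id}/{atoms[i].residue_index} vs "
            f"{atoms[j].chain_id}/{atoms[j].residue_index}); "
            "spec geometry is impossible"
        )
    topo = ComplexTopology(chains, atoms)
    truth = SyntheticGroundTruth()
    return topo, coords, truth


# ---------------------------------------------------------------------------
# ensemble generation
# ---------------------------------------------------------------------------


def _dna_mask_order(topology: ComplexTopology) -> tuple[np.ndarray, list[tuple[str, int]]]:
    idx = np.flatnonzero(
        (topology.atom_name == "C1'")
        & np.isin(topology.chain_id, topology.dna_chain_ids)
    )
    labels = [
        (str(topology.chain_id[i]), int(topology.residue_index[i])) for i in idx
    ]
    return idx, labels


def _affected_beads(
    spec: SyntheticSpec, labels: list[tuple[str, int]], dimer: str
) -> np.ndarray:
    """Mask-order positions of the arm beads adjacent to a dimer patch.

    The ``breathing_extent_bp`` parameter positions nearest the patch center
    are taken on each strand (strand J pairs index -r).
    """
    lo, hi = dimer_patch_ranges(spec.dna_bp)[dimer]
    center = 0.5 * (lo + hi)
    half = spec.breathing_extent_bp / 2.0
    out = []
    for pos, (chain, res) in enumerate(labels):
        param = res if chain == "I" else -res
        if abs(param - center) <= half and lo <= param <= hi:
            out.append(pos)
    return np.asarray(out, dtype=np.intp)


def _radial_mode(coords_c1p: np.ndarray, affected: np.ndarray) -> np.ndarray:
    """Unit 3N vector: outward xy-radial on affected beads, zero elsewhere."""
    n = coords_c1p.shape[0]
    mode = np.zeros((n, 3))
    for i in affected:
        radial = coords_c1p[i].copy()
        radial[2] = 0.0
        norm = np.linalg.norm(radial)
        mode[i] = radial / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
    flat = mode.reshape(-1)
    total = np.linalg.norm(flat)
    if total > 0:
        flat = flat / total
    return flat


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _rotation_z(angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def generate_ensemble(
    structure: tuple[ComplexTopology, np.ndarray, SyntheticGroundTruth] | None,
    spec: SyntheticSpec,
    variant: ModelVariant = ModelVariant.CANONICAL,
) -> tuple[TrajectoryEnsemble, SyntheticGroundTruth]:
    """Generate a multi-trial ensemble for one model variant.

    Frames are ``reference + breathing + drift + invasion + wobble + noise``
    per the module docstring.  Deleting an H2A/H2B dimer turns on arm
    breathing plus center drift; deleting an H3/H4 dimer with
    ``tail_invasion`` relocates the adjacent H2A C-terminal tail into the
    vacated patch and suppresses the breathing instead (without invasion the
    arm breathes like the H2A/H2B case).  The first saved frame sits one
    sampling interval after time zero and is noise about the reference.
    """
    if structure is None:
        structure = generate_structure(spec)
    canon_topo, canon_coords, _ = structure
    var_topo, keep_idx = build_variant(canon_topo, variant)
    ref = canon_coords[keep_idx]

    c1p_idx, c1p_labels = _dna_mask_order(var_topo)
    coords_c1p = ref[c1p_idx]
    n_dna = c1p_idx.size

    truth = SyntheticGroundTruth(c1p_labels=c1p_labels)
    amplitude = 0.0
    drift = 0.0
    mode_flat = np.zeros(3 * n_dna)
    invasion_targets: dict[int, np.ndarray] = {}  # var-topology atom index -> target

    if variant is not ModelVariant.CANONICAL:
        dimer = _VARIANT_PATCH[variant]
        affected = _affected_beads(spec, c1p_labels, dimer)
        mode_flat = _radial_mode(coords_c1p, affected)
        truth.affected_labels = [c1p_labels[i] for i in affected]
        lo, hi = dimer_patch_ranges(spec.dna_bp)[dimer]
        truth.patch_dna_labels = [
            (c, r)
            for c, r in c1p_labels
            if lo <= (r if c == "I" else -r) <= hi
        ]
        is_h3h4 = variant in _INVADING_H2A
        if is_h3h4 and spec.tail_invasion:
            # invading tail pins the arm: breathing suppressed, no drift
            amplitude = 0.0
            h2a_chain = _INVADING_H2A[variant]
            role = _H2A_CHAIN_ROLE[h2a_chain]
            tlo, thi = spec.region_table.tail_ranges(role)[-1]  # C-terminal
            inv_atoms = np.flatnonzero(
                (var_topo.chain_id == h2a_chain)
                & (var_topo.residue_index >= tlo)
                & (var_topo.residue_index <= thi)
            )
            truth.invading_labels = [
                (h2a_chain, int(var_topo.residue_index[i])) for i in inv_atoms
            ]
            patch_pos = [
                i
                for i, lab in enumerate(c1p_labels)
                if lab in set(truth.patch_dna_labels)
            ]
            for m, ai in enumerate(inv_atoms):
                target_dna = coords_c1p[patch_pos[m % len(patch_pos)]].copy()
                target_dna[:2] *= 0.9  # just inside the DNA bead, well under cutoff
                invasion_targets[int(ai)] = target_dna
        else:
            amplitude = spec.breathing_amplitude
            if not is_h3h4:
                drift = spec.drift_amplitude

    n_aff = len(truth.affected_labels)
    truth.mode = mode_flat
    truth.mode_amplitude = amplitude * math.sqrt(n_aff) if n_aff else 0.0
    truth.drift = drift
    bead_mode_sq = np.sum(mode_flat.reshape(n_dna, 3) ** 2, axis=1)
    truth.expected_rmsf = np.sqrt(
        truth.mode_amplitude**2 / 2.0 * bead_mode_sq + 3.0 * spec.noise_sigma**2
    )

    mode_disp = truth.mode_amplitude * mode_flat.reshape(n_dna, 3)  # peak per bead

    n_atoms = var_topo.n_atoms
    times = spec.sampling_interval * np.arange(1, spec.n_frames + 1)
    ramp_frames = max(1, int(spec.ramp_fraction * spec.n_frames))
    trials: list[Trial] = []
    for trial_no in range(spec.n_trials):
        rng = np.random.default_rng([spec.seed, trial_no])
        frames = np.broadcast_to(ref, (spec.n_frames, n_atoms, 3)).copy()
        f = np.arange(spec.n_frames, dtype=float)
        ramp = _smoothstep(f / ramp_frames)  # first frame starts at zero
        if truth.mode_amplitude > 0:
            breath = np.sin(2.0 * math.pi * f / spec.breathing_period_frames)
            frames[:, c1p_idx, :] += breath[:, None, None] * mode_disp[None, :, :]
        if drift > 0:
            frames[:, c1p_idx, :] += (
                (drift * ramp)[:, None, None] * mode_flat.reshape(n_dna, 3)[None, :, :]
            )
        for ai, target in invasion_targets.items():
            frames[:, ai, :] = (
                ref[ai][None, :] * (1 - ramp[:, None]) + target[None, :] * ramp[:, None]
            )
        if spec.wobble_deg > 0 or spec.wobble_translation > 0:
            phase = 2.0 * math.pi * f / spec.n_frames
            for fr in range(spec.n_frames):
                rot = _rotation_z(math.radians(spec.wobble_deg) * math.sin(phase[fr]))
                shift = spec.wobble_translation * math.sin(phase[fr])
                frames[fr] = frames[fr] @ rot.T + np.array([shift, 0.0, 0.0])
        if spec.noise_sigma > 0:
            frames += rng.normal(0.0, spec.noise_sigma, size=frames.shape)
        trials.append(Trial(times.copy(), frames))
    ensemble = TrajectoryEnsemble(var_topo, trials, spec.sampling_interval)
    return ensemble, truth


# ---------------------------------------------------------------------------
# fixture bundles
# ---------------------------------------------------------------------------


def write_fixture_bundle(
    path: str | Path,
    spec: SyntheticSpec,
    variants: Sequence[ModelVariant] = (ModelVariant.CANONICAL,),
) -> dict[str, dict[str, list[str]]]:
    """Write PDB topology + plain-text trajectories + ground-truth TSV per variant.

    Returns a manifest mapping variant name to the files written; everything
    reads back into an equivalent ensemble through :mod:`nucdyn.structure_io`.
    """
    import pandas as pd

    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    structure = generate_structure(spec)
    manifest: dict[str, dict[str, list[str]]] = {}
    for variant in variants:
        name = variant.value
        ensemble, truth = generate_ensemble(structure, spec, variant)
        pdb_path = outdir / f"{name}.pdb"
        ref0 = structure[1][build_variant(structure[0], variant)[1]]
        write_structure(pdb_path, ensemble.topology, ref0)
        traj_paths = []
        for k, trial in enumerate(ensemble.trials):
            tp = outdir / f"{name}_trial{k}.traj"
            write_text_trajectory(tp, trial)
            traj_paths.append(str(tp))
        gt_path = outdir / f"{name}_groundtruth.tsv"
        pd.DataFrame(
            {
                "chain": [c for c, _ in truth.c1p_labels],
                "residue_index": [r for _, r in truth.c1p_labels],
                "expected_rmsf_A": truth.expected_rmsf,
                "mode_x": truth.mode.reshape(-1, 3)[:, 0],
                "mode_y": truth.mode.reshape(-1, 3)[:, 1],
                "mode_z": truth.mode.reshape(-1, 3)[:, 2],
            }
        ).to_csv(gt_path, sep="\t", index=False)
        manifest[name] = {
            "topology": [str(pdb_path)],
            "trajectories": traj_paths,
            "ground_truth": [str(gt_path)],
        }
    return manifest


# ---------------------------------------------------------------------------
# ideal-geometry peptides (all-atom backbone) for secondary-structure tests
# ---------------------------------------------------------------------------

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8

ALPHA_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (180.0, 180.0)


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd|=bond, angle(b,c,d), torsion(a,b,c,d)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_peptide(
    n_residues: int,
    phi: float | Sequence[float],
    psi: float | Sequence[float],
    omega: float = 180.0,
    chain_id: str = "P",
) -> tuple[ComplexTopology, np.ndarray]:
    """Poly-alanine backbone (N, CA, C, O per residue) at prescribed phi/psi.

    ``phi``/``psi`` may be scalars or per-residue sequences in degrees.
    Carbonyl O is placed anti to the next residue's N in the peptide plane.
    """
    if n_residues < 2:
        raise InputError("a peptide needs at least 2 residues")
    phis = np.full(n_residues, phi, dtype=float) if np.isscalar(phi) else np.asarray(phi, dtype=float)
    psis = np.full(n_residues, psi, dtype=float) if np.isscalar(psi) else np.asarray(psi, dtype=float)
    if phis.shape != (n_residues,) or psis.shape != (n_residues,):
        raise InputError("phi/psi length must match residue count")

    n_pos = [np.array([0.0, 0.0, 0.0])]
    ca_pos = [np.array([_BOND_N_CA, 0.0, 0.0])]
    c0 = ca_pos[0] + _BOND_CA_C * np.array(
        [math.cos(math.pi - math.radians(_ANGLE_N_CA_C)),
         math.sin(math.pi - math.radians(_ANGLE_N_CA_C)), 0.0]
    )
    c_pos = [c0]
    for i in range(1, n_residues):
        n_i = _place_atom(n_pos[i - 1], ca_pos[i - 1], c_pos[i - 1],
                          _BOND_C_N, _ANGLE_CA_C_N, psis[i - 1])
        ca_i = _place_atom(ca_pos[i - 1], c_pos[i - 1], n_i,
                           _BOND_N_CA, _ANGLE_C_N_CA, omega)
        c_i = _place_atom(c_pos[i - 1], n_i, ca_i,
                          _BOND_CA_C, _ANGLE_N_CA_C, phis[i])
        n_pos.append(n_i)
        ca_pos.append(ca_i)
        c_pos.append(c_i)
    o_pos = []
    for i in range(n_residues):
        if i < n_residues - 1:
            # O anti to the next N across the C: torsion(N_i, CA_i, C_i, O) = psi_i + 180
            tor = psis[i] + 180.0
        else:
            tor = psis[i] + 180.0
        o_pos.append(
            _place_atom(n_pos[i], ca_pos[i], c_pos[i], _BOND_C_O, _ANGLE_CA_C_O, tor)
        )

    atoms: list[AtomSite] = []
    coords: list[np.ndarray] = []
    aid = 1
    for i in range(n_residues):
        for name, el, pos in (
            ("N", "N", n_pos[i]),
            ("CA", "C", ca_pos[i]),
            ("C", "C", c_pos[i]),
            ("O", "O", o_pos[i]),
        ):
            atoms.append(AtomSite(aid, name, el, chain_id, i + 1, "ALA", pos))
            coords.append(pos)
            aid += 1
    topo = ComplexTopology([(chain_id, "other")], atoms)
    return topo, np.array(coords)


def generate_peptide_ensemble(
    n_residues: int,
    helix_schedule: Sequence[bool],
    sampling_interval: float = 10.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[TrajectoryEnsemble, np.ndarray]:
    """Peptide trajectory whose frames are ideal helix or extended geometry.

    ``helix_schedule[f]`` selects the conformation of frame f; returns the
    ensemble and the schedule as a boolean array (the exact helix-state
    timeline oracle).
    """
    schedule = np.asarray(helix_schedule, dtype=bool)
    topo, helix_coords = build_peptide(n_residues, *ALPHA_PHI_PSI)
    _, ext_coords = build_peptide(n_residues, *EXTENDED_PHI_PSI)
    frames = np.where(schedule[:, None, None], helix_coords[None], ext_coords[None])
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        frames = frames + rng.normal(0.0, noise_sigma, size=frames.shape)
    times = sampling_interval * np.arange(1, schedule.size + 1)
    trial = Trial(times, frames)
    return TrajectoryEnsemble(topo, [trial], sampling_interval), schedule


def scaled_spec(spec: SyntheticSpec, **overrides) -> SyntheticSpec:
    """Convenience: a copy of a spec with fields overridden (for small test runs)."""
    return replace(spec, **overrides)
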