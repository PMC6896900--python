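"""Structure and trajectory readers/writers.

Structures are read from PDB (altloc resolved to highest occupancy).
Trajectories come either as binary DCD (the fixed-header single-precision
format written by common MD engines; coordinates are stored in Angstrom) or
as a documented plain-text frame format::

    <n_atoms> <time_ps>
    x y z        (one line per atom)
    ...repeated per frame

Multiple trajectory files form a :class:`TrajectoryEnsemble` of independent
trials sharing one topology.  No periodic-boundary unwrapping is performed;
the complex is assumed whole in every frame (imaging is a pre-processing
step for engine-specific tooling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from nucdyn.errors import FormatError, InputError, TopologyMismatchError, WindowError
from nucdyn.topology import DEFAULT_CHAIN_MAP, AtomSite, ComplexTopology

logger = logging.getLogger(__name__)

_TIME_TOL = 1e-6  # ps; tolerance on uniform frame spacing


@dataclass
class Trial:
    """One simulation run: frame times (ps) and coordinates (frames, atoms, 3) A."""

    frame_times: np.ndarray
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise InputError("trial coordinates must have shape (frames, atoms, 3)")
        if self.frame_times.shape != (self.coordinates.shape[0],):
            raise InputError("frame_times length must equal the frame count")
        if self.n_frames < 1:
            raise InputError("a trial needs at least one frame")
        if self.n_frames > 1:
            dt = np.diff(self.frame_times)
            if np.any(dt <= 0):
                raise InputError("frame times must be strictly increasing")
            if np.ptp(dt) > _TIME_TOL:
                raise InputError("frame times must be uniformly spaced")

    @property
    def n_frames(self) -> int:
        return int(self.coordinates.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coordinates.shape[1])


@dataclass
class TrajectoryEnsemble:
    """Multi-trial per-frame coordinates at a fixed sampling interval."""

    topology: ComplexTopology
    trials: list[Trial]
    sampling_interval: float  # ps

    def __post_init__(self) -> None:
        if not self.trials:
            raise InputError("at least one trial is required")
        for k, trial in enumerate(self.trials):
            if trial.n_atoms != self.topology.n_atoms:
                raise TopologyMismatchError(
                    f"trial {k} has {trial.n_atoms} atoms; topology has "
                    f"{self.topology.n_atoms}"
                )

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class AnalysisWindow:
    """A time window over each trial.

    With ``start_fraction`` f, frames with time strictly greater than
    f x (last frame time) are kept; the default f = 0.5 keeps the latter half
    of a run whose first saved frame sits one sampling interval after zero.
    An explicit ``time_range`` (t0, t1) keeps frames with t0 <= t <= t1.
    With neither set, every frame is kept.
    """

    start_fraction: float | None = 0.5
    time_range: tuple[float, float] | None = None

    @classmethod
    def latter_half(cls) -> "AnalysisWindow":
        return cls(start_fraction=0.5)

    @classmethod
    def full(cls) -> "AnalysisWindow":
        return cls(start_fraction=None)

    def describe(self) -> str:
        if self.time_range is not None:
            return f"time_range={self.time_range[0]}-{self.time_range[1]}ps"
        if self.start_fraction is not None:
            return f"start_fraction={self.start_fraction}"
        return "full"


def resolve_window(
    ensemble: TrajectoryEnsemble, window: AnalysisWindow | None = None
) -> list[np.ndarray]:
    """Frame-index arrays, one per trial, selected by the window."""
    if window is None:
        window = AnalysisWindow.latter_half()
    out: list[np.ndarray] = []
    for k, trial in enumerate(ensemble.trials):
        t = trial.frame_times
        if window.time_range is not None:
            t0, t1 = window.time_range
            idx = np.flatnonzero((t >= t0 - _TIME_TOL) & (t <= t1 + _TIME_TOL))
        elif window.start_fraction is not None:
            cut = window.start_fraction * t[-1]
            idx = np.flatnonzero(t > cut + _TIME_TOL)
        else:
            idx = np.arange(trial.n_frames)
        if idx.size == 0:
            raise WindowError(
                f"window {window.describe()} selects no frames of trial {k}"
            )
        out.append(idx)
    return out


# ---------------------------------------------------------------------------
# structure reading / writing (PDB)
# ---------------------------------------------------------------------------


def read_structure(
    path: str | Path, chain_map: Mapping[str, str] | None = None
) -> tuple[ComplexTopology, np.ndarray]:
    """Read a PDB file into a topology plus its reference-frame coordinates.

    Atom order follows the file.  Alternate locations are resolved to the
    highest occupancy (ties broken by the file's own ordering, which is
    alphabetical in deposited entries).  Chains absent from ``chain_map``
    are kept with role ``"other"`` (solvent, ions) and are excluded from
    analysis masks downstream.
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    if chain_map is None:
        chain_map = DEFAULT_CHAIN_MAP
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        arr = pdb_file.get_structure(
            model=1, altloc="occupancy", extra_fields=["atom_id"]
        )
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise FormatError(f"no atoms found in {path}")

    seen: set[tuple[str, int, str, str]] = set()
    chain_order: list[str] = []
    atoms: list[AtomSite] = []
    for i in range(arr.array_length()):
        cid = str(arr.chain_id[i])
        key = (cid, int(arr.res_id[i]), str(arr.ins_code[i]), str(arr.atom_name[i]))
        if key in seen:
            raise FormatError(
                f"duplicate atom {key[3]!r} in residue {key[1]} of chain {cid} "
                f"in {path}"
            )
        seen.add(key)
        if cid not in chain_order:
            chain_order.append(cid)
        atoms.append(
            AtomSite(
                atom_id=int(arr.atom_id[i]) if arr.atom_id[i] else i + 1,
                atom_name=str(arr.atom_name[i]),
                element=str(arr.element[i]) or "C",
                chain_id=cid,
                residue_index=int(arr.res_id[i]),
                residue_name=str(arr.res_name[i]),
                position=np.asarray(arr.coord[i], dtype=float),
            )
        )
    chains = [(cid, chain_map.get(cid, "other")) for cid in chain_order]
    topo = ComplexTopology(chains, atoms)
    coords = np.asarray(arr.coord, dtype=float)
    return topo, coords


def write_structure(
    path: str | Path, topology: ComplexTopology, coordinates: np.ndarray
) -> None:
    """Write a topology + coordinates as a single-model PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = topology.n_atoms
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != (n, 3):
        raise InputError("coordinates shape must be (n_atoms, 3)")
    arr = struc.AtomArray(n)
    arr.coord = coordinates.astype(np.float32)
    arr.chain_id = topology.chain_id.astype("U4")
    arr.res_id = topology.residue_index.astype(int)
    arr.res_name = topology.residue_name.astype("U5")
    arr.atom_name = topology.atom_name.astype("U6")
    arr.element = topology.element.astype("U2")
    arr.set_annotation("hetero", np.zeros(n, dtype=bool))
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# trajectory reading / writing
# ---------------------------------------------------------------------------


def read_trajectory(
    topology: ComplexTopology,
    paths: Sequence[str | Path],
    sampling_interval: float = 10.0,
) -> TrajectoryEnsemble:
    """Read one trial per file into an ensemble.

    ``.dcd`` files are read with the binary DCD reader (coordinates already in
    Angstrom; frame times assigned as k x sampling_interval starting at the
    interval, since the format carries no wall-clock).  Any other extension is
    read as the plain-text frame format, whose headers carry explicit times.
    """
    if not paths:
        raise InputError("at least one trajectory file is required")
    trials: list[Trial] = []
    for p in paths:
        p = Path(p)
        if p.suffix.lower() == ".dcd":
            trial = _read_dcd(p, sampling_interval)
        else:
            trial = _read_text_trajectory(p)
        if trial.n_atoms != topology.n_atoms:
            raise TopologyMismatchError(
                f"{p}: {trial.n_atoms} atoms per frame, topology has "
                f"{topology.n_atoms}"
            )
        trials.append(trial)
    return TrajectoryEnsemble(topology, trials, sampling_interval)


def _read_dcd(path: Path, sampling_interval: float) -> Trial:
    from mdtraj.formats import DCDTrajectoryFile

    try:
        with DCDTrajectoryFile(str(path)) as fh:
            xyz, _cell_lengths, _cell_angles = fh.read()
    except Exception as exc:
        raise FormatError(f"cannot read DCD file {path}: {exc}") from exc
    if xyz is None or len(xyz) == 0:
        raise FormatError(f"no frames in DCD file {path}")
    coords = np.asarray(xyz, dtype=float)
    times = sampling_interval * np.arange(1, coords.shape[0] + 1)
    return Trial(times, coords)


def _read_text_trajectory(path: Path) -> Trial:
    frames: list[np.ndarray] = []
    times: list[float] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        header = lines[i].split()
        if len(header) != 2:
            raise FormatError(f"{path}:{i + 1}: expected 'n_atoms time_ps' header")
        try:
            n_atoms, t = int(header[0]), float(header[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{i + 1}: bad frame header {lines[i]!r}") from exc
        block = lines[i + 1 : i + 1 + n_atoms]
        if len(block) < n_atoms:
            raise FormatError(f"{path}:{i + 1}: truncated frame (needs {n_atoms} atoms)")
        try:
            frame = np.array([[float(x) for x in ln.split()] for ln in block])
        except ValueError as exc:
            raise FormatError(f"{path}: bad coordinate line in frame at line {i + 1}") from exc
        if frame.shape != (n_atoms, 3):
            raise FormatError(f"{path}:{i + 1}: frame lines must hold exactly x y z")
        frames.append(frame)
        times.append(t)
        i += 1 + n_atoms
    if not frames:
        raise FormatError(f"no frames found in {path}")
    return Trial(np.asarray(times), np.stack(frames))


def write_text_trajectory(path: str | Path, trial: Trial, precision: int = 6) -> None:
    """Write a trial in the plain-text frame format (lossless to printed precision)."""
    fmt = f"%.{precision}f"
    with open(path, "w") as fh:
        for t, frame in zip(trial.frame_times, trial.coordinates):
            fh.write(f"{frame.shape[0]} {fmt % t}\n")
            np.savetxt(fh, frame, fmt=fmt, delimiter=" ")


def write_dcd_trajectory(path: str | Path, trial: Trial) -> None:
    """Write a trial as a binary DCD file (Angstrom, single precision)."""
    from mdtraj.formats import DCDTrajectoryFile

    with DCDTrajectoryFile(str(path), "w") as fh:
        fh.write(trial.coordinates.astype(np.float32))
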