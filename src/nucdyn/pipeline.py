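"""Orchestrate the full per-variant analysis from a single config.

Stages: read structure -> variant masks -> alignment (i, whole complex minus
tails) -> per-chain and DNA RMSD series -> alignment (ii, histone core only)
-> DNA RMSD + per-nucleotide RMSF -> essential-dynamics PCA, projections and
KDE landscape -> contact-frequency matrix -> helix occupancy.  Every output
is a TSV table; a manifest with checksums and a provenance block make reruns
auditable.  The analysis itself is deterministic: KDE and PCA have no
stochastic steps.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from nucdyn.config import parse_kv_file
from nucdyn.contacts import ContactFrequencyMatrix, contact_frequency, matrix_difference
from nucdyn.errors import InputError
from nucdyn.essential_dynamics import (
    EssentialDynamicsResult,
    FreeEnergyLandscape,
    ProjectionSeries,
    compute_modes,
    estimate_landscape,
    project,
)
from nucdyn.flexibility import RMSDSeries, RMSFProfile, rmsd_series, rmsf_profile
from nucdyn.secondary_structure import HelixOccupancy, helix_occupancy
from nucdyn.structure_io import (
    AnalysisWindow,
    TrajectoryEnsemble,
    read_structure,
    read_trajectory,
    resolve_window,
)
from nucdyn.superposition import align_ensemble
from nucdyn.topology import (
    DEFAULT_CHAIN_MAP,
    ModelVariant,
    RegionTable,
    make_selection,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated inputs for one variant analysis."""

    variant: ModelVariant
    topology_path: Path
    trajectory_paths: list[Path]
    sampling_interval: float = 10.0
    region_table: RegionTable = field(default_factory=RegionTable)
    chain_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CHAIN_MAP))
    window: AnalysisWindow = field(default_factory=AnalysisWindow.latter_half)
    cutoff: float = 10.0
    n_modes: int = 2
    kde_bandwidth: str = "scott"
    output_dir: Path | None = None
    seed: int = 0
    run_helix: bool = True

    def validate(self) -> None:
        if not self.topology_path.exists():
            raise InputError(f"topology file not found: {self.topology_path}")
        for p in self.trajectory_paths:
            if not p.exists():
                raise InputError(f"trajectory file not found: {p}")
        if not self.trajectory_paths:
            raise InputError("at least one trajectory path is required")
        if self.cutoff <= 0:
            raise InputError("cutoff must be positive")
        if self.n_modes < 1:
            raise InputError("need at least one PCA mode")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        items = parse_kv_file(path)
        base = Path(path).parent

        def respath(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        if "topology" not in items or "trajectories" not in items:
            raise InputError("config must set 'topology' and 'trajectories'")
        if "window.t0" in items or "window.t1" in items:
            window = AnalysisWindow(
                start_fraction=None,
                time_range=(float(items["window.t0"]), float(items["window.t1"])),
            )
        elif "window.start_fraction" in items:
            window = AnalysisWindow(start_fraction=float(items["window.start_fraction"]))
        else:
            window = AnalysisWindow.latter_half()
        chain_map = dict(DEFAULT_CHAIN_MAP)
        for key, value in items.items():
            if key.startswith("chainmap."):
                chain_map[key.split(".", 1)[1]] = value
        return cls(
            variant=ModelVariant.from_string(items.get("variant", "canonical")),
            topology_path=respath(items["topology"]),
            trajectory_paths=[
                respath(p.strip()) for p in items["trajectories"].split(",") if p.strip()
            ],
            sampling_interval=float(items.get("sampling_interval", "10")),
            region_table=RegionTable.from_config(items),
            chain_map=chain_map,
            window=window,
            cutoff=float(items.get("cutoff", "10")),
            n_modes=int(items.get("n_modes", "2")),
            kde_bandwidth=items.get("kde.bandwidth", "scott"),
            output_dir=respath(items["output"]) if "output" in items else None,
            seed=int(items.get("seed", "0")),
        )


@dataclass
class ReportBundle:
    """All tables of one variant analysis plus provenance."""

    variant: ModelVariant
    rmsd: list[RMSDSeries]
    dna_rmsd: RMSDSeries
    rmsf: RMSFProfile
    modes: EssentialDynamicsResult
    projections: ProjectionSeries
    landscape: FreeEnergyLandscape
    initial_point: tuple[float, float]
    contacts: ContactFrequencyMatrix
    helix: HelixOccupancy | None
    provenance: dict

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write every table as TSV plus a checksummed manifest; returns the manifest."""
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "rmsd.tsv": pd.concat(
                [s.to_dataframe() for s in self.rmsd + [self.dna_rmsd]],
                ignore_index=True,
            ),
            "rmsf.tsv": self.rmsf.to_dataframe(),
            "eigenvalues.tsv": pd.DataFrame(
                {
                    "mode": np.arange(1, self.modes.eigenvalues.size + 1),
                    "eigenvalue_A2": self.modes.eigenvalues,
                }
            ),
            "projections.tsv": self.projections.to_dataframe(),
            "landscape.tsv": self.landscape.to_dataframe(),
            "contacts.tsv": self.contacts.to_dataframe(),
        }
        arrows = pd.DataFrame(
            {
                "chain": [c for c, _ in self.modes.labels],
                "residue_index": [r for _, r in self.modes.labels],
            }
        )
        for m in self.projections.modes:
            vec = self.modes.eigenvectors[m - 1].reshape(-1, 3)
            arrows[f"mode{m}_dx"] = vec[:, 0]
            arrows[f"mode{m}_dy"] = vec[:, 1]
            arrows[f"mode{m}_dz"] = vec[:, 2]
        tables["mode_arrows.tsv"] = arrows
        if self.helix is not None and len(self.helix.labels):
            tables["helix_occupancy.tsv"] = self.helix.to_dataframe()
        manifest: dict[str, str] = {}
        for name, df in tables.items():
            path = outdir / name
            df.to_csv(path, sep="\t", index=False)
            manifest[name] = hashlib.sha256(path.read_bytes()).hexdigest()
        prov = dict(self.provenance)
        prov["initial_point"] = list(self.initial_point)
        (outdir / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest


def _stage(name: str, t0: float, **shapes) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-22s %6.2fs %s", name, t1 - t0, shapes or "")
    return t1


def run_full_analysis(
    config: RunConfig, ensemble: TrajectoryEnsemble | None = None
) -> ReportBundle:
    """Execute every analysis stage for one variant.

    ``ensemble`` may be supplied directly (e.g. fresh from the synthetic
    generator) to skip file reading; the config still drives masks, window,
    cutoff and mode count.
    """
    config.validate() if ensemble is None else None
    t0 = time.perf_counter()
    if ensemble is None:
        topo, ref_coords = read_structure(config.topology_path, config.chain_map)
        ensemble = read_trajectory(
            topo, config.trajectory_paths, config.sampling_interval
        )
    else:
        topo = ensemble.topology
        ref_coords = ensemble.trials[0].coordinates[0]
    t0 = _stage("read", t0, atoms=topo.n_atoms, trials=ensemble.n_trials)

    table = config.region_table
    dna_mask = make_selection(topo, table, "dna_c1p")
    ca_mask = make_selection(topo, table, "histone_ca")
    heavy = topo.heavy_mask()
    t0 = _stage("masks", t0, dna=len(dna_mask), ca=len(ca_mask))

    # convention (i): whole complex minus tails; RMSD vs each trial's start
    aligned_i = align_ensemble(ensemble, "whole_complex", region_table=table)
    rmsd_groups: list[RMSDSeries] = []
    for cid in topo.histone_chain_ids:
        idx = np.flatnonzero((topo.chain_id == cid) & heavy)
        core = [
            i
            for i in idx
            if table.classify(topo.role_of(cid), int(topo.residue_index[i])) == "core"
        ]
        if core:
            rmsd_groups.append(
                rmsd_series(aligned_i, np.asarray(core), group=topo.role_of(cid))
            )
    dna_idx = np.flatnonzero(np.isin(topo.chain_id, topo.dna_chain_ids) & heavy)
    rmsd_groups.append(rmsd_series(aligned_i, dna_idx, group="DNA(i)"))
    t0 = _stage("rmsd(i)", t0, groups=len(rmsd_groups))

    # convention (ii): histone core only, common reference = input structure,
    # so DNA deformation is measured in the core frame
    aligned_ii = align_ensemble(
        ensemble, "histone_core_only", reference=ref_coords, region_table=table
    )
    dna_rmsd = rmsd_series(aligned_ii, dna_idx, group="DNA(ii)")
    rmsf = rmsf_profile(aligned_ii, config.window, dna_mask, pooled=True)
    t0 = _stage("rmsf", t0, nucleotides=len(dna_mask))

    modes = compute_modes(aligned_ii, dna_mask, config.window)
    wanted = tuple(range(1, config.n_modes + 1))
    projections = project(aligned_ii, modes, wanted)
    window_sets = resolve_window(aligned_ii.ensemble, config.window)
    samples = projections.pooled(window_sets)[:, :2]
    landscape = estimate_landscape(samples, bandwidth_rule=config.kde_bandwidth)
    ref_x = ref_coords[dna_mask.indices].reshape(-1)
    s0 = (ref_x - modes.mean_structure.reshape(-1)) @ modes.eigenvectors[:2].T
    initial_point = (float(s0[0]), float(s0[1]))
    t0 = _stage("pca", t0, modes=config.n_modes, samples=samples.shape[0])

    contacts = contact_frequency(
        ensemble, dna_mask, ca_mask, cutoff=config.cutoff, window=config.window
    )
    t0 = _stage("contacts", t0, shape=contacts.values.shape)

    helix: HelixOccupancy | None = None
    if config.run_helix:
        has_backbone = bool(
            np.any(topo.atom_name == "N") and np.any(topo.atom_name == "O")
        )
        if has_backbone:
            helix = helix_occupancy(ensemble, config.window, topo.histone_chain_ids)
        else:
            logger.info("no backbone N/O atoms present; helix stage skipped")
        t0 = _stage("helix", t0)

    from importlib.metadata import version as _dist_version

    try:
        pkg_version = _dist_version("nucdyn")
    except Exception:
        pkg_version = "unknown"
    provenance = {
        "package_version": pkg_version,
        "variant": config.variant.value,
        "window": config.window.describe(),
        "cutoff_A": config.cutoff,
        "n_modes": config.n_modes,
        "kde_bandwidth": config.kde_bandwidth,
        "n_trials": ensemble.n_trials,
        "n_frames": [t.n_frames for t in ensemble.trials],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    return ReportBundle(
        variant=config.variant,
        rmsd=rmsd_groups,
        dna_rmsd=dna_rmsd,
        rmsf=rmsf,
        modes=modes,
        projections=projections,
        landscape=landscape,
        initial_point=initial_point,
        contacts=contacts,
        helix=helix,
        provenance=provenance,
    )


def compare_variants(bundles: list[ReportBundle]) -> dict:
    """Contact-matrix differences and RMSF ratios of each variant vs canonical."""
    canonical = next(
        (b for b in bundles if b.variant is ModelVariant.CANONICAL), None
    )
    if canonical is None:
        raise InputError("comparison requires a canonical bundle")
    out: dict[str, dict] = {}
    canon_rmsf = {lab: v for lab, v in zip(canonical.rmsf.labels, canonical.rmsf.values)}
    for b in bundles:
        if b is canonical:
            continue
        diff = matrix_difference(b.contacts, canonical.contacts)
        shared = [lab for lab in b.rmsf.labels if lab in canon_rmsf]
        ratios = np.array(
            [
                b.rmsf.values[b.rmsf.labels.index(lab)] / max(canon_rmsf[lab], 1e-12)
                for lab in shared
            ]
        )
        out[b.variant.value] = {
            "contact_difference": diff,
            "rmsf_ratio_labels": shared,
            "rmsf_ratio": ratios,
        }
    return out
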