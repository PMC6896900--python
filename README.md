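# nucdyn

Trajectory analysis for canonical and partially disassembled nucleosomes.

A nucleosome wraps ~147 bp of DNA around a histone octamer (two H2A/H2B and
two H3/H4 dimers).  During chromatin remodeling, nucleosomes transiently lose
a dimer — most often H2A/H2B, producing a hexasome — and the DNA's dynamics
change dramatically depending on which dimer is gone.  `nucdyn` implements
the post-processing pipeline used to characterize those dynamics from
molecular-dynamics trajectories of five model variants: the canonical
nucleosome and the four single-dimer deletions (ΔH3/H4, ΔH2A/H2B, ΔH3'/H4',
ΔH2A'/H2B', chains A–H in the usual 1KX5 convention).

It is aimed at structural-bioinformatics users who have trajectories (DCD or
a plain-text frame format) plus a PDB topology and want the standard
descriptor set without stitching together ad-hoc scripts.

## What it computes

With x_i(t) the position of atom i, and two alignment conventions —
(i) rigid-body fit on all heavy atoms except the histone tails, giving
x̄_i(t), and (ii) fit on histone-core heavy atoms only, giving x̂_i(t) —
the package computes:

* **RMSD(t)** = √⟨|x̄_i(t) − x̄_i(0)|²⟩_atoms per histone chain and for DNA,
  one series per trial.
* **RMSF per nucleotide** = √⟨|x̂_i − ⟨x̂_i⟩|²⟩ of each DNA C1' atom, pooled
  over the analysis window (default: the latter half of each run) and all
  trials.
* **Essential dynamics**: PCA of the stacked C1' coordinate vector X(τ);
  eigenvectors v_j are collective DNA deformation modes, and
  S(τ, j) = (X(τ) − ⟨X⟩)·v_j projects each frame into mode space.  A 2-D
  Gaussian KDE over (S₁, S₂) gives the probability-density landscape
  (−ln density is a free-energy surface up to kT).
* **Contact-frequency matrices**: a nucleotide (C1') and an amino acid (Cα)
  are in contact when their distance is strictly less than 10 Å; frequency is
  the fraction of pooled window frames in contact.  Differences against the
  canonical matrix expose tail relocation (e.g. the H2A C-terminal tail
  invading a vacated H3/H4 site).
* **α-helix occupancy** per histone residue, from backbone N–H···O=C
  hydrogen-bond energies (Kabsch–Sander electrostatic model, bond when
  E < −0.5 kcal/mol, amide H rebuilt from backbone geometry) and the
  minimal-helix rule of two consecutive i→i+4 turns.

A synthetic trajectory generator (`nucdyn.synthetic`) builds bead-level
nucleosome models — two DNA strands on the canonical superhelix, eight
histone chains with core/tail bead counts matching the standard region table
— and composes closed-form dynamics (sinusoidal arm breathing, center drift,
tail invasion, rigid wobble, Gaussian noise) so every analysis stage has an
exact oracle.  It is first-class, tested code, not a throwaway fixture.

## Worked example

Generate a ΔH2A/H2B ensemble (2 trials × 300 frames at the 147-bp study
geometry), align on the histone core, and compute RMSF, modes and the
landscape:

```python
import numpy as np
from nucdyn import (SyntheticSpec, generate_structure, generate_ensemble,
                    ModelVariant, RegionTable, make_selection, align_ensemble,
                    rmsf_profile, compute_modes, project, estimate_landscape)
from nucdyn.structure_io import AnalysisWindow, resolve_window

spec = SyntheticSpec(n_trials=2, n_frames=300, breathing_period_frames=60, seed=0)
structure = generate_structure(spec)
ensemble, truth = generate_ensemble(structure, spec, ModelVariant.DEL_H2A_H2B)

table = RegionTable()
dna = make_selection(ensemble.topology, table, "dna_c1p")
keep = np.isin(structure[0].chain_id, [c for c, _ in ensemble.topology.chains])
reference = structure[1][keep]
aligned = align_ensemble(ensemble, "histone_core_only", reference=reference)

window = AnalysisWindow.latter_half()
rmsf = rmsf_profile(aligned, window, dna)
arm = np.array([lab in set(truth.affected_labels) for lab in rmsf.labels])
print(f"RMSF: arm mean {rmsf.values[arm].mean():.2f} A, "
      f"background median {np.median(rmsf.values[~arm]):.2f} A")

modes = compute_modes(aligned, dna, window)
print(f"PCA: lambda_1 = {modes.eigenvalues[0]:.1f} A^2, "
      f"lambda_2 = {modes.eigenvalues[1]:.1f} A^2")
print(f"mode-1 overlap with injected breathing mode: "
      f"{abs(modes.eigenvectors[0] @ truth.mode):.3f}")

proj = project(aligned, modes, (1, 2))
landscape = estimate_landscape(proj.pooled(resolve_window(aligned.ensemble, window)))
s0 = (reference[dna.indices].reshape(-1)
      - modes.mean_structure.reshape(-1)) @ modes.eigenvectors[:2].T
print(f"initial conformation at S = ({s0[0]:.1f}, {s0[1]:.1f}) A; "
      f"density there / peak = {landscape.density_at(*s0)/landscape.density.max():.4f}")
```

Output:

```
RMSF: arm mean 2.92 A, background median 0.87 A
PCA: lambda_1 = 310.8 A^2, lambda_2 = 2.4 A^2
mode-1 overlap with injected breathing mode: 0.999
initial conformation at S = (56.7, -0.0) A; density there / peak = 0.0027
```

Reading it: DNA fluctuation is elevated ~3.4× on the arm adjacent to the
deleted H2A/H2B dimer and flat elsewhere; the leading PCA mode is exactly the
injected outward-breathing deformation; and the initial (crystal-like)
conformation sits in a near-zero-density region of the (S₁, S₂) landscape —
the ensemble has drifted away from it, the hexasome's signature.  Running the
same example with `ModelVariant.DEL_H3_H4` instead leaves the initial point
inside the high-density region: the invading H2A C-terminal tail pins the
DNA.

## Command line

```sh
nucdyn synth --out fixtures --variants canonical,dH2AH2B --trials 2 --frames 300
nucdyn validate --config run.cfg
nucdyn analyze  --config run.cfg --out report/
nucdyn compare  canonical.cfg dH3H4.cfg --out diffs/
```

Configs are plain `key = value` files (see `nucdyn/config.py` for the
schema); every output is TSV with a checksummed manifest and a provenance
block.

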