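# Methods

## Scope and model

`nucdyn` post-processes trajectories of nucleosome-like DNA–protein
complexes.  The object of study is the canonical nucleosome (eight histone
chains A–H, two 147-nt DNA strands I/J numbered −73…73 about the dyad) and
the four variants obtained by deleting one hetero-dimer: ΔH3/H4 (chains A,B),
ΔH2A/H2B (C,D), ΔH3'/H4' (E,F), ΔH2A'/H2B' (G,H).  Variants are constructed
by chain deletion only; surviving chains keep their file residue numbering
and atom order, and chain roles come from an explicit chain-id map (1KX5
defaults), never from sequence.

Histone residues are split into a folded core and disordered tails:

| histone | core    | tails                          |
|---------|---------|--------------------------------|
| H3      | 45–135  | 1–44 (N)                       |
| H4      | 25–102  | 1–24 (N)                       |
| H2A     | 18–98   | 1–17 (N), 99–128 (C)           |
| H2B     | 35–122  | 1–34 (N)                       |

Superposition, RMSD, RMSF and PCA exclude the tails (they are too disordered
to define a rigid frame); the contact analysis keeps them, because tail–DNA
contacts are exactly what distinguishes the variants.  Hydrogens, water and
ions are retained in the topology but excluded from every analysis mask.

## Alignment

Two conventions, both unweighted least-squares (Kabsch/SVD with the proper
rotation enforced by flipping the smallest singular direction when
det = −1):

* **(i) whole complex**: fit on all heavy atoms except histone tails.  Used
  for RMSD-vs-start of histones and DNA; removes global diffusion/rotation.
* **(ii) histone core only**: fit on histone-core heavy atoms, excluding all
  DNA.  Used before RMSF, PCA and projections, so DNA deformation is measured
  in the frame of the (nearly rigid) core.

The per-frame transform is applied to all atoms.  For RMSD-vs-start each
trial aligns to its own first frame; for the convention-(ii) analyses the
pipeline aligns every trial to the common input structure so that mode
projections and the initial conformation live in one frame.  Fewer than three
or collinear fit atoms raise rather than returning an ill-defined rotation.
Fits are mass-unweighted throughout.

## Descriptors

* RMSD(t) = √(mean over masked atoms of |x̄(t) − x̄(0)|²), one series per
  trial per group (one group per histone chain core, plus all-DNA).
* RMSF_i = √(mean over pooled window frames of |x̂_i − ⟨x̂_i⟩|²) for each DNA
  C1'.  The mean structure is computed over the same pooled window.  Pooled
  over trials by default; a per-trial flag reproduces one-curve-per-trajectory
  plots (with equal frame counts the pooled value equals the
  frame-count-weighted combination of per-trial moments, which is
  regression-tested).
* PCA: population covariance of the 3N-dimensional C1' coordinate vector over
  the pooled window (so Σλ_j equals the total positional variance), symmetric
  eigendecomposition, eigenvalues descending.  Eigenvector sign is fixed by
  making the largest-magnitude component positive; within numerically
  degenerate eigenvalues the order (by eigenvalue, then first differing
  component) is stable but physically arbitrary, and documented as such.
  Projections S(τ, j) are computed for *all* frames, not only the window, so
  trajectories can be drawn over the landscape.
* Landscape: 2-D Gaussian KDE (scipy, Scott's rule by default; Silverman
  selectable) over pooled (S₁, S₂) window samples, on a grid extending three
  bandwidths past the samples so the gridded density integrates to 1 within
  2%.  Reported as probability density; −ln(density) is available but no kT
  scaling is applied.  All samples identical yields a delta-like peak plus a
  warning instead of an error.
* Contacts: C1'–Cα Euclidean distance strictly below the cutoff (default
  10 Å; a pair at exactly 10 Å is a non-contact).  Raw, unaligned coordinates
  are used — distances are rigid-invariant.  The default engine prunes with a
  KD-tree but re-tests candidates with the same floating-point expression as
  the all-pairs loop, and is bit-equivalent to it (oracle-tested on 10³
  random frames).
* α-helix: backbone N–H···O=C energy
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond when
  E < −0.5 kcal/mol; both constants are config-exposed.  The amide H is
  always reconstructed (1.0 Å from N along the bisector opposite the
  C(i−1)–N–Cα angle), ignoring explicit hydrogens, so assignment is
  deterministic across force fields.  A residue is helical when it lies in a
  minimal helix i…i+3 supported by consecutive turns (bonds CO(i−1)→NH(i+3)
  and CO(i)→NH(i+4)).  Only the α class is assigned; 3₁₀/π helices and
  strands are out of scope.  Occupancy is helix-frames / window-frames,
  pooled; with equal per-trial frame counts pooling before or after the ratio
  coincides.

## Windows and file formats

The analysis window defaults to the latter half of each run.  Frame times
start one sampling interval after zero (a 100 ns run sampled every 10 ps has
frames at 0.01–100 ns), so "latter half" selects exactly the frames at
times strictly greater than half the final time — 5,000 of 10,000 frames,
i.e. 50.01–100 ns.  Explicit time ranges are also accepted.

Structures are PDB (biotite; altloc resolved to highest occupancy).
Trajectories are binary DCD (mdtraj's reader; coordinates natively in Å) or a
documented plain-text format (`n_atoms time_ps` header plus one `x y z` line
per atom, lossless to its printed precision).  No periodic-boundary
unwrapping is performed; the complex must be whole in each frame (re-imaging
is engine-specific pre-processing).  Tabular outputs are TSV with a
checksummed manifest.

## Synthetic trajectory generator

The generator emulates the *statistical structure* the analyses assume, with
closed-form ground truth, not molecular physics:

* Geometry: two DNA strands (one C1' bead per nucleotide) on a left-handed
  superhelix — radius 41.9 Å, pitch 25.9 Å, 1.65 turns, the standard
  nucleosome values; eight histone chains (one Cα bead per residue) as
  compact lattice balls at the four dimer positions, with tail beads winding
  helically around their own cluster.  Bead counts match the region table
  (e.g. H2A: 128).  Any two beads closer than 1 Å make the spec invalid and
  raise; the default geometry is tuned for ~147 bp and very small complexes
  may legitimately be impossible.
* Dynamics per frame: reference + breathing + drift + invasion + wobble +
  noise.
  * *Breathing*: sinusoid along an outward-radial unit mode over the arm
    beads adjacent to the deleted dimer (default 20 bp, i.e. 40 beads across
    both strands; per-bead peak amplitude 4 Å, period 200 frames).  The
    amplitude along the unit 3N mode is amplitude·√(n beads), stored in the
    ground truth together with per-bead expected RMSF
    √(A²_mode·|u_i|²/2 + 3σ²).
  * *Drift* (H2A/H2B-type deletions only): the fluctuation center moves
    60 Å along the same unit mode with a smooth ramp over the first 10% of
    frames — the ensemble leaves the initial conformation, giving the
    hexasome's landscape signature.
  * *Tail invasion* (H3/H4-type deletions, on by default): the adjacent H2A
    C-terminal tail (30 beads; chain G for ΔH3/H4, chain C for ΔH3'/H4')
    relocates onto the vacated DNA patch and the arm breathing is suppressed
    — fluctuations stay centered on the initial structure and the tail–DNA
    contact frequency gains.  With invasion off, the arm breathes like the
    H2A/H2B case.
  * *Wobble*: a slow rigid z-rotation (5°) plus translation (2 Å) of the
    whole complex, to exercise the alignment stage.
  * *Noise*: i.i.d. Gaussian, σ = 0.5 Å per coordinate (background RMSF
    σ√3 ≈ 0.87 Å, a typical thermal scale).
* Defaults mirror the study conditions: 147 bp, 10 trials × 10,000 frames at
  10 ps.  Identical spec + seed is bitwise reproducible (RNG keyed per
  (seed, trial)).

What it does **not** emulate — and therefore what passing tests do not show
about real data: anharmonic/diffusive DNA unwrapping (breathing here is a
single sinusoidal mode, chosen so mode shape and eigenvalue have closed
forms), force-field energetics, solvent, sequence effects, correlated
multi-mode dynamics, and all-atom side chains.  Secondary-structure code is
instead exercised on ideal-geometry poly-alanine backbones (N/CA/C/O placed
by internal-coordinate construction at prescribed φ/ψ; α: −57°/−47°,
extended: 180°/180°), where the hydrogen-bond ladder is known exactly and an
independent DSSP implementation agrees.

## Problem sizes

Tests and the acceptance script run the full 147-bp, all-chain geometry but
with reduced sampling chosen as the smallest sizes at which every statistical
check is comfortably stable: closed-form recoveries use 1 trial × 5,000
frames; the variant-signature analyses use 2 trials × 300 frames.  The
defaults remain the full study conditions.

## Known limitations

* Atom correspondence between structures is positional (mask order); there is
  no sequence alignment, so cross-crystal comparisons (e.g. a 1KX5-derived
  hexasome vs a deposited hexasome structure) require the caller to supply
  matched masks.  `structure_rmsd` exposes independent fit and measure masks
  for exactly that use.
* Whether both DNA strands should be pooled per nucleotide index in contact
  matrices is a presentation choice; strands are kept separate.
* Terminal DNA nucleotides are never excluded from selections by default.
* The KDE bandwidth rule is recorded in the landscape metadata because the
  landscape's absolute density values (though not its qualitative shape)
  depend on it.
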