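# Methods

## Scope and resolution

All models operate on one node per residue.  Structures are parsed from
standard PDB ATOM records down to Cα (and, where present, Cβ)
coordinates; hetero-atoms, waters and ions are ignored, residues
without a Cα are skipped with a warning, and a missing Cβ (glycine) is
recorded as missing rather than imputed.  Residues are addressed
internally by 0-based index and externally by `chain:resnum` labels, so
multi-chain complexes with overlapping numbering stay unambiguous.

## Elastic network models

The ANM connects residue pairs whose Cα–Cα distance is at most the
cutoff (boundary inclusive) with springs of uniform force constant γ.
Off-diagonal 3×3 Hessian blocks are −γ·r̂ᵢⱼr̂ᵢⱼᵀ, diagonal blocks the
negated sum of the row's off-diagonals, so rigid translations are
exactly in the null space.  The GNM uses the corresponding N×N graph
Laplacian (Kirchhoff matrix).  Defaults: cutoff 15 Å (ANM), 10 Å (GNM),
γ = 1.

*γ convention.*  No absolute energy scale is fixed: γ stays at 1 and
every derived quantity (mean-square fluctuations, PRS responses,
sampled trajectory amplitudes) is reported in γ-relative units.  Only
ratios, shapes and rankings are meaningful, which is all the analyses
consume.

*Zero-mode classification.*  Eigenvalues below `zero_tol` (default
1e-8) times the largest eigenvalue are rigid-body/disconnected modes;
more zero modes than expected (6 for ANM, 1 for GNM) logs a
degenerate-structure warning rather than raising, since near-mechanisms
(e.g. free torsion about a thin linker) are physically meaningful.
Covariances are pseudo-inverses over the nonzero modes only.

*Mode indexing.*  User-facing mode indices are 1-based over nonzero
modes: "mode 1" is the slowest internal motion.

*Overlap.*  `cumulative_overlap` reports |uᵢ·vⱼ| pair magnitudes —
eigenvector sign is arbitrary — and the cumulative overlap per k.  A
complete basis re-mixed by any orthogonal matrix scores 1 to numerical
precision, which is the completeness test.

*Subsystem reduction.*  `reduce_to_subsystem` eliminates environment
degrees of freedom by the Schur complement H_ss − H_se H_ee⁺ H_es.  The
environment block uses a pseudo-inverse so environment-internal rigid
null directions are tolerated.  The defining identity — the reduced
model's covariance equals the subsystem block of the full model's
covariance — holds on the subsystem's *internal* subspace: the full
complex's six rigid modes restrict to non-orthonormal rigid motions of
the subsystem, so the raw covariance blocks differ by rigid-body
components while the blocks projected off the subsystem's rigid basis
(`rigid_motion_basis`) agree to machine precision.  Tests and the
acceptance script compare in that projected form.  Comparing apo
versus in-complex modes of one molecule therefore proceeds by reducing
the complex to that molecule and overlapping against the standalone
model of the same residues.

## Hinge detection

Hinges are strict local minima of a GNM mode's squared shape within a
±`window` neighbourhood (default 3 residues), additionally required to
lie below `floor` (default 0.2) times the profile maximum.  Windows
never cross chain boundaries and the first/last `window` residues of a
chain are excluded — chain breaks and termini are not mechanical
hinges.  The defaults localise mode-1 hinge calls to the linker on the
synthetic dumbbell family; both are exposed as parameters since no
sharper criterion than "local minima" is canonical.

## Perturbation response scanning

The primary path is the closed form S_PRS[i,k] = ⅓‖C_ki‖²_F, the exact
infinite-sample limit of averaging ‖ΔR_k‖² over isotropically
distributed unit forces at residue i; finite Monte-Carlo force sampling
is retained only as an independent test oracle.  Rows are normalised by
their diagonal (response to unit deformation), making the diagonal
exactly 1.  Effectiveness/sensitivity are off-diagonal row/column means
of the normalised matrix — the self-response is a normalisation
artefact and is excluded.  Raw responses are squared displacements and
scale as 1/γ²; normalised responses, profiles and all rankings are
γ-independent.  Site rankings are dense (ties share a rank, rank 1
largest) with ties resolved at 9 significant digits so exact structural
symmetries are not split by floating-point noise.  PRS is built from
the intact complex's ANM so inter-chain responses are defined.

## Trajectory statistics

Statistics are Cα-level.  Superposition is a least-squares Kabsch fit
per frame, against the first frame or an iteratively refined mean
(convergence 1e-6 Å, max 20 iterations); an all-collinear frame gets
translated only, with a warning.  RMSD uses a reference frame (default
the first), RMSF and the DCCM use deviations from the trajectory mean.
The DCCM is clipped to [−1, 1] against rounding and refuses residues
with zero variance by name.  Trajectories produced by the modal
sampler are flagged aligned and skip superposition, because rigid-body
modes are never sampled (see below); real trajectories must be
superposed first, and the functions enforce the flag.

## Residue networks

Nodes sit on Cβ, falling back to Cα for glycine — the established
convention for this network type.  Trajectories carry one coordinate
per residue, so the Cβ node of frame f is the reference Cβ offset
rigidly attached to that frame's Cα; side-chain reorientation is below
this model's resolution.  A contact is a node pair within 6.5 Å in a
frame; the consensus graph keeps pairs at occupancy ≥ 0.5 (both
parameters exposed), and successive residues of a chain are always
connected (backbone guarantee, logged when it adds an edge the
distance test would reject) so chains cannot fragment at coarse
resolution.  Betweenness is unnormalised shortest-path centrality with
fractional credit among equal-length paths; a per-frame-averaged
variant is available via a flag since neither convention is canonical.
Path distances come from Floyd–Warshall on the unweighted consensus
graph; all minimum-length source→sink paths are enumerated
deterministically in lexicographic node order, capped at `max_paths`
(default 50).  Inter-chain steps along a path are reported as bridges.

## Synthetic structures and trajectories

The generator emulates three situations with known ground truth:

* **globule** — a self-avoiding random walk (bond 3.8 Å, hard core
  3.0 Å) confined to a sphere of radius 1.9·N^⅓ + 3 Å.  The
  confinement makes the 15 Å contact graph generically rigid, so the
  ANM has exactly 6 zero modes and the GNM 1 — the spectral counting
  benchmark.
* **dumbbell** — two such globules joined by a near-extended linker,
  with an enforced 10.5 Å clearance between the domains so the only
  short-range inter-domain contacts run through the linker; mode-1
  hinges and high-betweenness residues must localise there.
* **two-chain complex** — two chains grown into adjacent spheres until
  at least the requested number of inter-chain pairs fall within
  6.5 Å; the benchmark for subsystem reduction and bridge detection.

Pseudo-Cβ atoms sit 1.5 Å from the Cα along the local chain normal;
every 7th residue is a glycine without one, so the Cα fallback is
always exercised.  Generation is driven by a single explicitly seeded
RNG per call and retries are bounded; an unsatisfiable spec raises
rather than degrading.

Trajectories are sampled directly from a decomposed ANM: frame = 
reference + Σ c_k u_k with independent c_k ~ N(0, amplitude/λ_k) over
the nonzero modes, so the expected 3N×3N covariance is exactly
amplitude·H⁺ and the DCCM/RMSF oracles are analytic.  Zero modes are
excluded — no rigid drift, no superposition step to blur the
comparison.  What this does *not* emulate: anharmonicity, conformational
transitions, solvent friction and time correlation (frames are i.i.d.),
or side-chain packing.  Passing the recovery tests shows the estimators
are correct on harmonic, well-sampled data; it says nothing about
convergence behaviour on real MD, where sampling error and
superposition choices dominate.

Default study conditions used by the validation suite: 50 globules of
10–60 residues for the counting laws; a 20-residue globule for the PRS
oracle (20,000 Monte-Carlo forces); a 30-residue globule with 5,000
frames for covariance recovery; 20 two-chain complexes of 24 residues
for the reduction identity; 20 dumbbells (N = 40, linker residues
18–21) for hinge localisation; 100 random graphs of up to 12 nodes for
the network oracles.  These sizes keep every analytic oracle exact or
statistically tight while the whole suite runs in seconds.

## Pipeline

`allodyn run` executes generate/load → ENM (+ subsystem overlap when a
`subsystem` selection is supplied) → hinges → PRS → trajectory
statistics → network/pathways from one INI-style config.  Every output
file is listed in `manifest.json` with its sha256 and the parameters
used; nothing time-dependent is written, so a rerun with the same
config is bit-identical — the end-to-end determinism check.  A failing
stage aborts with the stage named, keeps earlier outputs, and marks the
manifest incomplete.

## Numerical choices and edge cases

* Eigendecomposition via `numpy.linalg.eigh` (dense, symmetric);
  matrices are kept exactly symmetric by construction, and effective
  Hessians are re-symmetrised after the Schur complement.
* Pseudo-inverses: spectral truncation at `zero_tol·λ_max` for model
  covariances; `rcond=1e-10` for the environment block.
* PDB coordinates are written at the format's fixed %8.3f precision;
  round-trips are exact to 5·10⁻⁴ Å.
* CSV outputs use a fixed `%.10g` float format and `\n` line endings
  for byte-stable reruns.
* Altloc handling follows Bio.PDB's deterministic highest-occupancy
  selection; insertion-coded residues are kept as distinct entries.

## Known limitations

Uniform spring constants only (no distance- or mass-weighted
variants); no mmCIF or binary trajectory formats; PRS from ENM
covariance only (not from MD covariance); suboptimal (longer than
minimum) pathway ensembles are out of scope; hinge definitions based
on mode sign crossovers are not implemented.  Biological conclusions
about any specific system require real structures and adequately
sampled trajectories — the synthetic benchmarks validate the
machinery, not the biology.
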