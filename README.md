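# allodyn

Coarse-grained allosteric dynamics of proteins and their complexes:
elastic-network mode analysis with subsystem/environment coupling,
hinge detection, perturbation response scanning (PRS), trajectory
fluctuation/correlation statistics, and residue-interaction-network
communication pathways.

## Who this is for

Structural bioinformaticians studying how binding partners, mutations
and post-translational modifications reshape a protein's collective
dynamics — e.g. how a partner protein docked on one domain re-routes
allosteric communication to a distant catalytic site.  The package
works at one-node-per-residue resolution (Cα, plus Cβ for network
nodes) and ships a synthetic-structure generator with analytically
known dynamics, so every stage can be validated against closed-form
oracles before being pointed at real structures.

## The models

**Elastic networks.**  In the anisotropic network model (ANM) each
residue is a node at its Cα position and residue pairs within
r_c = 15 Å are joined by springs of uniform force constant γ, giving a
3N×3N Hessian H whose diagonalisation yields 3N−6 nonzero modes; the
Gaussian network model (GNM) is the isotropic N×N Kirchhoff analogue
(r_c = 10 Å, N−1 nonzero modes) whose mode-shape minima predict hinge
residues.  Mode conservation between two states is scored by the
cumulative overlap

    Overlap(k) = [ (1/k) Σᵢ Σⱼ (uᵢ·vⱼ)² ]^{1/2},

and a complex is reduced to one of its molecules by the Schur
complement H_ss − H_se H_ee⁺ H_es, which keeps the elastic influence of
the eliminated environment.

**PRS.**  Linear response ΔR = H⁺F under a unit force applied one
residue at a time; averaging over isotropic force directions gives the
closed-form response matrix S_PRS[i,k] = ⅓‖C_ki‖²_F with C = H⁺.
Row-normalisation by the diagonal yields unit self-response; row means
(effectiveness) find residues whose perturbation propagates broadly,
column means (sensitivity) find residues that respond to perturbations
anywhere.

**Trajectory statistics.**  RMSD/RMSF after Kabsch superposition and
the dynamic cross-correlation map
C_ij = ⟨Δr_i·Δr_j⟩ / (⟨‖Δr_i‖²⟩⟨‖Δr_j‖²⟩)^{1/2} ∈ [−1, 1].

**Residue networks.**  Nodes at Cβ (Cα for glycine); an edge when two
nodes are within 6.5 Å, kept in the consensus graph when the contact
persists in ≥ 50% of frames.  Betweenness centrality ranks mediator
residues, and all shortest source→sink paths (Floyd–Warshall distances,
lexicographic enumeration) give the communication pathways, with
chain-crossing steps reported as interface bridges.

## Worked example

```python
import numpy as np
import allodyn as ad

spec = ad.SynthSpec(40, "dumbbell", linker_range=(18, 22), seed=1)
structure = ad.make_structure(spec)          # two domains + 4-residue linker

gnm = ad.GNM(structure).fit()
print(gnm.summary())
print("mode-1 hinges:", ad.find_mode_hinges(gnm, 1).labels(structure))

anm = ad.ANM(structure).fit()
print(ad.prs_matrix(anm).summary())

traj = ad.sample_enm_trajectory(anm, n_frames=500, amplitude=1.0, seed=2)
r = ad.rmsf(traj)
print("RMSF linker mean: %.2f, domain mean: %.2f (gamma-relative units)"
      % (r[18:22].mean(), np.r_[r[:18], r[22:]].mean()))

net = ad.build_network(traj)
bc = ad.betweenness(net)
top = np.argsort(bc)[::-1][:3]
print("top betweenness:", [(structure.labels[i], float(bc[i])) for i in top])
```

prints

```
GNM mode decomposition
  residues:        40
  cutoff:          10 A
  gamma:           1
  matrix size:     40
  zero modes:      1
  nonzero modes:   39
  slowest eigenvalues: 0.15155, 3.4065, 5.8377, 7.1678, 8.5266
mode-1 hinges: ['A:21']
Perturbation response scan
  residues:       40
  top effectors:  A:33, A:24, A:18, A:31, A:2
  top sensors:    A:15, A:7, A:13, A:5, A:28
RMSF linker mean: 32.87, domain mean: 27.46 (gamma-relative units)
top betweenness: [('A:21', 380.0), ('A:20', 380.0), ('A:19', 378.0)]
```

The single zero mode confirms a connected fold; the slowest mode's
hinge (A:21) falls inside the built-in linker (residues 19–22), and the
same linker residues dominate betweenness — every shortest path between
the domains is forced through them.  Fluctuation magnitudes are in
γ-relative units because the force constant is left at γ = 1.

The same workflow runs from the shell:

```bash
allodyn generate --topology dumbbell --n 40 --linker 18:22 --seed 1 --out toy.pdb
allodyn hinges --pdb toy.pdb --mode 1
allodyn run --config run.cfg        # full pipeline; see `allodyn config`
```

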