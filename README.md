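# tandemsh2

Analysis toolkit for heterogeneous solution ensembles of linker-tethered
two-domain proteins, modelled on the tandem SH2 domains of the phosphatase
SHP2 (N-SH2: residues 3–104, linker: 105–111, C-SH2: 112–216).

Multidomain proteins like the tandem SH2 do not adopt a single interdomain
arrangement in solution. Characterising the ensemble — and deciding whether
it is compatible with bivalent ligands such as bisphosphoryl tyrosine-based
activation motifs (BTAMs), whose ~40 Å linker must bridge both
phosphopeptide-binding sites — requires combining several analyses that
this package implements as one tested pipeline:

- **Essential dynamics** (`essential_dynamics`): PCA of Cα fluctuations
  after iterative least-squares fitting, projections of conformers and
  external crystal structures onto the essential plane (PC1, PC2),
  free-energy landscapes g = −kT ln(n/n_max), and GROMOS-style
  neighbour-counting clustering under a Cα-RMSD cutoff.
- **RDC analysis** (`rdc_analysis`): residual dipolar couplings obey
  D = D_max · eᵀ S e, with e the internuclear unit vector and S the
  traceless symmetric Saupe alignment tensor (5 degrees of freedom,
  fittable from ≥5 couplings by SVD least squares). Three schemes are
  provided: single template/single tensor, multiple templates constrained
  to one tensor, and one tensor per template fitted jointly to the
  ensemble-averaged couplings.
- **SAXS prediction** (`saxs_debye`): residue-bead Debye scattering
  I(q) = Σᵢⱼ fᵢfⱼ sin(qrᵢⱼ)/(qrᵢⱼ), ensemble averaging, self-consistent
  Guinier fits (Rg from ln I vs q² over q·Rg ≤ 1.3), and reduced χ² against
  experimental curves with fitted scale/offset.
- **Linkage screening** (`linkage_compat`): superposes peptide-bound
  single-domain templates onto each conformation and measures the
  head-to-tail and tail-to-head anchor distances (backbone C of the
  peptide's +6 residue to backbone N of the −4 residue, pY-relative
  numbering), threshold fractions with Wilson intervals, a straight-segment
  linker-clash heuristic, and displacement metrics (d_N-SH2, rmsd) relative
  to an autoinhibited reference.
- **Ensemble refinement** (`ensemble_refinement`): replica-averaged
  RDC-restrained rigid-body Monte Carlo, E = k Σⱼ(⟨D_calc⟩ − D_obs)²/σⱼ²,
  with per-replica tensors either refit from the data by SVD or computed
  from each replica's shape; greedy sub-ensemble selection; domain-integrity
  validation (KS statistics and histogram overlap of RMSD distributions).
- **Synthetic ground truth** (`synthetic_ensemble`): procedurally built
  rigid pseudo-domains joined by a flexible Cα linker, pose distributions
  with one, several, or a continuum of basins, shape-anchored surrogate
  alignment tensors, and simulated (noisy) RDC tables and SAXS curves — so
  every downstream stage is testable as a parameter-recovery problem.

`structure_io` supplies the shared containers (Structure, Ensemble,
Selection) with multi-model PDB as the interchange format (parsing via
biotite).

## Worked example

Generate a 30-conformer synthetic two-domain ensemble, analyse it, and fit
simulated couplings:

```bash
tandemsh2 generate --n 30 --seed 11 --out ens.pdb --truth-out truth.yaml
tandemsh2 pca ens.pdb --subspace-out sub.txt --projections-out proj.txt --fel-out fel.tsv
tandemsh2 cluster ens.pdb --out clusters.tsv
tandemsh2 saxs ens.pdb --out curve.dat
tandemsh2 rdc-fit ens.pdb rdc.tsv --scheme multi_tensor
```

which prints:

```
wrote 30 conformers to ens.pdb
PCA on 30 conformers: PC1-2 encompass 96.4%, PC1-5 98.8% of fluctuations
3 clusters; largest population 0.43
Guinier Rg = 1.754 nm (29 points, window q = 0.03-0.73 nm^-1)
RDC fit: 802 couplings, 30 tensor(s)
  Pearson r (global): 0.9963
  Q factor: 0.0859
```

Interpretation: the generated ensemble has three interdomain pose basins,
so the two leading principal components (which capture interdomain
rotation, not internal domain motion — hence ~96% of the fluctuation)
separate three clusters whose populations (0.43/0.37/0.20) recover the
planted basin weights. The Guinier radius of the ensemble-averaged curve
reflects the conserved prolate shape, and the multi-tensor RDC fit reaches
r ≈ 0.996 on couplings simulated with 0.5 Hz noise — the single-tensor and
single-structure schemes score visibly lower on the same data, which is the
diagnostic signature of a heterogeneous ensemble.

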