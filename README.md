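# pulsekinetics

Subcellular RNA kinetics from pulse-chase in situ sequencing data.

Metabolic pulse-chase labeling combined with in situ sequencing yields,
for each detected RNA molecule, a gene identity, a 3D position inside a
segmented cell, and a chase timepoint. From these, `pulsekinetics`
estimates four kinetic constants per gene — and resolves them by
cell-cycle phase:

| rate | meaning | units | estimator |
|---|---|---|---|
| α | synthesis | copies · voxel⁻¹ · h⁻¹ | closed-form inversion of the pulse ODE `dX/dt = α − βX`, `X(0)=0` |
| β | degradation | h⁻¹ | −slope of `ln X(t)` over the chase (`dX/dt = −βX`) |
| λ | nuclear export | h⁻¹ | −slope of the nuclear read fraction `y(t)` |
| γ | cytoplasmic translocation | DR · h⁻¹ | slope of mean distance ratio over chase time |

where `X(t)` is mean labeled concentration (copies per voxel of cell
volume, after normalization against constant reference genes) and the
distance ratio `DR = d_n/(d_n + d_c)` locates a cytoplasmic read
between the nuclear surface (0) and the cell membrane (→ 1);
`DR > 0.909` (i.e. `d_n/d_c > 10`) defines the peripheral shell.

The package covers the full path: two-base color-space barcode
decoding with quality-based error rejection, 3D read-to-cell and
compartment assignment via anisotropic distance transforms, reference
normalization and kinetic fitting with QC (α > 0, β > 0, R² ≥ 0.5),
marker-based cell-cycle phase scoring, and landscape analytics
(parameter correlations, Louvain kinetic gene clustering, expression
covariation over time, rank tests between gene groups). A pulse-chase
simulator with known ground truth backs every stage with
parameter-recovery tests.

Intended users: groups analyzing spatially resolved metabolic-labeling
experiments, and method developers who need a tested reference
implementation of the estimation chain with a generative model to
validate against.

## Worked example

```python
import pulsekinetics as pk

# simulate a small experiment with known rates
grid = pk.VoxelGrid((264, 264, 14))                  # 200x200x350 nm voxels
geometry = pk.synth.make_cell_geometry(grid, 100, seed=11)
truths = pk.synth.random_gene_truths(30, seed=12)    # 30 genes + 5 reference
cfg = pk.SimConfig(n_cells=100, genes=truths, detection_efficiency=0.2, seed=13)
reads, truth = pk.synth.simulate_experiment(cfg, geometry)

# assign reads to cells/compartments and estimate the four rates
assigned = pk.subcellular.assign_and_partition(reads, geometry)
design = pk.PulseChaseDesign()                       # 1 h pulse; 0,1,2,4,6 h chase; 1 h excluded
cm = pk.subcellular.count_matrix(assigned, geometry, design=design)
gs = pk.GeneSets(reference_genes=cfg.reference_genes)
norm = pk.kinetics.normalize_counts(cm, gs.reference_genes)
est = pk.kinetics.estimate_all(norm, design, genesets=gs, reads=assigned)
print(est[est.qc_pass][["gene", "alpha", "beta", "lam", "gamma", "r2_beta"]].head(3))
```

```
      gene     alpha      beta       lam     gamma   r2_beta
0  GENE000  0.001758  0.791845 -0.025140 -0.006061  0.972064
1  GENE001  0.002323  0.168247  0.081523 -0.019630  0.992202
2  GENE002  0.007931  0.752608  0.025207  0.019560  0.999519
```

Each row is one gene's fitted landscape: e.g. GENE002 is synthesized
at ~0.0079 copies/voxel/h, degrades at 0.75 h⁻¹ (half-life ~0.9 h),
loses ~2.5% nuclear fraction per hour, and its cytoplasmic pool drifts
outward at ~0.02 DR units/h; the decay fit explains 99.9% of the
variance. Against the simulator's truth these estimates rank-correlate
at Spearman 0.99 (α), 0.97 (β), 0.77 (λ) and 0.96 (γ) on this small
problem size; at the 200-cell study scale all four reach ≥ 0.86 even
at 20% detection (see `scripts/acceptance.py`).

The numbered scripts under `analysis/` run the same pipeline as a
narrative: `01` simulates and writes the workspace under `results/`,
`02` decodes simulated color intensities (99.5% accepted, 100% of
accepted correct at noise 0.2), `03` assigns compartments and shows
nuclear occupancy falling from 0.74 to 0.37 over the chase, `04` fits
and validates kinetics, `05` calls cell-cycle phases and produces the
phase-resolved 12-parameter table, `06` clusters the kinetic landscape
and runs the group comparisons.

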