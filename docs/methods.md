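# Methods

This note documents the models, conventions, defaults and known
limitations of `pulsekinetics`. It is the package's own account of its
science; every number quoted here is computed by the test suite, the
analysis drivers, or `scripts/acceptance.py`.

## The measurement being modeled

A metabolic label (a uridine analog such as 5-EU) is incorporated into
nascent RNA during a fixed **pulse** (default 1 h). Cells are then
washed and fixed at several **chase** times (default 0, 1, 2, 4, 6 h).
Labeled molecules are read out in situ: each detected amplicon carries
a gene identity (decoded over several color rounds) and a 3D position
inside a segmented cell. Because each timepoint is a separate fixed
sample, a "cell" downstream is a (segmentation label, timepoint) pair;
kinetics are inferred from population averages across cohorts, never
from tracking individual cells.

## Kinetic model

Let `X(t)` be a gene's labeled RNA concentration in copies per voxel
of cell volume. During the pulse of length τ, synthesis is zero-order
and degradation first-order:

    dX/dt = α − β·X,  X(0) = 0   →   X(τ) = (α/β)(1 − e^{−βτ})

After the pulse no new labeled RNA is made, so over the chase

    dX/dt = −β·X   →   X(t) = X₀·e^{−βt}.

Estimators (module `kinetics`):

* **β** — ordinary least squares of `ln X(t)` on chase time over the
  usable timepoints; β = −slope, with the fit's R² reported. A
  nonlinear least-squares mode on the natural scale exists for
  sensitivity analysis (`mode="nls"`); the log-linear form is the
  default because the measurement noise on mean concentrations is
  closer to multiplicative and the fit is closed-form and exact on
  noiseless exponentials.
* **α** — closed-form inversion of the pulse solution,
  `α = β·X₀/(1 − e^{−βτ})`, using the chase-0 concentration as X₀.
  When β ≤ 0 (or in `mode="linear"`), the zero-degradation limit
  `α = X₀/τ` is used and flagged. The inversion and its limit are
  asserted to 1e-4 in the tests (`α(X₀=2, β=0.5, τ=1) = 2.5415`).
* **λ** (nuclear export) — the nuclear read fraction
  `y(t) = nuclear/(nuclear+cytoplasmic)` is assumed to decline
  linearly with constant export; λ = −slope of the OLS fit, intercept
  f₀ retained. `y` is a *ratio of sums* across the cells of a
  timepoint (robust to empty cells), not a mean of per-cell ratios;
  the per-cell alternative is a one-line change where needed.
* **γ** (cytoplasmic translocation) — slope of the mean distance
  ratio of cytoplasmic reads, pooled across cells, on chase time. The
  sign is kept: genes genuinely moving inward have γ < 0.

All four regressions are unweighted across timepoints. The 1 h chase
is excluded by default (`PulseChaseDesign.excluded_chase_hours`):
residual label after washing inflates that sample, and the test suite
demonstrates that excluding it moves β̂ less than including it when a
multiplicative 1 h artifact is injected.

**Normalization.** Counts are rescaled per timepoint so the mean reads
per cell of the reference genes (probed for total, not labeled, RNA
and assumed time-invariant) are equal across timepoints; the common
target is the grand mean over timepoints, making the transform
idempotent. Concentrations divide normalized counts by the cell's
total voxel volume.

**QC.** A gene passes when α > 0, β > 0, and the β fit's R² ≥ 0.5.
λ and γ are not gated by default — they may legitimately be negative
and their fits are reported with their own R² for optional gating.
No gene is ever dropped by the estimator itself; `qc_pass` is a flag.

## Subcellular geometry and the distance ratio

`DR = d_n/(d_n + d_c)` where `d_n` is the distance to the nuclear
surface and `d_c` to the cell membrane: 0 at the nucleus, → 1 at the
membrane; `DR > 0.909` (equivalently `d_n/d_c > 10`) defines the thin
"periphery" shell, the rest of the cytoplasm is "middle"; ties go to
middle.

Convention (module `subcellular`): distances are Euclidean distance
transforms computed per cell in its padded bounding box, with the zero
set taken as the one-voxel shell just outside each surface (the
cytoplasmic voxels 26-adjacent to the nucleus, respectively to the
background). This makes `d_n = 0` exactly on nucleus-adjacent voxels
and `d_c = 0` on membrane-adjacent voxels, so DR spans [0, 1] on the
discrete grid. A voxel adjacent to both surfaces (degenerately thin
cytoplasm, < 1% of cytoplasmic voxels in the simulated geometries) has
`d_n + d_c = 0`; its DR is reported missing with a warning rather than
invented. `d_n` is measured only to the read's own cell's nucleus.
Distances use the physical anisotropic voxel spacing
(200 × 200 × 350 nm by default); `physical=False` reproduces
index-unit transforms for comparison with isotropic conventions. The
implementation is checked against an exhaustive all-pairs distance
oracle on small volumes.

## Decoding

Two-base color-space readout: one anchor base flanks each side of the
5-nt barcode, and the 6 overlapping dinucleotides of the anchored
sequence give the 6 round colors via the standard 4-color mapping
(identical-base pairs → 0; {AC,CA,GT,TG} → 1; {AG,GA,CT,TC} → 2;
{AT,TA,CG,GC} → 3). The mapping and anchors are configurable — the
chemistry's exact reading frame is a convention, and this is one
consistent realization of it.

Per round, the 4-channel vector is L2-normalized and the unique argmax
is the called color; tied maxima or a zero vector reject the dot.
Quality `Q = mean(−ln v_r)` over the normalized dominant values, 0 for
pure colors; the default acceptance threshold `Q ≤ 0.3` was calibrated
once so the false-assignment rate among accepted dots stays below 1%
at channel noise sd 0.2 (an even two-color mixture scores ≈ 0.35 and
is rejected). Matching is exact — no Hamming-distance rescue — so
single-round errors are rejected rather than corrected; codebook
construction refuses color-sequence collisions.

## Cell-cycle phase calling

Two scores per cell: mean nascent expression of the G1/S (19 genes,
replication licensing) and G2/M (18 genes, mitotic) marker sets, each
minus the mean of an expression-matched control pool (genes binned by
average expression into 25 bins, 50 controls sampled per marker from
its bin, seeded). Both scores ≤ 0 → G1, otherwise the larger score
wins; an exact positive tie goes to G2/M with a warning. Bin and
control-pool sizes follow the common single-cell convention and are
configurable. The implementation is cross-checked against scanpy's
gene scoring (correlation > 0.95 on a structured fixture; the two
sample control pools independently, so per-cell values differ
slightly).

A cell whose markers carry no signal scores near zero on both sets and
lands in G1 only by the sign convention, so recovery is measured on
cells whose markers are actually modulated: with 3-fold marker
inflation, ≥ 95% (observed: 100%) of inflated cells receive their
phase at 200 cells.

## Landscape analytics

* z-scores use the sample (n−1) standard deviation, parameter-wise,
  because between-parameter variance dominates between-phase variance.
* Gene clustering: Louvain multilevel community detection (via
  python-igraph) at resolution 1.0 on an undirected kNN graph
  (Euclidean on z-scored parameters, k = 20 by default), seeded.
  Genes with identical parameter vectors are deduplicated before graph
  construction so they always share a label. Clustering operates on
  the z-matrix directly; an embedding step before clustering is
  deliberately avoided as it adds a stochastic layer without changing
  what is being grouped.
* Covariation over time: Pearson correlation of normalized expression
  over all cells of the usable timepoints combined; average-linkage
  hierarchical clustering on 1 − r fixes one gene ordering that every
  per-timepoint matrix reuses, so the matrices are visually and
  numerically comparable. Zero-variance genes get missing rows/columns
  and sort last.
* Group comparisons (e.g. m6A-labeled vs unlabeled genes) use the
  two-sided Wilcoxon rank-sum test: exact enumeration when the smaller
  group has ≤ 10 genes and no ties, normal approximation with tie
  correction otherwise. Modification labels are consumed as a provided
  gene → label mapping; deriving them from immunoprecipitation data is
  out of scope. The analysis drivers use a clearly-marked *synthetic*
  label split for demonstration.

## The simulator and what it does (not) emulate

`synth` generates: non-overlapping ellipsoid cells with strictly
interior nucleus ellipsoids on a jittered lattice (anisotropic voxel
grid, non-overlap guaranteed by the lattice pitch); per-gene molecule
life histories — Poisson births in the nucleus during the pulse at
rate α × phase multiplier × cell volume, exponential lifetimes with
hazard β, nuclear→cytoplasm export, deterministic DR drift at rate γ
from a starting DR of 0.3 ± 0.05; independent per-molecule detection
(default efficiency 0.2, a realistic amplicon capture rate; recovery
is also validated at 1.0 to isolate estimator error from sampling
noise); constant-expression reference genes placed uniformly over the
whole cell; and cell-cycle phases drawn per cell (G1/G1S/G2M at
0.5/0.25/0.25) that scale α through per-gene phase multipliers.

Export has two modes because a constant first-order hazard does not
produce an exactly linear nuclear fraction: `linear_fraction_schedule`
makes the expected nuclear fraction exactly `max(0, f₀ − λt)`
(f₀ = 0.8), giving the λ estimator an exact target, while
`first_order_hazard` exports with constant hazard λ and lands
molecules at DR ≈ 0 just outside the nucleus. DR drift is
deterministic by default since the γ estimator uses only the mean DR;
the drift is a minimal stand-in for unknown cytoplasmic transport, not
a mechanistic claim. Cytoplasmic molecules are placed at the voxel
whose DR is nearest their target, so regenerating DR from the masks
agrees with the generative value up to grid quantization.

Default parameter ranges for recovery studies: α log-uniform on
[0.005, 0.05] copies/voxel/h (tens of copies per cell), β log-uniform
on [0.1, 1.0] /h (half-lives 0.7–7 h), λ uniform on [0.02, 0.10] /h,
γ uniform on [−0.03, 0.07] DR/h — spreads wide enough that rank
recovery is meaningful and magnitudes typical of mammalian mRNA
turnover on a 6 h chase.

Not emulated: optical blur and image formation (inputs begin at
per-dot intensities), amplicon size, cell migration/division during
the chase, segmentation errors, spatially correlated detection
dropout, and any synthesis after the pulse (matching the estimation
assumption; a residual-label artifact can be injected at one chosen
timepoint via `chase_inflation` for robustness tests). Passing
recovery tests therefore demonstrates the *estimators* are correct
under the stated model, not that real tissue obeys the model.

## Problem sizes and numerical choices

Recovery studies run 200 cells per timepoint × 50 kinetic genes + 5
reference genes over chases 0/1/2/4/6 h (the 1 h excluded at fitting),
the scale at which the simulator's Poisson noise leaves clear rank
structure; decoding studies use 10⁴ dots over a 100-gene codebook;
phase recovery uses 200 cells and the full printed marker lists;
cluster recovery uses two 50-gene Gaussian blobs (sd 0.1, centers 10
apart) over 10 clustering seeds. The analysis drivers use a smaller
100-cell × 30-gene workspace. All randomness flows through explicit
integer seeds (numpy `default_rng`; igraph seeded through Python's
`random`), and simulated read tables are byte-identical across runs
with the same configuration and seed.

Degenerate inputs are handled explicitly rather than silently: flat
series return slope 0 with undefined R² (failing QC), series with
fewer than 3 usable timepoints return missing estimates with flags,
zero reference signal and zero cell volumes raise, and degenerate-DR
reads carry missing DR.

## Known limitations

* β conflates nuclear and cytoplasmic degradation; compartment-
  specific decay is not identifiable from these aggregates and is
  deliberately not attempted.
* λ as a linear-decline slope is an approximation valid on the
  observed window; it is not a per-molecule export hazard, and the
  constant-hazard simulation mode shows the curvature the linear fit
  ignores.
* Estimates use population means per timepoint, so cell-to-cell
  kinetic heterogeneity within a phase is invisible.
* The γ estimator reads mean DR drift; diffusive transport with zero
  mean drift is indistinguishable from immobility.
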