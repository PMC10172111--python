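"""End-to-end validation studies on simulated pulse-chase data.

Each study generates its own inputs with the simulator, runs the full
estimation path (assignment -> compartment counts -> normalization ->
concentration -> kinetic fits), and measures how well known truth is
recovered.  These are the workhorses behind the analysis drivers and
the acceptance checks; problem sizes default to the study conditions
(200 cells per timepoint, 50 kinetic genes, chases 0/1/2/4/6 h).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import analysis, cellcycle, decoding, kinetics, subcellular, synth
from .datamodel import GeneSets, PulseChaseDesign, VoxelGrid

__all__ = [
    "run_recovery_study",
    "run_decoding_study",
    "run_phase_study",
    "run_cluster_study",
]

PARAMS = ("alpha", "beta", "lam", "gamma")


def run_recovery_study(
    seed: int = 0,
    n_cells: int = 200,
    n_genes: int = 50,
    detection_efficiency: float = 1.0,
    grid: VoxelGrid | None = None,
    by_phase: bool = False,
) -> dict:
    """Simulate, estimate, and compare estimates against truth.

    Returns the per-parameter Spearman correlation between true and
    estimated values, the relative bias of the degradation rate, and
    the full estimate/truth tables.  Each chase timepoint is its own
    ``n_cells``-cell cohort.
    """
    if grid is None:
        # lattice holding >= n_cells ellipsoid cells (pitch 24 x 24 in xy)
        import math

        side = math.ceil(math.sqrt(n_cells))
        grid = VoxelGrid((side * 24 + 24, side * 24 + 24, 14))
    geometry = synth.make_cell_geometry(grid, n_cells, seed=seed)
    fields = subcellular.distance_fields(geometry)
    truths = synth.random_gene_truths(n_genes, seed=seed + 1)
    cfg = synth.SimConfig(
        n_cells=n_cells,
        genes=truths,
        detection_efficiency=detection_efficiency,
        seed=seed + 2,
    )
    reads, truth = synth.simulate_experiment(cfg, geometry, fields=fields)
    assigned = subcellular.assign_and_partition(reads, geometry, fields=fields)
    design = PulseChaseDesign()
    cm = subcellular.count_matrix(assigned, geometry, design=design)
    genesets = GeneSets(reference_genes=cfg.reference_genes)
    norm = kinetics.normalize_counts(cm, genesets.reference_genes)
    phase_partition = None
    if by_phase:
        key = list(zip(cm.cells["timepoint_h"], cm.cells["cell_id"]))
        lookup = {
            (row.timepoint_h, row.cell_id): row.phase
            for row in truth.cell_phase.itertuples()
        }
        phase_partition = pd.Series([lookup[k] for k in key])
    estimates = kinetics.estimate_all(
        norm, design, genesets=genesets, reads=assigned, phase_partition=phase_partition
    )
    tf = truth.truth_frame()
    tf = tf[~tf["is_reference"]]
    merged = estimates[estimates["phase"] == "all"].set_index("gene").loc[tf.index]
    spearman = {
        p: float(spearmanr(tf[p], merged[p], nan_policy="omit").statistic)
        for p in PARAMS
    }
    rel = (merged["beta"] - tf["beta"]) / tf["beta"]
    return {
        "spearman": spearman,
        "beta_median_rel_bias": float(np.median(rel)),
        "qc_pass_fraction": float(merged["qc_pass"].mean()),
        "estimates": estimates,
        "truth": tf,
        "n_reads": int(len(assigned)),
        "matrix": norm,
        "reads": assigned,
        "cell_phase": truth.cell_phase,
    }


def run_decoding_study(
    seed: int = 0,
    n_dots: int = 10_000,
    noise_sd: float = 0.2,
    n_genes: int = 100,
    q_max: float = decoding.DEFAULT_Q_MAX,
) -> dict:
    """Simulate noisy color reads and measure decoding performance.

    Accuracy is computed among *accepted* dots; rejection is how the
    chemistry absorbs errors.
    """
    rng = np.random.default_rng(seed)
    codebook = decoding.random_codebook([f"G{i:03d}" for i in range(n_genes)], seed=seed)
    genes = rng.choice(list(codebook.entries), size=n_dots)
    dots = synth.simulate_intensities(pd.DataFrame({"gene": genes}), codebook, noise_sd, seed=seed + 1)
    result = decoding.decode(dots, codebook, q_max=q_max)
    accepted = result[~result["rejected"]]
    correct = accepted["gene"].to_numpy() == genes[accepted["dot_id"].to_numpy()]
    return {
        "n_dots": n_dots,
        "n_accepted": int(len(accepted)),
        "accept_rate": float(len(accepted) / n_dots),
        "accuracy": float(correct.mean()) if len(accepted) else np.nan,
        "result": result,
    }


def run_phase_study(
    seed: int = 0,
    n_cells: int = 200,
    inflation: float = 3.0,
) -> dict:
    """Score simulated marker-inflated cells and measure phase recovery.

    Accuracy is over the marker-inflated (G1/S and G2/M truth) cells:
    an uninflated G1 cell carries no signal by construction, so only
    inflated cells test the classifier.
    """
    expr, truth = synth.simulate_marker_expression(
        n_cells,
        cellcycle.G1S_MARKERS,
        cellcycle.G2M_MARKERS,
        inflation=inflation,
        seed=seed,
    )
    scores = cellcycle.score_cell_cycle(expr, seed=seed + 1)
    inflated = truth != "G1"
    acc = float((scores.loc[inflated, "phase"] == truth[inflated]).mean())
    return {
        "accuracy_inflated": acc,
        "n_cells": n_cells,
        "n_inflated": int(inflated.sum()),
        "scores": scores,
        "truth": truth,
    }


def run_cluster_study(seed: int = 0, n_seeds: int = 10) -> dict:
    """Cluster the two-blob parameter fixture across clustering seeds."""
    pm, blobs = synth.make_blob_parameters(seed=seed)
    agreements = []
    n_clusters = []
    for s in range(n_seeds):
        labels = analysis.cluster_kinetics(pm, k_neighbors=20, seed=seed + s)
        tab = pd.crosstab(labels, blobs)
        agreements.append(float(tab.max(axis=1).sum() / len(labels)))
        n_clusters.append(int(labels.nunique()))
    return {
        "min_agreement": min(agreements),
        "agreements": agreements,
        "n_clusters": n_clusters,
        "n_genes": len(pm),
    }
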