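#!/usr/bin/env python
"""Kinetic landscape analytics: correlations, clustering, covariation.

From the phase-resolved kinetic table (driver 05): z-scores the up-to-
12-parameter landscape, computes pairwise parameter correlations, and
clusters genes by Louvain on a kNN graph.  From the compartment counts
(driver 03): builds the nucleocytoplasmic matrix and the gene-gene
expression covariation matrices (combined and per timepoint, one fixed
hierarchical gene ordering).  Finally compares degradation rates
between two synthetic gene groups that emulate an RNA-modification
split (genes labeled by thresholding true decay with label noise —
a synthetic stand-in for measured modification calls).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import pulsekinetics as pk
from pulsekinetics import analysis
from pulsekinetics.datamodel import read_matrix_market

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "landscape"
SEED = 41


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    est = pd.read_csv(ROOT / "cellcycle" / "kinetics_by_phase.tsv", sep="\t")

    # z-scored landscape, correlations, Louvain clusters
    pm = analysis.pivot_phase_parameters(est, qc_only=True)
    z = analysis.zscore_parameters(pm)
    z.to_csv(OUT / "parameters_z.tsv", sep="\t", float_format="%.4f")
    corr = analysis.pairwise_parameter_correlation(pm)
    corr.to_csv(OUT / "correlations.tsv", sep="\t", float_format="%.4f")
    k = min(10, len(pm) - 1)
    clusters = analysis.cluster_kinetics(pm, k_neighbors=k, seed=SEED)
    clusters.to_csv(OUT / "clusters.tsv", sep="\t")
    print(f"clustered {len(pm)} QC-passing genes on {pm.shape[1]} parameters "
          f"into {clusters.nunique()} Louvain clusters (k={k}, resolution 1.0)")

    # covariation of normalized expression over time
    cm = read_matrix_market(ROOT / "sim" / "counts")
    design = pk.PulseChaseDesign.from_yaml(ROOT / "sim" / "design.yaml")
    norm = pk.kinetics.normalize_counts(
        cm, pk.GeneSets.from_yaml(ROOT / "sim" / "genesets.yaml").reference_genes
    )
    conc = pk.kinetics.to_concentration(norm)
    expr_by_tp = {
        t: conc.loc[:, (norm.cells["timepoint_h"] == t).to_numpy()]
        for t in design.usable_chase_hours
    }
    combined, per_tp = analysis.covariation_over_time(expr_by_tp)
    combined.to_csv(OUT / "covariation_combined.tsv", sep="\t", float_format="%.4f")
    for t, mat in per_tp.items():
        mat.to_csv(OUT / f"covariation_t{int(t)}.tsv", sep="\t", float_format="%.4f")
    nc = analysis.build_nucleocytoplasmic_matrix(norm)
    nc.to_csv(OUT / "nucleocytoplasmic_matrix.tsv", sep="\t", float_format="%.4f")
    print(f"covariation matrices written for combined + {len(per_tp)} timepoints "
          f"({combined.shape[0]} genes, one shared ordering)")

    # group comparison on a synthetic modification split
    truth = pd.DataFrame(
        json.loads((ROOT / "sim" / "truth.json").read_text())["gene_truth"]
    ).set_index("gene")
    truth = truth[~truth["is_reference"]]
    rng = np.random.default_rng(SEED)
    median_beta = truth["beta"].median()
    labels = {}
    for g, b in truth["beta"].items():
        lab = "m6a" if b > median_beta else "non_m6a"
        if rng.random() < 0.1:  # label noise
            lab = "non_m6a" if lab == "m6a" else "m6a"
        labels[g] = lab
    test = analysis.compare_gene_groups(est, labels, "beta", phase="all")
    (OUT / "group_test.json").write_text(json.dumps(test, indent=1))
    print(f"degradation, {test['group_a']} (n={test['n_a']}, median {test['median_a']:.3g}) vs "
          f"{test['group_b']} (n={test['n_b']}, median {test['median_b']:.3g}): "
          f"two-sided rank-sum p = {test['p_value']:.3g} ({test['method']})")


if __name__ == "__main__":
    main()
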