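#!/usr/bin/env python
"""Estimate per-gene kinetic constants and validate against truth.

Normalizes compartment counts against the constant reference genes,
converts to concentrations (copies/voxel), and fits the four rates per
gene over the 0/2/4/6 h chase (1 h excluded as the residual-label
outlier): degradation beta from log-linear decay, synthesis alpha by
closed-form inversion of the pulse solution, export lam from the
nuclear-fraction slope, translocation gamma from the mean-DR slope.
Writes kinetics.tsv and a truth-recovery summary.  Requires 01 + 03.
"""

import json
from pathlib import Path

import pandas as pd
from scipy.stats import spearmanr

import pulsekinetics as pk
from pulsekinetics.datamodel import read_matrix_market, read_reads_tsv

SIM = Path(__file__).resolve().parent.parent / "results" / "sim"
OUT = Path(__file__).resolve().parent.parent / "results" / "kinetics"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = pk.PulseChaseDesign.from_yaml(SIM / "design.yaml")
    genesets = pk.GeneSets.from_yaml(SIM / "genesets.yaml")
    cm = read_matrix_market(SIM / "counts")
    reads = read_reads_tsv(SIM / "reads_assigned.tsv", design=design)

    norm = pk.kinetics.normalize_counts(cm, genesets.reference_genes)
    estimates = pk.kinetics.estimate_all(norm, design, genesets=genesets, reads=reads)
    estimates.to_csv(OUT / "kinetics.tsv", sep="\t", index=False, float_format="%.6g")

    truth_doc = json.loads((SIM / "truth.json").read_text())
    truth = pd.DataFrame(truth_doc["gene_truth"]).set_index("gene")
    truth = truth[~truth["is_reference"]]
    merged = estimates.set_index("gene").loc[truth.index]
    summary = {"n_genes": len(truth), "qc_pass": int(merged["qc_pass"].sum())}
    for p in ("alpha", "beta", "lam", "gamma"):
        # genes with too few reads for a given fit carry NaN estimates
        rho = spearmanr(truth[p], merged[p], nan_policy="omit").statistic
        summary[f"spearman_{p}"] = round(float(rho), 4)
        summary[f"n_estimable_{p}"] = int(merged[p].notna().sum())
    (OUT / "recovery_summary.json").write_text(json.dumps(summary, indent=1))

    print(f"estimated 4 rates for {len(merged)} genes; {summary['qc_pass']} pass QC "
          f"(alpha>0, beta>0, R^2>=0.5)")
    print("Spearman(true, estimated):",
          {p: summary[f'spearman_{p}'] for p in ('alpha', 'beta', 'lam', 'gamma')})


if __name__ == "__main__":
    main()
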