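#!/usr/bin/env python
"""Decode simulated color-space reads and quantify error rejection.

Builds a random 5-nt barcode codebook for the simulated genes, emits
per-round 4-channel intensities for a 20,000-dot subsample at channel
noise 0.2, and decodes them: L2-normalized color calling, quality
scoring, exact codebook matching.  Reports acceptance and accuracy
among accepted dots (mismatches are rejected, never corrected).
Requires results/sim from 01_simulate_experiment.py.
"""

import json
from pathlib import Path

from pulsekinetics import decoding, synth
from pulsekinetics.datamodel import read_reads_tsv

SIM = Path(__file__).resolve().parent.parent / "results" / "sim"
OUT = Path(__file__).resolve().parent.parent / "results" / "decoding"
SEED = 21
NOISE_SD = 0.2


def main() -> None:
    reads = read_reads_tsv(SIM / "reads.tsv")
    OUT.mkdir(parents=True, exist_ok=True)
    genes = sorted(reads["gene"].unique())
    codebook = decoding.random_codebook(genes, seed=SEED)
    codebook.to_tsv(OUT / "codebook.tsv")

    sample = reads.sample(n=min(20_000, len(reads)), random_state=SEED).reset_index()
    dots = synth.simulate_intensities(sample, codebook, noise_sd=NOISE_SD, seed=SEED + 1)
    result = decoding.decode(dots, codebook)
    accepted = result[~result["rejected"]]
    truth = sample["gene"].to_numpy()
    accuracy = float((accepted["gene"].to_numpy() == truth[accepted["dot_id"].to_numpy()]).mean())
    summary = {
        "n_dots": len(sample),
        "noise_sd": NOISE_SD,
        "q_max": decoding.DEFAULT_Q_MAX,
        "accept_rate": round(len(accepted) / len(sample), 4),
        "accuracy_accepted": round(accuracy, 5),
        "rejections": result.loc[result["rejected"], "reason"].value_counts().to_dict(),
    }
    (OUT / "decode_summary.json").write_text(json.dumps(summary, indent=1))
    print(f"decoded {len(sample)} dots at noise sd {NOISE_SD}: "
          f"{summary['accept_rate']:.1%} accepted, "
          f"{summary['accuracy_accepted']:.2%} of accepted correct")
    print(f"rejection reasons: {summary['rejections']}")


if __name__ == "__main__":
    main()
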