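#!/usr/bin/env python
"""Simulate the study cohort.

Generates a case/control hiPSC-derived cohort with the emulated study's
structure — 11 case and 11 control donors, two lines per donor, each line
profiled as NPC and neuron (88 samples) — with a 2.2% donor effect, 10%
differentially expressed genes, Dirichlet cell-type mixing over a 12-profile
reference panel, sex-chromosome signatures, two embedded CNV deletions, and a
Sendai-positive donor subset.  Writes counts, metadata, the signature panel,
gene coordinates and the ground-truth channel under results/data/.
"""

import argparse
from pathlib import Path

from hipscpipe import io as pio
from hipscpipe.synthetic import SimulationConfig, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main(seed: int = 1, n_genes: int = 2500) -> None:
    cfg = SimulationConfig(
        n_genes=n_genes,
        cnv_events=[("case01", ("chr1", 100_000, 400_000), 0.5),
                    ("case02", ("chr2", 50_000, 300_000), 1.5)],
        sendai_donors=("case03", "ctrl04", "ctrl05"),
        n_intermediate_sex=4,
        seed=seed,
    )
    counts, md, truth = simulate_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    pio.write_counts(counts, OUT / "counts.tsv")
    pio.write_table(md, OUT / "metadata.tsv", index_label="sample_id")
    pio.write_table(md.attrs["gene_coords"], OUT / "gene_coords.tsv")
    panel = md.attrs["signature"]
    sig = panel.profiles.copy()
    sig.columns = [f"{panel.cell_type_map[p]}#{p}" for p in sig.columns]
    pio.write_table(sig, OUT / "signature.tsv")
    pio.write_table(
        truth.variance_fractions.join(truth.log2fc).join(truth.de_indicator)
        .join(truth.eqtl_indicator), OUT / "truth_genes.tsv")
    pio.write_table(truth.mixing, OUT / "truth_mixing.tsv", index_label="sample_id")
    pio.write_gene_list(truth.eqtl_indicator.index[truth.eqtl_indicator],
                        OUT / "eqtl_genes.txt")
    print(f"cohort: {counts.shape[0]} genes x {counts.shape[1]} samples "
          f"({md['donor'].nunique()} donors), written to {OUT}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-genes", type=int, default=2500)
    a = ap.parse_args()
    main(a.seed, a.n_genes)
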