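#!/usr/bin/env python
"""Coexpression modules.

Builds the unsigned soft-threshold (beta = 9) network and topological
overlap per cell type, cuts modules of at least 20 genes, and tests each
module (including grey) for enrichment of the simulated DE genes and eQTL
genes.  Diffusely distributed DE effects are expected to concentrate in the
grey (unassigned) module rather than in coherent modules.
"""

from pathlib import Path

import pandas as pd

from hipscpipe import io as pio
from hipscpipe.coexpression import (detect_modules, module_enrichment,
                                    soft_adjacency, topological_overlap)
from hipscpipe.enrichment import GeneSetCollection

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(max_genes: int = 1500) -> None:
    logcpm = pio.read_table(ROOT / "qc" / "log2_cpm.tsv")
    md = pio.read_table(ROOT / "data" / "metadata.tsv")
    truth = pio.read_table(ROOT / "data" / "truth_genes.tsv")
    out = ROOT / "coexpression"
    out.mkdir(parents=True, exist_ok=True)

    for ct in sorted(md["cell_type"].unique()):
        expr = logcpm[md.index[md["cell_type"] == ct]]
        keep = expr.var(axis=1).sort_values(ascending=False).index[:max_genes]
        expr = expr.loc[sorted(keep)]
        modules = detect_modules(topological_overlap(soft_adjacency(expr, beta=9)),
                                 min_module_size=20)
        modules.labels.to_csv(out / f"modules_{ct}.tsv", sep="\t",
                              header=["module"], index_label="gene_id")
        universe = set(modules.labels.index)
        sets = GeneSetCollection(
            sets={"de_genes": set(truth.index[truth["is_de"]]),
                  "eqtl_genes": set(truth.index[truth["is_eqtl"]])},
            universe=universe)
        enr = module_enrichment(modules, sets)
        enr.to_csv(out / f"module_enrichment_{ct}.tsv", sep="\t", index=False)
        grey = enr[(enr["module"] == "grey") & (enr["set"] == "de_genes")]
        sizes = modules.module_sizes.to_dict()
        print(f"{ct}: modules {sizes}; grey DE enrichment OR="
              f"{grey['odds_ratio'].iloc[0]:.2f} p={grey['p_value'].iloc[0]:.2e}"
              if len(grey) else f"{ct}: modules {sizes}")


if __name__ == "__main__":
    main()
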