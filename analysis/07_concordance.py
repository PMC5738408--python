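#!/usr/bin/env python
"""Cross-cohort concordance.

Simulates a second, independent cohort whose true diagnosis effects share
half their variance with the main cohort's (the regime where a small study
shows weak but highly significant rank correlation with a larger one), runs
DE in both, and reports the Spearman/Pearson concordance of t-statistics.
Also demonstrates the category-summary clustering and classical MDS on
samples pooled across the two cohorts: samples should organize by cell type
first.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hipscpipe import io as pio
from hipscpipe.concordance import category_summary_clustering, classical_mds, concordance
from hipscpipe.diffexpr import de_pipeline
from hipscpipe.synthetic import (SimulationConfig, cohort_gene_names,
                                 make_signature_panel, simulate_paired_cohorts)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    out = ROOT / "concordance"
    out.mkdir(parents=True, exist_ok=True)

    # both cohorts profile the same genes, so they share one signature panel
    panel = make_signature_panel(cohort_gene_names(2000),
                                 np.random.default_rng(seed + 1000))
    cfg_big = SimulationConfig(n_genes=2000, n_donors_case=40, n_donors_control=40,
                               lines_per_donor=2, cell_types=("NPC", "neuron"),
                               icc_donor=0.2, frac_de_genes=0.3, lfc_sd=0.5,
                               signature=panel, seed=seed)
    cfg_small = SimulationConfig(n_genes=2000, n_donors_case=10, n_donors_control=10,
                                 lines_per_donor=2, cell_types=("NPC", "neuron"),
                                 icc_donor=0.2, frac_de_genes=0.3, lfc_sd=0.5,
                                 signature=panel, seed=seed)
    (ca, ma, _), (cb, mb, _) = simulate_paired_cohorts(cfg_big, 0.5, cfg_small)

    def de(c, m, cell_type):
        sub = m[m["cell_type"] == cell_type]
        X = np.column_stack([np.ones(len(sub)),
                             (sub["diagnosis"] == "case").to_numpy(float)])
        return de_pipeline(c[sub.index], X, 1, block=sub["donor"].tolist(),
                           use_weights=False)

    rows = []
    for ct in ("NPC", "neuron"):
        rep = concordance(de(cb, mb, ct), de(ca, ma, ct), stat="t")
        rows.append({"cell_type": ct, "spearman": rep.spearman,
                     "p_one_sided": rep.spearman_p_onesided,
                     "pearson": rep.pearson, "n_genes": rep.n_shared_genes})
    tab = pd.DataFrame(rows).set_index("cell_type")
    pio.write_table(tab, out / "t_statistic_concordance.tsv", index_label="cell_type")
    print("small-cohort vs large-cohort concordance of t-statistics:")
    print(tab.round(4).to_string())

    # pooled sample clustering and MDS by cohort x cell type category
    from hipscpipe.normalize import filter_genes, tmm_normalize
    norm_a = tmm_normalize(ca.loc[filter_genes(ca)])
    norm_b = tmm_normalize(cb.loc[filter_genes(cb)])
    shared = norm_a.genes.intersection(norm_b.genes)
    pool = pd.concat([norm_a.log2_cpm.loc[shared],
                      norm_b.log2_cpm.loc[shared]], axis=1)
    cats = ([f"cohortA_{c}" for c in ma["cell_type"]]
            + [f"cohortB_{c}" for c in mb["cell_type"]])
    summary, newick = category_summary_clustering(pool, cats)
    pio.write_table(summary, out / "category_distance.tsv", index_label="category")
    (out / "category_tree.nwk").write_text(newick + "\n")
    coords = classical_mds(summary, k=2)
    pio.write_table(coords, out / "category_mds.tsv", index_label="category")
    print(f"category tree: {newick}")


if __name__ == "__main__":
    main()
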