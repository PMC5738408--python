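#!/usr/bin/env python
"""Effective sample size and study design.

Uses the donor effect estimated by variance partitioning to compute the
cohort's ESS and tabulates (a) the marginal ESS of additional lines across
the donor-effect range and (b) budget-optimal designs as the relative line
cost and donor effect vary.  At a low donor effect replicate lines are
almost as good as new donors; as the donor effect or the line cost grows the
optimum shifts to one line per donor.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hipscpipe import io as pio
from hipscpipe.design import ess, ess_increment, optimize_design

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(budget: float = 30.0) -> None:
    med = pio.read_table(ROOT / "varpart" / "median_fractions.tsv")
    rho_hat = float(med.loc["donor", "with_ctc"])
    md = pio.read_table(ROOT / "data" / "metadata.tsv")
    out = ROOT / "design"
    out.mkdir(parents=True, exist_ok=True)

    k_list = md.groupby("donor")["line"].nunique().tolist()
    cohort = ess(k_list, rho_hat)

    rows = []
    for rho in (0.022, rho_hat, 0.2, 0.488, 0.8):
        rows.append({"rho": rho,
                     **{f"line_{k+1}_gain": ess_increment(k, rho) for k in range(4)}})
    gains = pd.DataFrame(rows).set_index("rho")
    pio.write_table(gains, out / "marginal_ess_gains.tsv", index_label="rho")

    rows = []
    for alpha in (1.0, 0.5, 0.3):
        for rho in (0.022, 0.2, 0.488):
            spec, rep = optimize_design(budget, 1.0, alpha, rho)
            ks = pd.Series(spec.k_list).value_counts().sort_index()
            rows.append({"alpha": alpha, "rho": rho,
                         "n_donors": len(spec.k_list),
                         "n_samples": rep.n_samples,
                         "ess": rep.ess,
                         "design": "+".join(f"{n}x{k}" for k, n in ks.items())})
    opt = pd.DataFrame(rows)
    opt.to_csv(out / "optimal_designs.tsv", sep="\t", index=False)

    print(f"cohort donor effect (median) = {rho_hat:.3f}; "
          f"ESS of {cohort.n_samples} lines from {cohort.n_donors} donors = "
          f"{cohort.ess:.1f}")
    print("marginal ESS of each additional line per donor:")
    print(gains.round(3).to_string())
    print(f"budget-optimal designs (B = {budget} donor-units):")
    print(opt.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
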