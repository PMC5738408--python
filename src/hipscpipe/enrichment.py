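"""Gene-set enrichment: hypergeometric over-representation and the permutation
fold-enrichment curve relating variance fractions to an eQTL gene list.

The fold-enrichment statistic asks whether genes whose expression varies most
across a variable (typically donor) are over-represented among the top
cis-eQTL genes of an external study.  At each of a grid of cutoffs on the
variance fraction, the overlap between genes passing the cutoff and the eQTL
list is compared with the mean overlap after randomly permuting the variance
fractions across genes:

    fold enrichment = overlap_observed / mean(overlap_permuted)

with a confidence band taken from the permutation quantiles of the same
ratio.  The curve is truncated once too few genes pass the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "EnrichmentCurve",
    "hypergeom_enrich",
    "eqtl_fold_enrichment",
]


@dataclass
class GeneSetCollection:
    """Named gene sets over an explicit background universe.

    Sets are intersected with the universe on construction so downstream
    2x2 tables are well defined.
    """

    sets: dict[str, set]
    universe: set

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty background universe")
        self.universe = set(self.universe)
        self.sets = {name: set(s) & self.universe for name, s in self.sets.items()}

    @classmethod
    def from_gmt(cls, path, universe: Sequence[str]) -> "GeneSetCollection":
        """Read GMT (tab-separated: name, description, gene ids...)."""
        sets = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sets[parts[0]] = set(g for g in parts[2:] if g)
        return cls(sets=sets, universe=set(universe))


def hypergeom_enrich(hits: set, gene_set: set, universe: set) -> tuple[float, float, int]:
    """One-sided over-representation test of ``hits`` in ``gene_set``.

    Both sets are intersected with the universe.  Returns
    ``(odds_ratio, p_value, overlap)``.  The p-value is the upper tail of the
    hypergeometric distribution (probability of an overlap at least as large
    under random draws).  The odds ratio comes from the 2x2 table; a Haldane
    correction of 0.5 is added only when some cell is zero.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty background universe")
    hits = set(hits) & universe
    gene_set = set(gene_set) & universe
    n_univ = len(universe)
    k = len(hits & gene_set)
    # upper-tail P(X >= k), X ~ Hypergeom(N=n_univ, K=len(gene_set), n=len(hits))
    p = float(stats.hypergeom.sf(k - 1, n_univ, len(gene_set), len(hits)))
    a = k
    b = len(hits) - k
    c = len(gene_set) - k
    d = n_univ - len(hits) - len(gene_set) + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    return float(odds_ratio), p, k


@dataclass
class EnrichmentCurve:
    """Permutation fold-enrichment as a function of the variance-fraction cutoff."""

    cutoffs: np.ndarray
    n_passing: np.ndarray
    observed_overlap: np.ndarray
    mean_permuted_overlap: np.ndarray
    fold_enrichment: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    variable: str
    n_top: int
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "n_passing": self.n_passing,
                "observed_overlap": self.observed_overlap,
                "mean_permuted_overlap": self.mean_permuted_overlap,
                "fold_enrichment": self.fold_enrichment,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def eqtl_fold_enrichment(
    varfracs: pd.DataFrame,
    variable: str,
    top_genes: Sequence[str],
    n_top: int = 2000,
    n_cutoffs: int = 40,
    n_perm: int = 10_000,
    min_genes: int = 100,
    ci: float = 0.90,
    seed: int | None = None,
) -> EnrichmentCurve:
    """Permutation fold-enrichment of ``top_genes`` among high-variance genes.

    Parameters
    ----------
    varfracs : gene x variable table of variance fractions (genes in the index).
    variable : column whose fractions define the ranking.
    top_genes : eQTL gene list; truncated to the first ``n_top`` entries and
        intersected with the varfracs index (dropped ids produce a warning).
    n_cutoffs : number of quantile-spaced cutoffs spanning the fraction range.
    n_perm : permutations of the fraction vector across genes.
    min_genes : the curve stops at the first cutoff where <= min_genes pass.
    ci : coverage of the permutation confidence band.
    """
    if variable not in varfracs.columns:
        raise KeyError(f"variable {variable!r} not in variance fractions")
    fracs = varfracs[variable].to_numpy(dtype=float)
    genes = varfracs.index.to_numpy()
    if np.all(np.isnan(fracs)):
        raise ValueError(f"variance fractions for {variable!r} are all NA")
    keep = ~np.isnan(fracs)
    fracs, genes = fracs[keep], genes[keep]
    n_genes = fracs.size

    top_genes = list(top_genes)[:n_top]
    top_set = set(top_genes)
    dropped = top_set - set(genes)
    if dropped:
        warnings.warn(f"{len(dropped)} of {len(top_set)} top genes absent from the "
                      "variance-fraction table; they are ignored")
    is_top = np.fromiter((g in top_set for g in genes), dtype=bool, count=n_genes)
    k_top = int(is_top.sum())
    if k_top == 0:
        raise ValueError("no overlap between top_genes and the analyzed genes")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable permutation null")

    rng = np.random.default_rng(seed)
    # quantile-spaced cutoff grid over the observed fraction range
    qs = np.linspace(0.0, 1.0, n_cutoffs + 2)[1:-1]
    cutoffs = np.unique(np.quantile(fracs, qs))

    # Permuting the fraction vector across genes makes the permuted overlap at
    # a cutoff depend only on which fraction values land on top-list genes, so
    # each permutation is equivalent to sampling k_top fraction values without
    # replacement.  Overlap at cutoff c = number of sampled values > c.
    perm_vals = np.empty((n_perm, k_top))
    for i in range(n_perm):
        perm_vals[i] = fracs[rng.permutation(n_genes)[:k_top]]

    rows = []
    for cut in cutoffs:
        n_pass = int(np.sum(fracs > cut))
        if n_pass <= min_genes:
            break
        obs = int(np.sum(is_top & (fracs > cut)))
        # per-permutation overlap: sampled fraction values strictly above the cutoff
        perm_overlap = (perm_vals > cut).sum(axis=1).astype(float)
        mean_perm = float(perm_overlap.mean())
        if mean_perm == 0:
            break
        fe = obs / mean_perm
        fe_perm = perm_overlap / mean_perm
        lo = float(np.quantile(fe_perm, (1 - ci) / 2))
        hi = float(np.quantile(fe_perm, 1 - (1 - ci) / 2))
        rows.append((cut, n_pass, obs, mean_perm, fe, lo, hi))

    if not rows:
        raise ValueError("no cutoff left more than min_genes genes; nothing to report")
    arr = np.array(rows, dtype=float)
    return EnrichmentCurve(
        cutoffs=arr[:, 0],
        n_passing=arr[:, 1].astype(int),
        observed_overlap=arr[:, 2].astype(int),
        mean_permuted_overlap=arr[:, 3],
        fold_enrichment=arr[:, 4],
        ci_lower=arr[:, 5],
        ci_upper=arr[:, 6],
        variable=variable,
        n_top=n_top,
        n_perm=n_perm,
    )
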