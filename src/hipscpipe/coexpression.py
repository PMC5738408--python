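"""Weighted coexpression networks: soft-threshold adjacency, topological
overlap, module detection, and per-module gene-set enrichment.

The network is unsigned: adjacency a_ij = |cor(i, j)|^beta with beta = 9 by
default, chosen to approximate a scale-free degree distribution.  The
topological overlap matrix (TOM) augments direct adjacency with shared
neighbours,

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

where k_i is the connectivity of gene i and the sum runs over u != i, j.
Modules are branches of an average-linkage tree on the dissimilarity 1 - TOM,
cut at a fixed quantile of the merge heights; branches smaller than the
minimum module size fall into the "grey" (unassigned) module.  Module labels
follow the conventional colour order with the largest module "turquoise".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .enrichment import GeneSetCollection, hypergeom_enrich

__all__ = [
    "ModuleAssignment",
    "soft_adjacency",
    "topological_overlap",
    "detect_modules",
    "module_enrichment",
    "MODULE_COLORS",
]

# conventional WGCNA colour order; "grey" is reserved for unassigned genes
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
]


@dataclass
class ModuleAssignment:
    """Gene -> module colour labels; unassigned genes carry the 'grey' label."""

    labels: pd.Series  # index: gene ids, values: colour strings

    @property
    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def genes_in(self, module: str) -> list:
        return list(self.labels.index[self.labels == module])

    @property
    def modules(self) -> list[str]:
        """Non-grey modules ordered by decreasing size."""
        sizes = self.module_sizes.drop(index="grey", errors="ignore")
        return list(sizes.index)


def soft_adjacency(expr: pd.DataFrame, beta: float = 9) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |cor|^beta from a gene x sample matrix."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = expr.index[sd == 0][:5].tolist()
        raise ValueError(f"zero-variance genes must be filtered first (e.g. {bad})")
    cor = np.corrcoef(x)
    adj = np.abs(cor) ** beta
    np.fill_diagonal(adj, 1.0)
    adj = np.clip(adj, 0.0, 1.0)
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency matrix (diagonal set to 1)."""
    a = adj.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)  # connectivity excludes self-links
    k = a.sum(axis=1)
    shared = a @ a  # sum_u a_iu a_uj, includes u=i,j terms which are 0 off-diagonal
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 20,
    cut_height_quantile: float = 0.99,
) -> ModuleAssignment:
    """Cut the average-linkage tree on 1 - TOM into coexpression modules.

    A static cut at ``cut_height_quantile`` times the tallest merge height
    approximates dynamic branch pruning (uncorrelated genes join the tree at
    dissimilarity ~1, coherent branches well below); branches smaller than
    ``min_module_size`` genes are assigned to grey.  Genes are processed in
    stable sorted-id order so the result does not depend on input ordering.
    """
    order = np.argsort(tom.index.to_numpy().astype(str), kind="stable")
    tom = tom.iloc[order, order]
    genes = tom.index
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2, 0.0, None)
    Z = hierarchy.linkage(squareform(diss, checks=False), method="average")
    heights = Z[:, 2]
    cut = float(cut_height_quantile * heights.max())
    flat = hierarchy.fcluster(Z, t=cut, criterion="distance")

    labels = pd.Series("grey", index=genes, dtype=object)
    sizes = pd.Series(flat).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_module_size]
    # largest first; ties broken by cluster id for determinism
    kept.sort(key=lambda c: (-sizes[c], c))
    if len(kept) > len(MODULE_COLORS):
        warnings.warn(f"{len(kept)} modules exceed the colour list; extra modules "
                      "get numeric labels")
    for rank, c in enumerate(kept):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module_{rank}"
        labels.iloc[np.flatnonzero(flat == c)] = color
    if not kept:
        warnings.warn("no cluster reached the minimum module size; all genes grey")
    return ModuleAssignment(labels=labels)


def module_enrichment(
    modules: ModuleAssignment,
    sets: GeneSetCollection,
    alpha: float = 0.05,
    include_grey: bool = True,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every gene set in every module.

    The background universe is the full set of clustered genes.  The grey
    module is tested too by default — diffusely distributed signals (e.g.
    differential expression hits that do not form coherent modules) show up
    there.  Significance flags use a Bonferroni family of
    n_modules x n_sets tests.
    """
    universe = set(modules.labels.index)
    module_names = modules.modules
    if include_grey and (modules.labels == "grey").any():
        module_names = module_names + ["grey"]
    family = len(module_names) * len(sets.sets)
    rows = []
    for mod in module_names:
        mod_genes = set(modules.genes_in(mod))
        for set_name, gene_set in sets.sets.items():
            odds, p, k = hypergeom_enrich(mod_genes, gene_set, universe)
            rows.append({
                "module": mod,
                "set": set_name,
                "module_size": len(mod_genes),
                "set_size": len(gene_set & universe),
                "overlap": k,
                "odds_ratio": odds,
                "p_value": p,
                "significant": bool(family > 0 and p < alpha / family),
            })
    return pd.DataFrame(rows)
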