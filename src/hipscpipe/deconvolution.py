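"""Reference-based cell-type-composition (CTC) scoring and correction.

Bulk expression of a heterogeneous culture is modeled as a nonnegative
combination of reference profiles (e.g. single-cell derived neuron, myocyte,
fibroblast, hiPSC signatures).  Per sample, the linear-scale expression over
the panel's marker genes — each gene standardized by the panel's per-gene
mean and standard deviation across profiles — is regressed on the
standardized signatures by nonnegative least squares.  Coefficients of
profiles mapping to the same cell type are summed and the result is
renormalized to sum to one.  The absolute scale of such scores is not
biologically meaningful (the reference panel is incomplete and cross-species)
so they are treated as *composition scores* and used only comparatively:
as covariates, in residualization, and in correlation screens against
principal components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

__all__ = [
    "SignaturePanel",
    "ctc_scores",
    "residualize",
    "score_pc_screen",
    "principal_components",
]


@dataclass
class SignaturePanel:
    """Gene x reference-profile expression (linear scale) plus profile -> cell type map."""

    profiles: pd.DataFrame  # genes x profiles, linear scale, nonnegative
    cell_type_map: dict[str, str]  # profile name -> cell type

    def __post_init__(self) -> None:
        if (self.profiles.to_numpy() < 0).any():
            raise ValueError("signature profiles must be nonnegative")
        unmapped = set(self.profiles.columns) - set(self.cell_type_map)
        if unmapped:
            raise ValueError(f"profiles without a cell-type mapping: {sorted(unmapped)}")

    @property
    def cell_types(self) -> list[str]:
        seen: list[str] = []
        for p in self.profiles.columns:
            ct = self.cell_type_map[p]
            if ct not in seen:
                seen.append(ct)
        return seen

    def marker_genes(self, n_per_profile: int = 50) -> list:
        """Top marker genes per profile by fold over the mean of the others."""
        x = self.profiles.to_numpy(dtype=float) + 1e-8
        k = x.shape[1]
        markers: list = []
        for j in range(k):
            others = (x.sum(axis=1) - x[:, j]) / max(k - 1, 1)
            fold = x[:, j] / (others + 1e-8)
            top = np.argsort(-fold, kind="stable")[:n_per_profile]
            markers.extend(self.profiles.index[top])
        return sorted(set(markers), key=str)


def ctc_scores(
    expr: pd.DataFrame,
    panel: SignaturePanel,
    marker_genes: Sequence | None = None,
    n_markers_per_profile: int = 50,
    linear_scale: bool = False,
) -> pd.DataFrame:
    """Cell-type composition scores per sample (rows sum to 1).

    Parameters
    ----------
    expr : gene x sample matrix; log2 values by default (converted to linear
        scale internally), or pass ``linear_scale=True`` for linear input.
    panel : reference signatures.
    marker_genes : genes to fit on; defaults to the panel's top markers.

    Each sample's linear expression over the marker genes is standardized
    gene-wise by the panel's per-gene mean and sd across profiles and fit by
    nonnegative least squares against the standardized signatures.  A free
    (sign-unconstrained) column carrying the per-gene mean term is included
    so the fit is exact for any positive rescaling of the sample: pure
    profiles recover a unit score and noise-free mixtures recover their
    weights exactly, and the normalized scores are invariant to multiplying
    a sample by a constant.  Coefficients are summed within cell type and
    normalized to sum 1.
    """
    if marker_genes is None:
        marker_genes = panel.marker_genes(n_markers_per_profile)
    shared = [g for g in marker_genes if g in expr.index and g in panel.profiles.index]
    if not shared:
        raise ValueError("no genes shared between expression matrix and panel")
    if len(shared) < 100:
        warnings.warn(f"only {len(shared)} shared signature genes; scores may be noisy")

    S = panel.profiles.loc[shared].to_numpy(dtype=float)
    mu = S.mean(axis=1, keepdims=True)
    sd = S.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    S_std = (S - mu) / sd

    X = expr.loc[shared].to_numpy(dtype=float)
    if not linear_scale:
        X = np.power(2.0, X)
    totals = X.sum(axis=0)
    if (totals <= 0).any():
        bad = expr.columns[totals <= 0].tolist()
        raise ValueError(f"all-zero samples over the signature genes: {bad}")
    X_std = (X - mu) / sd

    # free mean-term column (+/- pair emulates an unconstrained coefficient
    # inside the nonnegative solver); absorbs the sample's overall scale
    v = (mu / sd).ravel()
    design = np.column_stack([S_std, v, -v])

    cell_types = panel.cell_types
    prof_ct = [panel.cell_type_map[p] for p in panel.profiles.columns]
    n_prof = S.shape[1]
    rows = []
    for j in range(X_std.shape[1]):
        coef, _ = nnls(design, X_std[:, j])
        by_ct = {ct: 0.0 for ct in cell_types}
        for c, ct in zip(coef[:n_prof], prof_ct):
            by_ct[ct] += float(c)
        total = sum(by_ct.values())
        if total <= 0:
            # fit entirely at the boundary: fall back to uniform scores
            by_ct = {ct: 1.0 / len(cell_types) for ct in cell_types}
        else:
            by_ct = {ct: v / total for ct, v in by_ct.items()}
        rows.append(by_ct)
    return pd.DataFrame(rows, index=expr.columns, columns=cell_types)


def residualize(
    expr: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Residuals of every gene on an intercept plus the given covariates (OLS).

    Residuals are orthogonal to each covariate.  A rank-deficient design
    raises with the names of the collinear columns.
    """
    cov = covariates.loc[expr.columns]
    X = np.column_stack([np.ones(len(cov)), cov.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns that add no rank
        bad = []
        base = np.ones((len(cov), 1))
        for name in cov.columns:
            cand = np.column_stack([base, cov[name].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad.append(name)
            else:
                base = cand
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    Y = expr.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T
    return pd.DataFrame(resid, index=expr.index, columns=expr.columns)


def principal_components(expr: pd.DataFrame, n_pcs: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the first PCs of a gene x sample matrix.

    Genes are centered but not scaled.  Returns (scores, explained variance
    fractions).
    """
    x = expr.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    n = x.shape[1]
    if n_pcs > n:
        raise ValueError(f"requested {n_pcs} PCs from {n} samples")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s ** 2
    frac = var / var.sum()
    scores = pd.DataFrame(
        vt[:n_pcs].T * s[:n_pcs],
        index=expr.columns,
        columns=[f"PC{i+1}" for i in range(n_pcs)],
    )
    return scores, frac[:n_pcs]


def score_pc_screen(
    scores: pd.DataFrame,
    expr_matrices: Mapping[str, pd.DataFrame],
    n_pcs: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate every CTC score with the top PCs of each expression matrix.

    The Bonferroni family size is n_scores x n_pcs x n_matrices; rows carry
    the correlation, two-sided p, and a significance flag at
    alpha / family_size.
    """
    family = scores.shape[1] * n_pcs * len(expr_matrices)
    rows = []
    for mat_name, expr in expr_matrices.items():
        common = [s for s in expr.columns if s in scores.index]
        if len(common) <= n_pcs:
            raise ValueError(f"matrix {mat_name!r}: fewer samples than PCs requested")
        pcs, _ = principal_components(expr[common], n_pcs)
        for score_name in scores.columns:
            sc = scores.loc[common, score_name].to_numpy(dtype=float)
            for pc_name in pcs.columns:
                r, p = stats.pearsonr(sc, pcs[pc_name].to_numpy())
                rows.append({
                    "matrix": mat_name,
                    "score": score_name,
                    "pc": pc_name,
                    "r": float(r),
                    "p_value": float(p),
                    "n_tests": family,
                    "significant": bool(p < alpha / family),
                })
    return pd.DataFrame(rows)
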