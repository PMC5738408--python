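"""Per-gene decomposition of expression variance into fractions attributable
to experimental variables.

Each gene's expression y is fit with a linear mixed model in which
categorical variables (cell type, donor, diagnosis, sex, ...) enter as
random effects with their own variance components and continuous variables
(cell-type-composition scores, ...) enter as fixed-effect slopes:

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, s2_k I),  e ~ N(0, s2_e I)

Variance components are estimated by restricted maximum likelihood (REML)
with the residual variance profiled out, optimizing over the nonnegative
variance ratios.  The fraction attributed to a random effect is
s2_k / total; a fixed effect contributes the empirical variance of its
fitted term X_k beta_k across samples; the residual fraction is s2_e / total,
where total is the sum of all components.  Fractions are in [0, 1] and sum
to 1 per gene.

For a balanced one-way design with a single random effect the REML estimate
coincides with the classical ANOVA intraclass-correlation estimator
truncated at zero, which serves as an independent oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VarPartFormula",
    "partition_gene",
    "partition_matrix",
    "compare_partitions",
    "anova_icc",
]


@dataclass
class VarPartFormula:
    """Which metadata columns enter as random (categorical) vs fixed (continuous)."""

    random_effects: list[str]
    fixed_effects: list[str] = field(default_factory=list)


def _design_matrices(
    metadata: pd.DataFrame, formula: VarPartFormula, samples: pd.Index
) -> tuple[np.ndarray, list[np.ndarray], list[str], list[str]]:
    md = metadata.loc[samples]
    Zs, z_names = [], []
    for var in formula.random_effects:
        if var not in md.columns:
            raise KeyError(f"random effect {var!r} not in metadata")
        dummies = pd.get_dummies(md[var].astype(str))
        if dummies.shape[1] < 2:
            raise ValueError(f"random effect {var!r} has fewer than 2 levels")
        Zs.append(dummies.to_numpy(dtype=float))
        z_names.append(var)
    X_cols = [np.ones(len(md))]
    x_names = ["intercept"]
    for var in formula.fixed_effects:
        if var not in md.columns:
            raise KeyError(f"fixed effect {var!r} not in metadata")
        X_cols.append(md[var].to_numpy(dtype=float))
        x_names.append(var)
    X = np.column_stack(X_cols)
    n = X.shape[0]
    if n <= X.shape[1] + 2:
        raise ValueError("too few samples for the number of fixed effects")
    return X, Zs, z_names, x_names


def _reml_neg2loglik(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                     Gs: list[np.ndarray]) -> float:
    """Profiled REML -2 log likelihood (up to a constant) at log variance ratios."""
    n, p = X.shape
    V0 = np.eye(n)
    for t, G in zip(theta, Gs):
        V0 = V0 + np.exp(t) * G
    try:
        L = np.linalg.cholesky(V0)
    except np.linalg.LinAlgError:
        return 1e30
    logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_X = np.linalg.solve(V0, X)
    Vi_y = np.linalg.solve(V0, y)
    XtViX = X.T @ Vi_X
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e30
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    yPy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    if yPy <= 0:
        return 1e30
    return (n - p) * np.log(yPy) + logdet_V + logdet_XtViX


def _mom_start(y: np.ndarray, X: np.ndarray, Zs: list[np.ndarray]) -> np.ndarray:
    """Method-of-moments starting values for the log variance ratios."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    s2 = max(float(np.var(r, ddof=X.shape[1])), 1e-12)
    theta = []
    for Z in Zs:
        counts = Z.sum(axis=0)
        means = (Z.T @ r) / np.maximum(counts, 1)
        between = float(np.average(means ** 2, weights=counts))
        kbar = float(counts.mean())
        ratio = max((between - s2 / max(kbar, 1.0)) / s2, 1e-4)
        theta.append(np.log(ratio))
    return np.asarray(theta)


def partition_gene(
    y: np.ndarray | pd.Series,
    metadata: pd.DataFrame,
    formula: VarPartFormula,
    samples: pd.Index | None = None,
) -> dict:
    """Variance fractions of one gene; see the module docstring for the model.

    Returns a dict with one fraction per variable plus ``residual``; on
    failure returns NaNs with a ``fit_error`` message.
    """
    if isinstance(y, pd.Series):
        samples = y.index if samples is None else samples
        y = y.to_numpy(dtype=float)
    if samples is None:
        samples = metadata.index
    y = np.asarray(y, dtype=float)
    X, Zs, z_names, x_names = _design_matrices(metadata, formula, samples)
    names = z_names + x_names[1:] + ["residual"]

    tot_var = float(np.var(y))
    if tot_var < 1e-12:
        return {**{k: np.nan for k in names}, "fit_error": "zero variance"}

    Gs = [Z @ Z.T for Z in Zs]
    bounds = [(-18.0, 12.0)] * len(Gs)
    starts = [np.full(len(Gs), np.log(0.1)), _mom_start(y, X, Zs)]
    best = None
    for th0 in starts:
        th0 = np.clip(th0, -18.0, 12.0)
        res = optimize.minimize(
            _reml_neg2loglik, th0, args=(y, X, Gs), method="L-BFGS-B",
            bounds=bounds, options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e29:
        return {**{k: np.nan for k in names}, "fit_error": "REML did not converge"}

    gamma = np.exp(best.x)
    n, p = X.shape
    V0 = np.eye(n)
    for g_k, G in zip(gamma, Gs):
        V0 = V0 + g_k * G
    Vi_X = np.linalg.solve(V0, X)
    Vi_y = np.linalg.solve(V0, y)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    yPy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    s2_e = yPy / (n - p)
    s2_random = gamma * s2_e

    fixed_var = []
    for j, name in enumerate(x_names):
        if name == "intercept":
            continue
        contrib = X[:, j] * beta[j]
        fixed_var.append(float(np.var(contrib)))

    comps = list(s2_random) + fixed_var + [s2_e]
    total = float(np.sum(comps))
    fracs = [c / total for c in comps]
    out = dict(zip(names, fracs))
    out["fit_error"] = ""
    return out


def partition_matrix(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    formula: VarPartFormula,
) -> tuple[pd.DataFrame, pd.Series]:
    """Variance fractions for every gene plus the per-variable medians.

    Genes with (numerically) zero total variance are skipped and reported as
    NA rows; the medians ignore NAs.
    """
    rows = {}
    for gene in expr.index:
        rows[gene] = partition_gene(expr.loc[gene], metadata, formula,
                                    samples=expr.columns)
    table = pd.DataFrame.from_dict(rows, orient="index")
    n_failed = int((table["fit_error"] != "").sum())
    if n_failed:
        warnings.warn(f"{n_failed} genes skipped or failed during variance partitioning")
    fracs = table.drop(columns=["fit_error"])
    medians = fracs.median(skipna=True)
    return table, medians


def compare_partitions(
    fracs_a: pd.DataFrame,
    fracs_b: pd.DataFrame,
    variable: str = "donor",
) -> dict:
    """Paired one-sided Wilcoxon signed-rank test of variable fractions (b > a)."""
    shared = fracs_a.index.intersection(fracs_b.index)
    a = fracs_a.loc[shared, variable].astype(float)
    b = fracs_b.loc[shared, variable].astype(float)
    ok = a.notna() & b.notna()
    a, b = a[ok], b[ok]
    if len(a) < 10:
        raise ValueError(f"only {len(a)} paired genes; need at least 10")
    diff = b - a
    if np.allclose(diff, 0):
        return {"p_value": 0.5, "median_difference": 0.0, "n_genes": int(len(a))}
    res = stats.wilcoxon(b, a, alternative="greater", zero_method="wilcox")
    return {
        "p_value": float(res.pvalue),
        "median_difference": float(np.median(diff)),
        "n_genes": int(len(a)),
    }


def anova_icc(y: np.ndarray, groups: np.ndarray) -> float:
    """Balanced one-way ANOVA method-of-moments ICC, truncated at 0.

    Independent closed-form oracle for the single-random-effect model:
    ICC = (MSB - MSW) / (MSB + (k - 1) MSW) with k the common group size.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    levels, inv = np.unique(groups, return_inverse=True)
    sizes = np.bincount(inv)
    if len(set(sizes)) != 1:
        raise ValueError("anova_icc requires a balanced design")
    k = int(sizes[0])
    m = len(levels)
    means = np.array([y[inv == i].mean() for i in range(m)])
    grand = y.mean()
    msb = k * np.sum((means - grand) ** 2) / (m - 1)
    msw = sum(np.sum((y[inv == i] - means[i]) ** 2) for i in range(m)) / (m * (k - 1))
    icc = (msb - msw) / (msb + (k - 1) * msw)
    return float(max(icc, 0.0))
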