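"""Count filtering, TMM/CPM normalization, expression-based sex inference,
and z-scoring of genes inside CNV regions.

All downstream analyses work on log2 counts per million (CPM) after
trimmed-mean-of-M-values (TMM) normalization.  TMM estimates a per-sample
scaling factor as a weighted, doubly trimmed mean of gene-wise log2 ratios
(M-values) against a reference sample, which corrects for compositional
differences that raw library-size scaling cannot.

Sex is inferred from the expression of XIST (chrX) and a panel of chrY genes:
female samples show high XIST and silent chrY, males the reverse, and samples
matching neither pattern (contamination or aberrant X-inactivation) are
called intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "NormalizedMatrix",
    "SexCall",
    "filter_genes",
    "tmm_normalize",
    "log2_cpm",
    "infer_sex",
    "cnv_zscores",
]


@dataclass
class NormalizedMatrix:
    """log2-CPM matrix with the TMM factors and library sizes that produced it."""

    log2_cpm: pd.DataFrame  # genes x samples
    tmm_factors: pd.Series  # per sample, geometric mean 1
    library_sizes: pd.Series  # per sample, raw totals

    @property
    def samples(self) -> pd.Index:
        return self.log2_cpm.columns

    @property
    def genes(self) -> pd.Index:
        return self.log2_cpm.index


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    libsize = counts.sum(axis=0)
    zero = libsize.index[libsize == 0].tolist()
    if zero:
        raise ValueError(f"samples with zero library size: {zero}")


def filter_genes(counts: pd.DataFrame, min_cpm: float = 1.0, min_frac: float = 0.30) -> list:
    """Genes expressed above ``min_cpm`` in at least ``min_frac`` of samples.

    CPM here uses raw library sizes (pre-TMM).  A gene is retained iff its
    CPM exceeds ``min_cpm`` in at least ``ceil(min_frac * n_samples)``
    samples; a count exactly at the threshold fraction is retained ("at
    least").  Gene order is preserved.
    """
    _check_counts(counts)
    libsize = counts.sum(axis=0)
    cpm = counts.div(libsize, axis=1) * 1e6
    n_needed = int(np.ceil(min_frac * counts.shape[1]))
    ok = (cpm > min_cpm).sum(axis=1) >= n_needed
    return counts.index[ok].tolist()


def _tmm_factor_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_logratio: float,
    trim_abs: float,
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**f)."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        warnings.warn("no genes shared with the reference after removing zeros; factor 1")
        return 1.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) variance of M, used as inverse-variance weight
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)

    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0:
        warnings.warn("all genes trimmed in TMM; factor set to 1")
        return 1.0
    # double trim: drop the most extreme M-values and A-values
    m_lo, m_hi = np.quantile(m, [trim_logratio, 1 - trim_logratio])
    a_lo, a_hi = np.quantile(a, [trim_abs, 1 - trim_abs])
    keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
    if not keep.any():
        warnings.warn("all genes trimmed in TMM; factor set to 1")
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f)


def tmm_normalize(
    counts: pd.DataFrame,
    trim_logratio: float = 0.30,
    trim_abs: float = 0.05,
    prior_count: float = 0.5,
    ref_sample: str | None = None,
) -> NormalizedMatrix:
    """TMM scaling factors plus log2-CPM with a prior count.

    The reference sample is the one whose 75th count percentile (library-size
    scaled) is closest to the mean across samples, unless given explicitly.
    Factors are rescaled to geometric mean 1; effective library size =
    raw library size x factor; log2-CPM uses ``prior_count`` to avoid log 0.
    """
    _check_counts(counts)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    x = counts.to_numpy(dtype=float)
    libsize = x.sum(axis=0)
    if ref_sample is None:
        q75 = np.quantile(x / libsize, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_sample)

    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        factors[j] = _tmm_factor_pair(
            x[:, j], x[:, ref_idx], libsize[j], libsize[ref_idx],
            trim_logratio, trim_abs,
        )
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1

    eff_lib = libsize * factors
    # prior count scaled per sample as in standard cpm(log=TRUE) practice
    prior = prior_count * eff_lib / eff_lib.mean()
    logcpm = np.log2((x + prior[None, :]) / (eff_lib + 2 * prior)[None, :] * 1e6)
    return NormalizedMatrix(
        log2_cpm=pd.DataFrame(logcpm, index=counts.index, columns=counts.columns),
        tmm_factors=pd.Series(factors, index=counts.columns, name="tmm_factor"),
        library_sizes=pd.Series(libsize, index=counts.columns, name="library_size"),
    )


def log2_cpm(counts: pd.DataFrame, prior_count: float = 0.5) -> pd.DataFrame:
    """Plain library-size log2-CPM (no TMM), mainly for quick looks."""
    _check_counts(counts)
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    x = counts.to_numpy(dtype=float)
    return pd.DataFrame(
        np.log2((x + prior_count) / (lib + 2 * prior_count)[None, :] * 1e6),
        index=counts.index, columns=counts.columns,
    )


@dataclass
class SexCall:
    sample: str
    call: str  # male / female / intermediate
    xist_log2cpm: float
    chry_mean_log2cpm: float
    annotated_sex: str | None = None
    mismatch: bool | None = None


def infer_sex(
    norm: NormalizedMatrix,
    xist_id: str,
    chry_ids: Sequence[str],
    annotated_sex: pd.Series | None = None,
    xist_female_min: float = 2.0,
    xist_male_max: float = 1.0,
    chry_male_min: float = 2.0,
    chry_female_max: float = 1.0,
) -> list[SexCall]:
    """Call sample sex from XIST and mean chrY expression (log2-CPM units).

    female: XIST >= xist_female_min and chrY mean < chry_female_max;
    male: XIST < xist_male_max and chrY mean >= chry_male_min;
    anything else: intermediate.  If ``annotated_sex`` is given, samples whose
    call (male/female only) contradicts the annotation are flagged.
    """
    missing = [g for g in [xist_id, *chry_ids] if g not in norm.log2_cpm.index]
    if missing:
        raise KeyError(f"sex genes missing from the matrix: {missing}")
    xist = norm.log2_cpm.loc[xist_id]
    chry = norm.log2_cpm.loc[list(chry_ids)].mean(axis=0)
    calls = []
    for s in norm.samples:
        x, y = float(xist[s]), float(chry[s])
        if x >= xist_female_min and y < chry_female_max:
            call = "female"
        elif x < xist_male_max and y >= chry_male_min:
            call = "male"
        else:
            call = "intermediate"
        ann = None if annotated_sex is None else str(annotated_sex.get(s))
        mism = None
        if ann is not None:
            mism = call in ("male", "female") and call != ann
        calls.append(SexCall(sample=s, call=call, xist_log2cpm=x,
                             chry_mean_log2cpm=y, annotated_sex=ann, mismatch=mism))
    return calls


def cnv_zscores(
    norm: NormalizedMatrix,
    metadata: pd.DataFrame,
    regions: pd.DataFrame,
    gene_coords: pd.DataFrame,
    cell_type_col: str = "cell_type",
) -> pd.DataFrame:
    """Per-(gene, sample) expression z-scores restricted to CNV-region genes.

    log2-CPM is residualized on cell type (one-way linear model) and each
    gene's residuals are z-scored across samples.  ``regions`` is BED-style
    (chrom, start, end, [name]) with 0-based half-open intervals;
    ``gene_coords`` has columns chrom/start/end (1-based inclusive) indexed by
    gene id.  A gene overlaps a region iff the intervals intersect after
    converting gene coordinates to the BED convention.

    Zero-variance genes get z = 0 with ``flat_gene = True`` instead of NaN.
    """
    req = {"chrom", "start", "end"}
    if not req <= set(regions.columns) or not req <= set(gene_coords.columns):
        raise ValueError("regions and gene_coords need chrom/start/end columns")

    # 1-based inclusive -> 0-based half-open
    g_start = gene_coords["start"].to_numpy(dtype=np.int64) - 1
    g_end = gene_coords["end"].to_numpy(dtype=np.int64)
    g_chrom = gene_coords["chrom"].astype(str).to_numpy()

    hit_rows = []
    for _, reg in regions.iterrows():
        same = g_chrom == str(reg["chrom"])
        overlap = same & (g_start < int(reg["end"])) & (g_end > int(reg["start"]))
        name = reg.get("name", f"{reg['chrom']}:{reg['start']}-{reg['end']}")
        for g in gene_coords.index[overlap]:
            if g in norm.genes:
                hit_rows.append((g, name))
    if not hit_rows:
        return pd.DataFrame(columns=["gene_id", "region", "sample", "z", "flat_gene"])

    # residualize on cell type across all genes we need
    genes = sorted({g for g, _ in hit_rows})
    y = norm.log2_cpm.loc[genes].to_numpy(dtype=float)
    ct = pd.get_dummies(metadata.loc[norm.samples, cell_type_col]).to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(ct, y.T, rcond=None)
    resid = y - (ct @ beta).T
    mu = resid.mean(axis=1, keepdims=True)
    sd = resid.std(axis=1, ddof=1, keepdims=True)
    flat = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd[flat, 0] = 1.0
    z = (resid - mu) / sd
    z[flat, :] = 0.0
    zdf = pd.DataFrame(z, index=genes, columns=norm.samples)
    flat_map = dict(zip(genes, flat))

    out = []
    for g, region in hit_rows:
        for s in norm.samples:
            out.append((g, region, s, float(zdf.at[g, s]), bool(flat_map[g])))
    return pd.DataFrame(out, columns=["gene_id", "region", "sample", "z", "flat_gene"])
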