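"""Synthetic case/control hiPSC-derived RNA-seq cohorts with known ground truth.

The generator emulates the structure of a repeated-measures case/control
cohort: ~11 case and ~11 control donors, one to three hiPSC lines per donor,
each line profiled as both an NPC and a neuron culture (~88-94 samples).
Each sample is a mixture of reference cell-type signatures drawn from a
Dirichlet distribution (differentiation heterogeneity), on top of per-gene
donor random effects, diagnosis shifts on a subset of genes, sex-chromosome
signatures (XIST / chrY panel), optional CNV dosage changes and residual
Sendai-virus expression, with negative-binomial counts.

Calibration.  On the log2 scale the donor effect standard deviation is
calibrated against a fixed residual noise budget sigma_res (default 0.5):
sigma_d^2 = icc * sigma_res^2 / (1 - icc), so that a gene's donor variance
fraction equals ``icc_donor`` in expectation when no other component varies.
The residual budget *includes* the counting noise: the Gaussian noise added
per observation has variance max(sigma_res^2 - v_NB, 0) where
v_NB = (1/mu + phi) / ln(2)^2 is the delta-method log2-scale variance of a
negative-binomial count with mean mu and dispersion phi (Var = mu + phi*mu^2).

All randomness flows from one generator stream in a fixed, documented order
(signature, gene annotation, effect sizes, donor attributes, library sizes,
mixing proportions, donor effects, residual noise, Sendai, counts), so a
seed fully determines the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import math

import numpy as np
import pandas as pd

from .deconvolution import SignaturePanel

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_signature_panel",
    "simulate_cohort",
    "simulate_paired_cohorts",
    "DEFAULT_SEX_GENES",
]

LN2_SQ = math.log(2.0) ** 2

# XIST plus the six-gene chrY panel used for expression-based sex inference
DEFAULT_SEX_GENES = {
    "xist": "XIST",
    "chry": ["USP9Y", "UTY", "NLGN4Y", "ZFY", "RPS4Y1", "TXLNG2P"],
}

# 12 reference profiles collapsing to 11 cell types (two neuron sources)
_DEFAULT_PROFILES = [
    ("brain_neuron", "Neuron"),
    ("culture_neuron", "Neuron"),
    ("astrocyte", "Astrocyte"),
    ("opc", "OPC"),
    ("oligo_newly_formed", "NewOligo"),
    ("oligo_myelinating", "MyelOligo"),
    ("microglia", "Microglia"),
    ("endothelial", "Endothelial"),
    ("myocyte", "Myocyte"),
    ("fibroblast_1", "fibroblast_1"),
    ("fibroblast_2", "fibroblast_2"),
    ("hipsc", "hiPSC"),
]

# Dirichlet concentrations per culture cell type over the 12 profiles:
# NPCs carry a strong stemness (hiPSC) signal, neurons a stronger neuron and
# fibroblast_1 signal, with low-level glial/other contamination everywhere.
_DEFAULT_MIXING = {
    "NPC": [1.5, 1.5, 0.5, 0.5, 0.3, 0.3, 0.3, 0.3, 0.5, 1.5, 1.5, 6.0],
    "neuron": [4.0, 4.0, 1.0, 0.5, 0.3, 0.3, 0.3, 0.3, 0.5, 3.0, 1.5, 1.5],
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults mirror the emulated study."""

    n_genes: int = 4000
    n_donors_case: int = 11
    n_donors_control: int = 11
    lines_per_donor: int | Sequence[int] = 2
    cell_types: Sequence[str] = ("NPC", "neuron")
    icc_donor: float = 0.022  # median donor variance fraction of the emulated study
    frac_de_genes: float = 0.10
    lfc_sd: float = 0.30
    signature: SignaturePanel | None = None
    mixing_concentration: dict[str, Sequence[float]] | None = None
    libsize_log_mean: float = math.log(2.0e7)
    libsize_log_sd: float = 0.35
    nb_dispersion: float | np.ndarray = 0.1
    sigma_res: float = 0.5  # log2-scale residual noise budget (incl. counting noise)
    frac_eqtl_genes: float = 0.10
    eqtl_icc: float | None = None  # donor ICC of eQTL genes; default min(3*icc, 0.75)
    sex_genes: dict = field(default_factory=lambda: dict(DEFAULT_SEX_GENES))
    cnv_events: list = field(default_factory=list)  # (donor, (chrom,start,end), dosage)
    sendai_donors: Sequence[str] = ()
    n_intermediate_sex: int = 0
    mixture_floor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.icc_donor < 1.0):
            raise ValueError("icc_donor must be in [0, 1)")
        if not (0.0 <= self.frac_de_genes <= 1.0):
            raise ValueError("frac_de_genes must be in [0, 1]")
        for name in ("n_genes", "n_donors_case", "n_donors_control"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.mixing_concentration is not None:
            for ct, alpha in self.mixing_concentration.items():
                if np.any(np.asarray(alpha, dtype=float) <= 0):
                    raise ValueError(f"Dirichlet parameters for {ct!r} must be > 0")


@dataclass
class GroundTruth:
    """The generative quantities downstream stages try to recover."""

    log2fc: pd.Series  # per-gene true diagnosis effect
    de_indicator: pd.Series
    eqtl_indicator: pd.Series
    mixing: pd.DataFrame  # sample x cell type true proportions (sum to 1)
    variance_fractions: pd.DataFrame  # per-gene approximate true fractions
    donor_sd: pd.Series  # per-gene donor effect sd (log2)


def cohort_gene_names(n_genes: int, sex_genes: dict | None = None) -> list[str]:
    """The gene identifiers a cohort of ``n_genes`` genes will carry.

    Useful for building a shared signature panel to pass to several cohorts.
    """
    sex = sex_genes or DEFAULT_SEX_GENES
    special = [sex["xist"], *sex["chry"]]
    n_reg = n_genes - len(special)
    if n_reg < 1:
        raise ValueError("n_genes must exceed the number of sex signature genes")
    return [f"G{i+1:05d}" for i in range(n_reg)] + special


def make_signature_panel(
    genes: Sequence[str],
    rng: np.random.Generator,
    marker_frac: float = 0.25,
    marker_boost: float = 4.0,
    baseline_mean: float = 5.0,
    baseline_sd: float = 1.5,
) -> SignaturePanel:
    """A synthetic reference panel over the given genes.

    Each gene gets a log2 baseline; a fraction of genes are markers of one
    cell type (boosted in that cell type's profiles); profiles of the same
    cell type differ by small independent jitter, mirroring the use of
    multiple noisy representatives per reference cell type.
    """
    genes = list(genes)
    n = len(genes)
    profiles = [p for p, _ in _DEFAULT_PROFILES]
    cell_map = dict(_DEFAULT_PROFILES)
    cell_types = list(dict.fromkeys(cell_map.values()))

    baseline = rng.normal(baseline_mean, baseline_sd, size=n)
    ct_effect = np.zeros((n, len(cell_types)))
    n_markers = int(marker_frac * n)
    marker_idx = rng.choice(n, size=n_markers, replace=False)
    marker_ct = rng.integers(0, len(cell_types), size=n_markers)
    ct_effect[marker_idx, marker_ct] = marker_boost * (0.5 + rng.random(n_markers))
    # mild unstructured cell-type wobble on every gene
    ct_effect += rng.normal(0.0, 0.4, size=ct_effect.shape)

    log2_prof = np.empty((n, len(profiles)))
    for j, prof in enumerate(profiles):
        ct_j = cell_types.index(cell_map[prof])
        log2_prof[:, j] = baseline + ct_effect[:, ct_j] + rng.normal(0, 0.25, size=n)
    return SignaturePanel(
        profiles=pd.DataFrame(np.power(2.0, log2_prof), index=genes, columns=profiles),
        cell_type_map=cell_map,
    )


def _gene_coords(genes: Sequence[str], sex_genes: dict) -> pd.DataFrame:
    """Deterministic toy gene annotation: genes laid out on chr1..22, 10 kb apart.

    Sex genes are placed on chrX / chrY so CNV regions and sex signatures can
    reference real-looking coordinates (1-based inclusive).
    """
    chroms, starts, ends = [], [], []
    autosomes = [f"chr{i}" for i in range(1, 23)]
    per_chrom = int(np.ceil(len(genes) / len(autosomes)))
    for i, g in enumerate(genes):
        if g == sex_genes["xist"]:
            chroms.append("chrX"); starts.append(73_040_486); ends.append(73_072_588)
            continue
        if g in sex_genes["chry"]:
            k = sex_genes["chry"].index(g)
            chroms.append("chrY")
            starts.append(2_650_000 + k * 1_000_000)
            ends.append(2_700_000 + k * 1_000_000)
            continue
        c = i // per_chrom
        pos = (i % per_chrom) * 10_000 + 1
        chroms.append(autosomes[min(c, len(autosomes) - 1)])
        starts.append(pos)
        ends.append(pos + 5_000)
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends},
                        index=list(genes))


def _build_samples(config: SimulationConfig) -> pd.DataFrame:
    donors = [f"case{i+1:02d}" for i in range(config.n_donors_case)] + \
             [f"ctrl{i+1:02d}" for i in range(config.n_donors_control)]
    diagnosis = ["case"] * config.n_donors_case + ["control"] * config.n_donors_control
    if np.isscalar(config.lines_per_donor):
        lines = [int(config.lines_per_donor)] * len(donors)
    else:
        lines = [int(k) for k in config.lines_per_donor]
        if len(lines) != len(donors):
            raise ValueError("per-donor lines list must match the number of donors")
    rows = []
    for d, dx, k in zip(donors, diagnosis, lines):
        for line in range(1, k + 1):
            for ct in config.cell_types:
                rows.append({
                    "sample_id": f"{d}_L{line}_{ct}",
                    "donor": d,
                    "line": f"{d}_L{line}",
                    "cell_type": ct,
                    "diagnosis": dx,
                })
    md = pd.DataFrame(rows).set_index("sample_id")
    md["batch"] = [f"batch{(i % 3) + 1}" for i in range(len(md))]
    return md


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate counts, metadata and ground truth for one cohort.

    Returns ``(counts, metadata, truth)``: an integer gene x sample count
    matrix, a per-sample metadata table (donor, line, cell type, diagnosis,
    sex, batch, sendai score), and the :class:`GroundTruth` channel.
    Deterministic given ``config.seed``.  ``metadata.attrs['gene_coords']``
    carries the toy gene annotation used for CNV placement.
    """
    rng = np.random.default_rng(config.seed)
    sex = dict(config.sex_genes)
    genes = cohort_gene_names(config.n_genes, sex)
    n_reg = config.n_genes - 1 - len(sex["chry"])

    # 1. signature
    if config.signature is None:
        panel = make_signature_panel(genes, rng)
    else:
        panel = config.signature
        missing = [g for g in genes if g not in panel.profiles.index]
        if missing:
            raise ValueError(
                f"signature panel lacks {len(missing)} of the simulated genes "
                f"(e.g. {missing[:3]}); gene sets are inconsistent with n_genes")
    sig = panel.profiles.loc[genes].to_numpy(dtype=float)  # linear scale
    profiles = list(panel.profiles.columns)

    coords = _gene_coords(genes, sex)
    md = _build_samples(config)
    samples = md.index
    n_g, n_s = len(genes), len(samples)
    donors = md["donor"].unique().tolist()

    # 2. per-gene effects: DE genes, eQTL genes, donor sds
    n_de = int(round(config.frac_de_genes * n_reg))
    de_idx = rng.choice(n_reg, size=n_de, replace=False)
    log2fc = np.zeros(n_g)
    log2fc[de_idx] = rng.normal(0.0, config.lfc_sd, size=n_de)

    n_eqtl = int(round(config.frac_eqtl_genes * n_reg))
    eqtl_idx = rng.choice(n_reg, size=n_eqtl, replace=False)
    icc = np.full(n_g, config.icc_donor)
    icc_eqtl = config.eqtl_icc
    if icc_eqtl is None:
        icc_eqtl = min(3.0 * config.icc_donor, 0.75) if config.icc_donor > 0 else 0.0
    icc[eqtl_idx] = icc_eqtl
    s_res = config.sigma_res
    donor_sd = np.sqrt(icc * s_res ** 2 / (1.0 - icc))

    # 3. donor sex (balanced alternating within group, deterministic)
    donor_sex = {d: ("female" if i % 2 == 0 else "male") for i, d in enumerate(donors)}
    md["sex"] = md["donor"].map(donor_sex)
    sex_frac = np.ones(n_s)  # 1 = fully own sex; 0.5 = 50/50 intermediate mix
    if config.n_intermediate_sex > 0:
        females = np.flatnonzero((md["sex"] == "female").to_numpy())
        pick = rng.choice(females, size=min(config.n_intermediate_sex, females.size),
                          replace=False)
        sex_frac[pick] = 0.5

    # 4. library sizes
    libsize = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, size=n_s)

    # 5. mixing proportions
    mixing_conc = config.mixing_concentration
    if mixing_conc is None:
        mixing_conc = {ct: _DEFAULT_MIXING.get(ct, [1.0] * len(profiles))
                       for ct in config.cell_types}
    pi = np.empty((n_s, len(profiles)))
    for i, s in enumerate(samples):
        alpha = np.asarray(mixing_conc[md.at[s, "cell_type"]], dtype=float)
        if alpha.size != len(profiles):
            raise ValueError("mixing concentration length must match panel profiles")
        pi[i] = rng.dirichlet(alpha)

    # 6. donor effects
    donor_eff = rng.normal(0.0, 1.0, size=(n_g, len(donors))) * donor_sd[:, None]
    donor_of = np.array([donors.index(d) for d in md["donor"]])

    # deterministic mean on the log2 scale
    mix_mean = np.log2(sig @ pi.T + config.mixture_floor)  # genes x samples
    is_case = (md["diagnosis"] == "case").to_numpy(dtype=float)
    mu_log2 = mix_mean + donor_eff[:, donor_of] + np.outer(log2fc, is_case)

    # sex signatures override the mixture for the dedicated genes; expressed
    # in CPM units against each sample's simulated transcriptome total so the
    # log2-CPM thresholds downstream see comparable values at any n_genes
    XIST_ON_CPM, CHRY_ON_CPM, OFF_CPM = 50.0, 30.0, 0.2
    is_female = (md["sex"] == "female").to_numpy(dtype=float)
    female_weight = np.where(is_female == 1.0, sex_frac, 1.0 - sex_frac)
    gi = {g: i for i, g in enumerate(genes)}
    sex_rows = [gi[sex["xist"]]] + [gi[g] for g in sex["chry"]]
    reg_mask = np.ones(n_g, dtype=bool)
    reg_mask[sex_rows] = False
    totals = np.power(2.0, mu_log2[reg_mask]).sum(axis=0)  # per-sample totals
    scale = np.log2(totals / 1e6)
    mu_log2[gi[sex["xist"]], :] = np.log2(
        female_weight * XIST_ON_CPM + (1 - female_weight) * OFF_CPM) + scale
    for g in sex["chry"]:
        mu_log2[gi[g], :] = np.log2(
            (1 - female_weight) * CHRY_ON_CPM + female_weight * OFF_CPM) + scale

    # CNV dosage changes
    for donor, region, dosage in config.cnv_events:
        chrom, start, end = region
        in_region = ((coords["chrom"] == chrom)
                     & (coords["start"] - 1 < end)
                     & (coords["end"] > start)).to_numpy()
        cols = (md["donor"] == donor).to_numpy()
        mu_log2[np.ix_(in_region, cols)] += np.log2(dosage)

    # 7. residual noise, NB-compensated so total residual variance ~ sigma_res^2
    rel = np.power(2.0, mu_log2)
    rel = rel / rel.sum(axis=0, keepdims=True)
    mu_counts = rel * libsize[None, :]
    phi = np.asarray(config.nb_dispersion, dtype=float)
    phi_col = phi.reshape(-1, 1) if phi.ndim == 1 else np.full((n_g, 1), float(phi))
    v_nb = (1.0 / np.clip(mu_counts, 1e-8, None) + phi_col) / LN2_SQ
    extra_sd = np.sqrt(np.clip(s_res ** 2 - v_nb, 0.0, None))
    noise = rng.normal(0.0, 1.0, size=(n_g, n_s)) * extra_sd
    mu_log2 = mu_log2 + noise

    # 8. Sendai covariate: residual viral load in a subset of donors
    sendai = np.zeros(n_s)
    if len(config.sendai_donors):
        in_set = md["donor"].isin(config.sendai_donors).to_numpy()
        raw = rng.lognormal(1.0, 0.8, size=int(in_set.sum()))
        sendai[in_set] = raw
        # quantile-normalize the positive scores against a half-normal reference
        pos = np.flatnonzero(in_set)
        ranks = stats_rankdata(sendai[pos])
        ref = np.abs(np.sort(rng.normal(0, 1, size=pos.size)))
        sendai[pos] = np.sort(ref)[ranks - 1] + 1.0
    md["sendai"] = sendai

    # 9. negative-binomial counts (gamma-Poisson); phi = 0 gives Poisson
    rel = np.power(2.0, mu_log2)
    rel = rel / rel.sum(axis=0, keepdims=True)
    mu_counts = rel * libsize[None, :]
    if np.all(np.asarray(config.nb_dispersion) == 0):
        counts = rng.poisson(mu_counts)
    else:
        shape = 1.0 / phi_col
        lam = rng.gamma(np.broadcast_to(shape, mu_counts.shape),
                        mu_counts * phi_col)
        counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts.astype(np.int64), index=genes, columns=samples)

    # ground truth
    ct_map = [panel.cell_type_map[p] for p in profiles]
    mixing_ct = pd.DataFrame(pi, index=samples, columns=profiles)
    mixing_ct = mixing_ct.T.groupby(ct_map).sum().T

    # approximate true variance fractions from the deterministic components
    var_mix = mix_mean.var(axis=1)
    var_donor = (donor_eff[:, donor_of]).var(axis=1)
    var_dx = np.outer(log2fc, is_case).var(axis=1)
    var_res = np.full(n_g, s_res ** 2)
    total = var_mix + var_donor + var_dx + var_res
    vf = pd.DataFrame({
        "cell_type_mixture": var_mix / total,
        "donor": var_donor / total,
        "diagnosis": var_dx / total,
        "residual": var_res / total,
    }, index=genes)

    de_ind = np.zeros(n_g, dtype=bool)
    de_ind[de_idx] = True
    eqtl_ind = np.zeros(n_g, dtype=bool)
    eqtl_ind[eqtl_idx] = True
    truth = GroundTruth(
        log2fc=pd.Series(log2fc, index=genes, name="log2fc"),
        de_indicator=pd.Series(de_ind, index=genes, name="is_de"),
        eqtl_indicator=pd.Series(eqtl_ind, index=genes, name="is_eqtl"),
        mixing=mixing_ct,
        variance_fractions=vf,
        donor_sd=pd.Series(donor_sd, index=genes, name="donor_sd"),
    )
    md.attrs["gene_coords"] = coords
    md.attrs["signature"] = panel
    return counts_df, md, truth


def stats_rankdata(x: np.ndarray) -> np.ndarray:
    """Ordinal ranks (1-based) with stable tie order."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, len(x) + 1)
    return ranks


def simulate_paired_cohorts(
    config: SimulationConfig,
    shared_effect_corr: float,
    config_b: SimulationConfig | None = None,
) -> tuple[tuple, tuple]:
    """Two cohorts whose true diagnosis effect vectors correlate as requested.

    The same genes are declared differentially expressed in both cohorts and
    their effect sizes are drawn jointly bivariate-normal with correlation
    ``shared_effect_corr`` (exactly equal at 1).  Everything else (donors,
    mixing, noise, counts) is independent between the cohorts.
    """
    if not (-1.0 <= shared_effect_corr <= 1.0):
        raise ValueError("shared_effect_corr must be in [-1, 1]")
    cfg_b = config_b if config_b is not None else config
    if cfg_b.n_genes != config.n_genes or cfg_b.frac_de_genes != config.frac_de_genes:
        raise ValueError("paired cohorts must share n_genes and frac_de_genes")

    rng = np.random.default_rng(config.seed)
    seed_a, seed_b = rng.integers(0, 2**31 - 1, size=2)

    import dataclasses
    cohort_a = simulate_cohort(dataclasses.replace(config, seed=int(seed_a)))
    counts_a, md_a, truth_a = cohort_a

    # rebuild cohort B with effects correlated to cohort A's
    r = shared_effect_corr
    a_vec = truth_a.log2fc.to_numpy()
    de_mask = truth_a.de_indicator.to_numpy()
    sd = config.lfc_sd if config.lfc_sd > 0 else 1.0
    z2 = rng.normal(0.0, 1.0, size=int(de_mask.sum()))
    if r == 1.0:
        b_on_de = a_vec[de_mask]
    elif r == -1.0:
        b_on_de = -a_vec[de_mask]
    else:
        b_on_de = r * a_vec[de_mask] + math.sqrt(1 - r * r) * sd * z2

    cohort_b = simulate_cohort(dataclasses.replace(cfg_b, seed=int(seed_b)))
    counts_b, md_b, truth_b = cohort_b
    # overwrite cohort B's diagnosis component with the correlated effects
    b_vec = np.zeros_like(a_vec)
    b_vec[de_mask] = b_on_de
    delta = b_vec - truth_b.log2fc.to_numpy()
    is_case = (md_b["diagnosis"] == "case").to_numpy(dtype=float)
    # adjust counts multiplicatively on case samples (exact on the mean scale)
    factor = np.power(2.0, np.outer(delta, is_case))
    counts_b = pd.DataFrame(
        np.round(counts_b.to_numpy() * factor).astype(np.int64),
        index=counts_b.index, columns=counts_b.columns,
    )
    truth_b = GroundTruth(
        log2fc=pd.Series(b_vec, index=truth_b.log2fc.index, name="log2fc"),
        de_indicator=truth_a.de_indicator.copy(),
        eqtl_indicator=truth_b.eqtl_indicator,
        mixing=truth_b.mixing,
        variance_fractions=truth_b.variance_fractions,
        donor_sd=truth_b.donor_sd,
    )
    return (counts_a, md_a, truth_a), (counts_b, md_b, truth_b)
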