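"""End-to-end orchestration of the analysis stages with a config file.

``run_pipeline`` executes the enabled stages in dependency order
(qc -> deconvolution -> varpart / eqtl enrichment -> differential expression
-> coexpression -> design report), writing each stage's tables to its own
subdirectory of the output directory plus a run manifest (seed, parameters,
input checksums).  Identical config and seed give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .normalize import filter_genes, tmm_normalize, infer_sex
from .deconvolution import SignaturePanel, ctc_scores, residualize, principal_components
from .varpart import VarPartFormula, partition_matrix
from .enrichment import eqtl_fold_enrichment
from .diffexpr import de_pipeline
from .coexpression import soft_adjacency, topological_overlap, detect_modules
from .design import ess, optimize_design

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_PARAMS"]

# stage parameters; defaults follow the emulated study's analysis settings
DEFAULT_PARAMS: dict[str, Any] = {
    "min_cpm": 1.0,
    "min_frac": 0.30,
    "beta": 9,
    "min_module_size": 20,
    "n_top_eqtl": 2000,
    "n_perm": 10000,
    "n_cutoffs": 40,
    "min_genes_cutoff": 100,
    "fdr_cutoffs": [0.10, 0.30],
    "ctc_covariates": ["fibroblast_1", "fibroblast_2"],
    "varpart_random": ["cell_type", "donor", "diagnosis", "sex"],
    "coexpr_max_genes": 2000,
    "design_rho": None,  # default: median donor fraction from varpart
    "design_budget": 30.0,
    "design_cost_per_donor": 1.0,
    "design_alpha": 0.5,
}

_STAGES = ["qc", "deconvolution", "varpart", "enrichment", "de", "coexpression", "design"]


@dataclasses.dataclass
class PipelineConfig:
    counts: str
    metadata: str
    signature: str | None = None
    eqtl_genes: str | None = None
    gene_sets: str | None = None
    regions: str | None = None
    stages: list[str] = dataclasses.field(default_factory=lambda: list(_STAGES))
    params: dict = dataclasses.field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        unknown = set(self.params) - set(DEFAULT_PARAMS)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def resolved_params(self) -> dict:
        out = dict(DEFAULT_PARAMS)
        out.update(self.params)
        return out


def _checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run the enabled stages; returns the output directory.

    On stage failure a FAILED marker naming the stage is written and the
    exception re-raised; completed stage outputs are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.resolved_params()

    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stages": config.stages,
        "params": params,
        "inputs": {},
    }
    for key in ("counts", "metadata", "signature", "eqtl_genes", "gene_sets", "regions"):
        path = getattr(config, key)
        if path:
            manifest["inputs"][key] = {"path": str(path), "sha256_16": _checksum(path)}

    (out / "config.yaml").write_text(yaml.safe_dump({
        **{k: getattr(config, k) for k in
           ("counts", "metadata", "signature", "eqtl_genes", "gene_sets", "regions")},
        "stages": config.stages, "params": config.params, "seed": config.seed,
    }))

    counts = pio.read_counts(config.counts)
    metadata = pio.read_table(config.metadata)
    metadata = metadata.loc[counts.columns]
    state: dict[str, Any] = {}
    current = ""
    try:
        if "qc" in config.stages:
            current = "qc"
            d = out / "qc"; d.mkdir(exist_ok=True)
            kept = filter_genes(counts, params["min_cpm"], params["min_frac"])
            counts = counts.loc[kept]
            norm = tmm_normalize(counts)
            state["norm"] = norm
            pio.write_table(norm.log2_cpm, d / "log2_cpm.tsv")
            pio.write_table(
                pd.DataFrame({"tmm_factor": norm.tmm_factors,
                              "library_size": norm.library_sizes}),
                d / "sample_factors.tsv", index_label="sample_id")
            sexg = [g for g in ["XIST", "USP9Y", "UTY", "NLGN4Y", "ZFY", "RPS4Y1",
                                "TXLNG2P"] if g in norm.genes]
            if len(sexg) == 7:
                calls = infer_sex(norm, sexg[0], sexg[1:],
                                  annotated_sex=metadata.get("sex"))
                pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
                    d / "sex_calls.tsv", sep="\t", index=False)
            manifest["qc"] = {"genes_retained": len(kept)}

        if "deconvolution" in config.stages and config.signature:
            current = "deconvolution"
            d = out / "deconvolution"; d.mkdir(exist_ok=True)
            sig = pio.read_table(config.signature)
            # profile -> cell type map: strip trailing replicate suffix if present
            cmap = {c: c.rsplit("#", 1)[0] for c in sig.columns}
            panel = SignaturePanel(profiles=sig, cell_type_map=cmap)
            norm = state["norm"]
            scores = ctc_scores(norm.log2_cpm, panel)
            state["scores"] = scores
            pio.write_table(scores, d / "ctc_scores.tsv", index_label="sample_id")
            cols = [c for c in params["ctc_covariates"] if c in scores.columns]
            if cols:
                resid = residualize(norm.log2_cpm, scores[cols])
                state["resid"] = resid
                pio.write_table(resid, d / "residual_log2_cpm.tsv")
                _, frac_raw = principal_components(norm.log2_cpm, 2)
                _, frac_res = principal_components(resid, 2)
                manifest["deconvolution"] = {
                    "pc1_variance_raw": float(frac_raw[0]),
                    "pc1_variance_residual": float(frac_res[0]),
                }

        if "varpart" in config.stages:
            current = "varpart"
            d = out / "varpart"; d.mkdir(exist_ok=True)
            norm = state["norm"]
            rand = [v for v in params["varpart_random"] if v in metadata.columns
                    and metadata[v].nunique() > 1]
            fixed = []
            if "scores" in state:
                for c in params["ctc_covariates"]:
                    if c in state["scores"].columns:
                        metadata[f"ctc_{c}"] = state["scores"][c]
                        fixed.append(f"ctc_{c}")
            formula = VarPartFormula(random_effects=rand, fixed_effects=fixed)
            table, medians = partition_matrix(norm.log2_cpm, metadata, formula)
            state["varfracs"] = table
            pio.write_table(table, d / "variance_fractions.tsv")
            medians.to_csv(d / "medians.tsv", sep="\t", header=["median_fraction"])
            manifest["varpart"] = {"formula_random": rand, "formula_fixed": fixed,
                                   "medians": {k: float(v) for k, v in medians.items()}}

        if "enrichment" in config.stages and config.eqtl_genes:
            current = "enrichment"
            d = out / "enrichment"; d.mkdir(exist_ok=True)
            top = pio.read_gene_list(config.eqtl_genes)
            curve = eqtl_fold_enrichment(
                state["varfracs"].drop(columns=["fit_error"]), "donor", top,
                n_top=params["n_top_eqtl"], n_cutoffs=params["n_cutoffs"],
                n_perm=params["n_perm"], min_genes=params["min_genes_cutoff"],
                seed=config.seed)
            pio.write_table(curve.to_frame(), d / "eqtl_fold_enrichment.tsv",
                            index_label="row")

        if "de" in config.stages:
            current = "de"
            d = out / "de"; d.mkdir(exist_ok=True)
            norm = state["norm"]
            for ct in sorted(metadata["cell_type"].unique()):
                mask = metadata["cell_type"] == ct
                sub = metadata[mask]
                design_cols = [np.ones(mask.sum()),
                               (sub["diagnosis"] == "case").to_numpy(float)]
                names = ["intercept", "diagnosis"]
                if sub["sex"].nunique() > 1:
                    design_cols.append((sub["sex"] == "male").to_numpy(float))
                    names.append("sex")
                if "scores" in state:
                    for c in params["ctc_covariates"]:
                        if c in state["scores"].columns:
                            design_cols.append(state["scores"].loc[sub.index, c].to_numpy())
                            names.append(f"ctc_{c}")
                design = np.column_stack(design_cols)
                res = de_pipeline(counts[sub.index], design, contrast=1,
                                  block=sub["donor"].tolist(),
                                  logcpm=norm.log2_cpm[sub.index])
                state[f"de_{ct}"] = res
                pio.write_table(res, d / f"de_{ct}.tsv")
                manifest.setdefault("de", {})[ct] = {
                    "consensus_rho": float(res.attrs["consensus_rho"]),
                    "pi0": float(res.attrs["pi0"]),
                    **{f"n_fdr_{int(c*100)}": int((res["fdr_bh"] < c).sum())
                       for c in params["fdr_cutoffs"]},
                }

        if "coexpression" in config.stages:
            current = "coexpression"
            d = out / "coexpression"; d.mkdir(exist_ok=True)
            norm = state["norm"]
            for ct in sorted(metadata["cell_type"].unique()):
                cols = metadata.index[metadata["cell_type"] == ct]
                expr = norm.log2_cpm[cols]
                # restrict to the most variable genes to keep the network tractable
                v = expr.var(axis=1)
                keep = v.sort_values(ascending=False).index[:params["coexpr_max_genes"]]
                expr = expr.loc[sorted(keep)]
                adj = soft_adjacency(expr, beta=params["beta"])
                tom = topological_overlap(adj)
                modules = detect_modules(tom, params["min_module_size"])
                modules.labels.to_csv(d / f"modules_{ct}.tsv", sep="\t",
                                      header=["module"], index_label="gene_id")
                manifest.setdefault("coexpression", {})[ct] = {
                    "n_modules": len(modules.modules),
                    "n_grey": int((modules.labels == "grey").sum()),
                }

        if "design" in config.stages:
            current = "design"
            d = out / "design"; d.mkdir(exist_ok=True)
            rho = params["design_rho"]
            if rho is None and "varfracs" in state and "donor" in state["varfracs"]:
                rho = float(state["varfracs"]["donor"].median())
            if rho is None:
                rho = 0.0
            k_by_donor = metadata.groupby("donor")["line"].nunique()
            rep = ess(k_by_donor.tolist(), rho)
            spec, best = optimize_design(params["design_budget"],
                                         params["design_cost_per_donor"],
                                         params["design_alpha"], rho)
            (d / "ess_report.json").write_text(json.dumps({
                "rho": rho,
                "cohort_n_samples_per_cell_type": rep.n_samples,
                "cohort_ess": rep.ess,
                "optimal_design_k": spec.k_list,
                "optimal_design_ess": best.ess,
            }, indent=2))
            manifest["design"] = {"rho": rho, "cohort_ess": rep.ess,
                                  "optimal_ess": best.ess}
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {current} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
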