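"""Filtering worked examples, TMM properties against toy oracles, sex calls,
and CNV z-scores."""

import numpy as np
import pandas as pd
import pytest

from hipscpipe.normalize import (
    NormalizedMatrix,
    cnv_zscores,
    filter_genes,
    infer_sex,
    tmm_normalize,
)
from hipscpipe.synthetic import SimulationConfig, simulate_cohort


def _matrix_with_library(genes: dict, n_samples: int = 10, lib: int = 1_000_000):
    """Matrix where a filler gene tops every library up to ``lib`` counts."""
    rows = {k: np.asarray(v) for k, v in genes.items()}
    used = sum(rows.values())
    rows = {"filler": lib - used, **rows}
    return pd.DataFrame(rows, index=[f"s{j}" for j in range(n_samples)]).T


class TestFilterGenes:
    def test_all_zero_gene_removed(self):
        m = _matrix_with_library({"zero": [0] * 10, "ok": [50] * 10})
        assert "zero" not in filter_genes(m)
        assert "ok" in filter_genes(m)

    def test_hand_computed_retention_at_exact_threshold(self):
        # CPM = 2 in exactly 3/10 = 30% of samples: retained ("at least")
        m = _matrix_with_library({"g": [2, 2, 2, 0, 0, 0, 0, 0, 0, 0]})
        assert "g" in filter_genes(m, min_cpm=1, min_frac=0.30)

    def test_hand_computed_removal_below_threshold(self):
        # CPM = 2 in 2/10 = 20% < 30%: removed
        m = _matrix_with_library({"g": [2, 2, 0, 0, 0, 0, 0, 0, 0, 0]})
        assert "g" not in filter_genes(m, min_cpm=1, min_frac=0.30)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.poisson(3, size=(200, 12)),
                         index=[f"g{i}" for i in range(200)])
        kept = filter_genes(m)
        assert filter_genes(m.loc[kept]) == kept

    def test_zero_library_sample_named_in_error(self):
        m = pd.DataFrame({"a": [1, 2], "bad": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="bad"):
            filter_genes(m)


class TestTMM:
    @pytest.fixture()
    def base(self, rng):
        return (rng.lognormal(4, 1.2, 200).round().astype(int) + 1)

    def test_identical_columns_factor_one(self, base):
        c = pd.DataFrame({"a": base, "b": base, "c": base})
        np.testing.assert_allclose(tmm_normalize(c).tmm_factors, 1.0, atol=1e-12)

    def test_pure_depth_doubling_absorbed_by_library_size(self, base):
        c = pd.DataFrame({"a": base, "b": base * 2, "c": base})
        f = tmm_normalize(c).tmm_factors
        assert abs(f["b"] / f["a"] - 1) < 1e-6

    def test_composition_shift_lowers_factor(self, base):
        shifted = base.copy()
        shifted[:20] = shifted[:20] * 10  # 10% of genes get 10x counts
        c = pd.DataFrame({"a": base, "b": base, "c": base, "d": shifted})
        f = tmm_normalize(c).tmm_factors
        assert f["d"] < 1.0 < f["a"]

    def test_geometric_mean_one_and_global_rescale_invariance(self, base, rng):
        c = pd.DataFrame(rng.poisson(base[:, None] * [1.0, 1.4, 0.7, 1.1]),
                         columns=list("abcd"))
        c = c + 1
        f1 = tmm_normalize(c).tmm_factors
        f2 = tmm_normalize(c * 5).tmm_factors
        assert abs(np.exp(np.mean(np.log(f1))) - 1) < 1e-12
        np.testing.assert_allclose(f1, f2, rtol=1e-10)

    def test_needs_two_samples(self, base):
        with pytest.raises(ValueError):
            tmm_normalize(pd.DataFrame({"a": base}))


class TestInferSex:
    CHRY = ["USP9Y", "UTY", "NLGN4Y", "ZFY", "RPS4Y1", "TXLNG2P"]

    def _norm(self, xist, chry):
        genes = ["XIST", *self.CHRY, "other"]
        vals = np.array([[xist], *[[chry]] * 6, [5.0]])
        df = pd.DataFrame(vals, index=genes, columns=["s1"])
        return NormalizedMatrix(log2_cpm=df,
                                tmm_factors=pd.Series([1.0], index=["s1"]),
                                library_sizes=pd.Series([1e6], index=["s1"]))

    @pytest.mark.parametrize("xist,chry,expected", [
        (6.0, 0.0, "female"),
        (0.0, 5.0, "male"),
        (4.0, 4.0, "intermediate"),  # 50/50 mixture pattern
    ])
    def test_extreme_and_mixed_profiles(self, xist, chry, expected):
        calls = infer_sex(self._norm(xist, chry), "XIST", self.CHRY)
        assert calls[0].call == expected

    def test_missing_genes_listed(self):
        norm = self._norm(1, 1)
        with pytest.raises(KeyError, match="NOPE"):
            infer_sex(norm, "XIST", ["NOPE"])

    def test_synthetic_cohort_calls_match_annotation(self):
        cfg = SimulationConfig(n_genes=500, n_donors_case=4, n_donors_control=4,
                               n_intermediate_sex=3, seed=2)
        counts, md, _ = simulate_cohort(cfg)
        norm = tmm_normalize(counts)
        calls = infer_sex(norm, "XIST", self.CHRY, annotated_sex=md["sex"])
        assert sum(c.call == "intermediate" for c in calls) == 3
        assert not any(c.mismatch for c in calls)


class TestCnvZscores:
    @pytest.fixture(scope="class")
    def cohort(self):
        region = ("chr1", 100_000, 400_000)
        cfg = SimulationConfig(n_genes=600, n_donors_case=5, n_donors_control=5,
                               seed=8, cnv_events=[("case01", region, 0.5)])
        counts, md, _ = simulate_cohort(cfg)
        norm = tmm_normalize(counts)
        regions = pd.DataFrame(
            [{"chrom": "chr1", "start": 100_000, "end": 400_000, "name": "del"}])
        z = cnv_zscores(norm, md, regions, md.attrs["gene_coords"])
        return norm, md, regions, z

    def test_z_mean_zero_sd_one_per_gene(self, cohort):
        _, _, _, z = cohort
        piv = z.pivot_table(index="gene_id", columns="sample", values="z")
        np.testing.assert_allclose(piv.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(piv.std(axis=1, ddof=1), 1, atol=1e-8)

    def test_heterozygous_deletion_depresses_carrier_z(self, cohort):
        _, md, _, z = cohort
        piv = z.pivot_table(index="gene_id", columns="sample", values="z")
        carrier = md.index[md["donor"] == "case01"]
        assert piv[carrier].to_numpy().mean() < -1.0

    def test_constant_gene_flagged_zero(self, cohort):
        norm, md, regions, _ = cohort
        flat = norm.log2_cpm.copy()
        gene = flat.index[flat.index.str.startswith("G")][0]
        flat.loc[gene] = 3.14
        norm2 = NormalizedMatrix(flat, norm.tmm_factors, norm.library_sizes)
        coords = md.attrs["gene_coords"].copy()
        coords.loc[gene, ["chrom", "start", "end"]] = ["chr1", 100_001, 100_500]
        z = cnv_zscores(norm2, md, regions, coords)
        sub = z[z["gene_id"] == gene]
        assert (sub["z"] == 0).all() and sub["flat_gene"].all()

    def test_sample_permutation_equivariance(self, cohort):
        norm, md, regions, z = cohort
        perm = norm.log2_cpm.columns[::-1]
        norm2 = NormalizedMatrix(norm.log2_cpm[perm], norm.tmm_factors[perm],
                                 norm.library_sizes[perm])
        z2 = cnv_zscores(norm2, md, regions, md.attrs["gene_coords"])
        a = z.set_index(["gene_id", "sample"])["z"]
        b = z2.set_index(["gene_id", "sample"])["z"]
        np.testing.assert_allclose(a.sort_index(), b.sort_index(), atol=1e-10)
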