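"""Variance partitioning against the closed-form ANOVA oracle, recovery,
invariances, and the paired Wilcoxon comparison."""

import numpy as np
import pandas as pd
import pytest

from hipscpipe.varpart import (
    VarPartFormula,
    anova_icc,
    compare_partitions,
    partition_gene,
    partition_matrix,
)
from tests.conftest import balanced_metadata

FORMULA_DONOR = VarPartFormula(random_effects=["donor"])


def _one_way(rng, icc, m=20, k=4):
    sd_d = np.sqrt(icc / (1 - icc)) if icc > 0 else 0.0
    u = rng.normal(0, sd_d, m)
    return u[np.repeat(np.arange(m), k)] + rng.normal(0, 1, m * k)


class TestSingleRandomEffect:
    def test_matches_anova_oracle_within_1e3(self, rng):
        md = balanced_metadata(20, 4)
        for icc in (0.0, 0.3, 0.7):
            for _ in range(15):
                y = _one_way(rng, icc)
                res = partition_gene(y, md, FORMULA_DONOR, samples=md.index)
                oracle = anova_icc(y, md["donor"].to_numpy())
                assert abs(res["donor"] - oracle) < 1e-3

    @pytest.mark.parametrize("icc", [0.1, 0.5, 0.8])
    def test_icc_recovered_within_tenth(self, icc):
        rng = np.random.default_rng(int(icc * 1000) + 7)
        md = balanced_metadata(20, 4)
        recs = [partition_gene(_one_way(rng, icc), md, FORMULA_DONOR,
                               samples=md.index)["donor"] for _ in range(100)]
        assert abs(np.median(recs) - icc) < 0.1

    def test_null_gene_residual_dominates(self, rng):
        md = balanced_metadata(15, 4)
        res_fracs = [partition_gene(rng.normal(0, 1, 60), md, FORMULA_DONOR,
                                    samples=md.index)["residual"]
                     for _ in range(30)]
        assert np.median(res_fracs) > 0.9

    def test_affine_rescaling_invariance(self, rng):
        md = balanced_metadata(12, 3)
        y = _one_way(rng, 0.4, 12, 3)
        a = partition_gene(y, md, FORMULA_DONOR, samples=md.index)
        b = partition_gene(5.0 * y - 3.0, md, FORMULA_DONOR, samples=md.index)
        assert a["donor"] == pytest.approx(b["donor"], abs=1e-6)

    def test_monotone_in_simulated_donor_variance(self):
        rng = np.random.default_rng(99)
        md = balanced_metadata(20, 4)
        medians = []
        for icc in (0.1, 0.4, 0.7):
            vals = [partition_gene(_one_way(rng, icc), md, FORMULA_DONOR,
                                   samples=md.index)["donor"] for _ in range(60)]
            medians.append(np.median(vals))
        assert medians[0] < medians[1] < medians[2]


class TestMultipleComponents:
    def test_fractions_sum_to_one_with_fixed_effects(self, rng):
        n = 48
        md = balanced_metadata(12, 4)
        md["cell_type"] = np.tile(["NPC", "neuron"], n // 2)
        md["ctc"] = rng.normal(0, 1, n)
        y = (rng.normal(0, 0.8, 12)[np.repeat(np.arange(12), 4)]
             + 0.5 * md["ctc"].to_numpy() + rng.normal(0, 1, n))
        formula = VarPartFormula(["donor", "cell_type"], ["ctc"])
        res = partition_gene(y, md, formula, samples=md.index)
        total = res["donor"] + res["cell_type"] + res["ctc"] + res["residual"]
        assert total == pytest.approx(1.0, abs=1e-8)
        assert all(0 <= res[k] <= 1 for k in ("donor", "cell_type", "ctc", "residual"))

    def test_matrix_medians_rank_components_by_size(self, rng):
        md = balanced_metadata(10, 4)
        md["cell_type"] = np.tile(["NPC", "neuron"], 20)
        big_ct = np.where(md["cell_type"] == "NPC", 1.6, -1.6)
        genes = {}
        for g in range(40):
            u = rng.normal(0, 0.5, 10)
            genes[f"g{g}"] = (big_ct + u[np.repeat(np.arange(10), 4)]
                              + rng.normal(0, 1, 40))
        expr = pd.DataFrame(genes).T
        expr.columns = md.index
        _, med = partition_matrix(expr, md, VarPartFormula(["cell_type", "donor"]))
        assert med["cell_type"] > med["donor"] > 0
        assert med["residual"] > med["donor"]

    def test_zero_variance_gene_reported_na(self):
        md = balanced_metadata(6, 2)
        expr = pd.DataFrame({s: [1.0, 2.0] for s in md.index},
                            index=["flat", "flat2"])
        expr.loc["flat2"] = np.arange(12, dtype=float)
        with pytest.warns(UserWarning):
            table, _ = partition_matrix(expr, md, FORMULA_DONOR)
        assert table.loc["flat", "fit_error"] != ""
        assert np.isnan(table.loc["flat", "donor"])

    def test_sample_order_permutation_invariant(self, rng):
        md = balanced_metadata(8, 3)
        y = pd.Series(_one_way(rng, 0.5, 8, 3), index=md.index)
        perm = md.index[::-1]
        a = partition_gene(y, md, FORMULA_DONOR)
        b = partition_gene(y[perm], md.loc[perm], FORMULA_DONOR)
        assert a["donor"] == pytest.approx(b["donor"], abs=1e-6)


class TestComparePartitions:
    def _fracs(self, rng, n=200, shift=0.0):
        donor = np.clip(rng.beta(2, 8, n), 0.001, 0.95)
        a = pd.DataFrame({"donor": donor}, index=[f"g{i}" for i in range(n)])
        b = pd.DataFrame({"donor": np.clip(donor + shift, 0, 1)}, index=a.index)
        return a, b

    def test_identical_tables_give_half_p(self, rng):
        a, b = self._fracs(rng)
        out = compare_partitions(a, b)
        assert out["p_value"] == pytest.approx(0.5, abs=0.05)
        assert out["median_difference"] == 0.0

    def test_systematic_increase_detected(self, rng):
        a, b = self._fracs(rng, n=2000, shift=0.02)
        out = compare_partitions(a, b)
        assert out["p_value"] < 1e-10
        assert out["median_difference"] == pytest.approx(0.02, abs=1e-9)

    def test_reversed_direction_near_one(self, rng):
        a, b = self._fracs(rng, n=2000, shift=0.02)
        out = compare_partitions(b, a)  # testing a > b, opposite of truth
        assert out["p_value"] > 0.99

    def test_too_few_genes_refused(self, rng):
        a, b = self._fracs(rng, n=5)
        with pytest.raises(ValueError):
            compare_partitions(a, b)
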