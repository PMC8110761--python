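import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from hybridexpr import (
    Contrast,
    CountMatrix,
    SampleDesign,
    SimConfig,
    adjust_fdr,
    call_deg,
    estimate_dispersion,
    estimate_size_factors,
    nb_wald_test,
    simulate_experiment,
)
from hybridexpr.de import read_de_table, write_de_table
from hybridexpr.io import ValidationError


def two_group_design(reps, tissue="t"):
    rows = [
        {"sample_id": f"{tissue}_{line}_{r}", "line": line, "tissue": tissue,
         "replicate": r}
        for line in ("P1", "P2")
        for r in range(1, reps + 1)
    ]
    return SampleDesign(pd.DataFrame(rows))


class TestSizeFactors:
    def test_identical_columns_give_one(self):
        m = CountMatrix(pd.DataFrame({"s1": [10, 20], "s2": [10, 20]}, index=["a", "b"]))
        sf = estimate_size_factors(m)
        assert np.allclose(sf, 1.0)

    def test_doubled_column_ratio_two(self):
        # hand computation: ref_g = sqrt(K * 2K) = K*sqrt(2);
        # ratios are 1/sqrt(2) and sqrt(2) for every gene, so s2/s1 = 2
        m = CountMatrix(
            pd.DataFrame({"s1": [10, 40, 100], "s2": [20, 80, 200]}, index=list("abc"))
        )
        sf = estimate_size_factors(m)
        assert np.isclose(sf["s2"] / sf["s1"], 2.0)
        assert np.isclose(sf["s1"], 1 / np.sqrt(2))

    def test_global_scaling_invariance(self):
        # median-of-ratios is a *relative* measure: scaling the whole
        # matrix leaves the factors unchanged
        rng = np.random.default_rng(0)
        base = rng.poisson(100, size=(50, 4)) + 1
        m1 = CountMatrix(pd.DataFrame(base, columns=list("abcd")))
        m2 = CountMatrix(pd.DataFrame(base * 3, columns=list("abcd")))
        pd.testing.assert_series_equal(
            estimate_size_factors(m1), estimate_size_factors(m2)
        )

    def test_no_common_gene_errors_and_fallback(self):
        m = CountMatrix(pd.DataFrame({"s1": [5, 0], "s2": [0, 5]}, index=["a", "b"]))
        with pytest.raises(ValidationError, match="pseudo_reference"):
            estimate_size_factors(m)
        sf = estimate_size_factors(m, pseudo_reference=True)
        assert (sf > 0).all()

    def test_recovers_simulated_depths(self):
        cfg = SimConfig(n_genes=2000, n_replicates=2, tissues=("t",), seed=21,
                        dispersion=0.05)
        depths = np.linspace(0.5, 2.0, len(cfg.sample_ids))
        cfg.depth_factors = dict(zip(cfg.sample_ids, depths))
        matrix, _, _ = simulate_experiment(cfg)
        sf = estimate_size_factors(matrix).to_numpy()
        rel_sf = sf / np.exp(np.mean(np.log(sf)))
        rel_truth = depths / np.exp(np.mean(np.log(depths)))
        assert np.max(np.abs(rel_sf / rel_truth - 1)) < 0.05


class TestDispersion:
    def run_sim(self, alpha, reps, seed=0, n=2000):
        cfg = SimConfig(
            n_genes=n, n_replicates=reps, tissues=("t",), hybrids=(),
            category_proportions={"t": {"conserved": 1.0}},
            dispersion=alpha, seed=seed,
        )
        matrix, design, _ = simulate_experiment(cfg)
        sf = estimate_size_factors(matrix)
        return estimate_dispersion(matrix, sf, design)

    def test_poisson_null(self):
        est = self.run_sim(alpha=0.0, reps=2)
        assert est.median() <= 0.01

    def test_recovers_alpha(self):
        est = self.run_sim(alpha=0.1, reps=6)
        assert 0.05 <= est.median() <= 0.2

    def test_constant_counts_zero(self):
        design = two_group_design(3)
        m = CountMatrix(
            pd.DataFrame(
                np.tile([[50], [100]], (1, 6)), index=["a", "b"],
                columns=design.samples,
            )
        )
        sf = estimate_size_factors(m)
        est = estimate_dispersion(m, sf, design)
        assert np.allclose(est, 0.0)

    def test_single_replicate_warns(self):
        design = two_group_design(1)
        m = CountMatrix(
            pd.DataFrame([[50, 60]], index=["a"], columns=design.samples)
        )
        sf = estimate_size_factors(m)
        with pytest.warns(UserWarning, match="dispersion"):
            est = estimate_dispersion(m, sf, design)
        assert np.allclose(est, 0.0)


class TestWaldTest:
    def build(self, rows, reps=2):
        design = two_group_design(reps)
        m = CountMatrix(
            pd.DataFrame(rows, columns=design.samples,
                         index=[f"g{i}" for i in range(len(rows))])
        )
        sf = pd.Series(1.0, index=design.samples)
        return m, design, sf

    def test_identical_groups(self):
        m, design, sf = self.build([[30, 30, 30, 30]])
        res = nb_wald_test(m, sf, 0.05, design, Contrast(("P1", "t"), ("P2", "t")))
        assert res["log2fc"].iloc[0] == 0.0
        assert res["pvalue"].iloc[0] == 1.0

    def test_fold_change_arithmetic(self):
        m, design, sf = self.build([[100, 100, 25, 25]])
        res = nb_wald_test(m, sf, 0.05, design, Contrast(("P1", "t"), ("P2", "t")))
        assert np.isclose(res["log2fc"].iloc[0], 2.0)

    def test_all_zero_gene_flagged(self):
        m, design, sf = self.build([[0, 0, 0, 0], [10, 10, 10, 10]])
        res = nb_wald_test(m, sf, 0.05, design, Contrast(("P1", "t"), ("P2", "t")))
        assert res["pvalue"].iloc[0] == 1.0
        assert res["log2fc"].iloc[0] == 0.0
        assert np.isnan(res["se"].iloc[0])

    def test_zero_floor_bounds_fold_change(self):
        m, design, sf = self.build([[0, 0, 32, 32]])
        res = nb_wald_test(
            m, sf, 0.0, design, Contrast(("P1", "t"), ("P2", "t")), zero_floor=0.5
        )
        assert np.isclose(res["log2fc"].iloc[0], np.log2(0.5 / 32))

    def test_swap_negates_lfc_preserves_p(self):
        rng = np.random.default_rng(1)
        m, design, sf = self.build(rng.poisson(80, size=(40, 4)))
        fwd = nb_wald_test(m, sf, 0.05, design, Contrast(("P1", "t"), ("P2", "t")))
        rev = nb_wald_test(m, sf, 0.05, design, Contrast(("P2", "t"), ("P1", "t")))
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["pvalue"], rev["pvalue"])

    def test_null_pvalues_uniform(self):
        cfg = SimConfig(
            n_genes=5000, n_replicates=2, tissues=("t",), hybrids=(),
            category_proportions={"t": {"conserved": 1.0}}, dispersion=0.05,
            seed=13,
        )
        matrix, design, _ = simulate_experiment(cfg)
        sf = estimate_size_factors(matrix)
        disp = estimate_dispersion(matrix, sf, design)
        res = nb_wald_test(matrix, sf, disp, design, Contrast(("P1", "t"), ("P2", "t")))
        assert kstest(res["pvalue"], "uniform").statistic < 0.05

    def test_missing_condition_errors(self):
        m, design, sf = self.build([[1, 2, 3, 4]])
        with pytest.raises(ValidationError, match="condition"):
            nb_wald_test(m, sf, 0.05, design, Contrast(("H_fwd", "t"), ("P1", "t")))

    def test_table_round_trip(self, tmp_path):
        m, design, sf = self.build([[100, 90, 25, 30]])
        res = call_deg(
            nb_wald_test(m, sf, 0.05, design, Contrast(("P1", "t"), ("P2", "t")))
        )
        p = tmp_path / "de.tsv"
        write_de_table(res, p)
        back = read_de_table(p)
        assert list(back.columns) == list(res.columns)
        assert np.allclose(back["log2fc"], res["log2fc"])


class TestAdjustFdr:
    def test_single_p(self):
        assert adjust_fdr([0.03]).tolist() == [0.03]

    def test_textbook_example(self):
        # BH by hand: padj_i = min_{j>=i} m*p_j/j
        out = adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_fdr([0.5, 1.5])
        with pytest.raises(ValidationError):
            adjust_fdr([-0.1])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_dominates_p(self, ps):
        padj = adjust_fdr(ps)
        assert (padj <= 1).all()
        assert all(q >= p - 1e-12 for p, q in zip(ps, padj))
        order = np.argsort(ps, kind="stable")
        assert all(
            padj[order[i]] <= padj[order[i + 1]] + 1e-12
            for i in range(len(ps) - 1)
        )


class TestCallDeg:
    @pytest.mark.parametrize(
        "padj,lfc,expected",
        [(0.005, 1.5, "over"), (0.005, 0.9, "ns"), (0.02, 3.0, "ns"),
         (0.005, -1.5, "under"), (0.005, -1.0, "ns")],
    )
    def test_rule(self, padj, lfc, expected):
        table = pd.DataFrame(
            {"log2fc": [lfc], "pvalue": [padj], "padj": [padj]}, index=["g"]
        )
        assert call_deg(table)["call"].iloc[0] == expected

    def test_call_sign_consistency(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            {"log2fc": rng.normal(0, 2, 200), "pvalue": rng.uniform(0, 1, 200)}
        )
        out = call_deg(table)
        assert (out.loc[out["call"] == "over", "log2fc"] > 1).all()
        assert (out.loc[out["call"] == "under", "log2fc"] < -1).all()


class TestCalibration:
    def null_called_fraction(self, seed):
        cfg = SimConfig(
            n_genes=2000, n_replicates=2, tissues=("t",), hybrids=(),
            category_proportions={"t": {"conserved": 1.0}}, dispersion=0.05,
            seed=seed,
        )
        matrix, design, _ = simulate_experiment(cfg)
        sf = estimate_size_factors(matrix)
        disp = estimate_dispersion(matrix, sf, design)
        res = call_deg(
            nb_wald_test(matrix, sf, disp, design, Contrast(("P1", "t"), ("P2", "t")))
        )
        return (res["call"] != "ns").mean()

    def test_fdr_control_two_seeds(self):
        for seed in (0, 1):
            assert self.null_called_fraction(seed) <= 0.02

    def test_power_monotone_in_effect_size(self):
        # fraction called is non-decreasing in the true |log2fc|
        rng = np.random.default_rng(5)
        design = two_group_design(3)
        n, n_shift = 500, 50  # most genes stay null so normalization holds
        fractions = []
        for lfc in (0.0, 1.0, 2.0, 3.0):
            mu1 = np.full(n, 100.0)
            mu2 = np.full(n, 100.0)
            mu1[:n_shift] *= 2 ** (lfc / 2)
            mu2[:n_shift] *= 2 ** (-lfc / 2)
            counts = np.column_stack(
                [rng.poisson(mu1[:, None], size=(n, 3)),
                 rng.poisson(mu2[:, None], size=(n, 3))]
            )
            m = CountMatrix(
                pd.DataFrame(counts, columns=design.samples,
                             index=[f"g{i}" for i in range(n)])
            )
            sf = estimate_size_factors(m)
            disp = estimate_dispersion(m, sf, design)
            res = call_deg(
                nb_wald_test(m, sf, disp, design, Contrast(("P1", "t"), ("P2", "t")))
            )
            fractions.append((res["call"].iloc[:n_shift] != "ns").mean())
        assert all(a <= b + 1e-9 for a, b in zip(fractions, fractions[1:]))
        assert fractions[0] < 0.05 and fractions[-1] > 0.9
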