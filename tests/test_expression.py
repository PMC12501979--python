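"""TPM, rank groups, differential expression and ASE classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methaplo.expression import (
    RANK_GROUPS,
    call_degs,
    classify_ase,
    compute_tpm,
    crosstab_bias,
    rank_expression,
)


class TestTpm:
    def test_single_gene_gets_the_whole_million(self):
        tpm = compute_tpm(pd.DataFrame({"s": [50]}, index=["g"]),
                          pd.Series({"g": 1000}))
        assert tpm.loc["g", "s"] == pytest.approx(1e6)

    def test_length_normalization(self):
        tpm = compute_tpm(pd.DataFrame({"s": [100, 100]}, index=["a", "b"]),
                          pd.Series({"a": 1000, "b": 2000}))
        assert tpm.loc["a", "s"] / tpm.loc["b", "s"] == pytest.approx(2.0)

    def test_columns_sum_to_a_million(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(0, 500, (50, 4)),
                              index=[f"g{i}" for i in range(50)],
                              columns=list("abcd"))
        lengths = pd.Series(rng.integers(500, 5000, 50), index=counts.index)
        tpm = compute_tpm(counts, lengths)
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            compute_tpm(pd.DataFrame({"s": [1]}, index=["g"]),
                        pd.Series({"g": 0}))


class TestRankGroups:
    @pytest.mark.parametrize("tpm,group", [
        (0.0, "N"), (0.5, "L"), (1.0, "L"), (1.0001, "LM"), (7.0, "LM"),
        (7.0001, "MH"), (100.0, "MH"), (100.0001, "H"), (500.0, "H"),
    ])
    def test_exact_boundaries(self, tpm, group):
        s = pd.Series([tpm])
        assert rank_expression(s).iloc[0] == group

    def test_groups_partition_the_genes(self):
        rng = np.random.default_rng(3)
        tpm = pd.Series(np.exp(rng.normal(1, 3, 500)))
        tpm.iloc[:50] = 0.0
        groups = rank_expression(tpm)
        counts = groups.value_counts()
        assert counts.sum() == 500
        assert set(counts.index) <= set(RANK_GROUPS)


class TestDegs:
    def _counts(self, rng, n=100, effect_idx=(), fold=8):
        base = rng.integers(50, 500, n)
        cols = {}
        for grp, mult in (("t", fold), ("c", 1)):
            for r in (1, 2):
                lam = base.astype(float)
                lam[list(effect_idx)] = base[list(effect_idx)] * mult
                cols[f"{grp}{r}"] = rng.poisson(lam)
        return pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])

    def test_identical_groups_yield_no_degs(self):
        rng = np.random.default_rng(10)
        counts = self._counts(rng)
        deg = call_degs(counts, ["t1", "t2"], ["c1", "c2"])
        assert (deg["deg_status"] == "ns").all()

    def test_strong_effects_recovered_with_expected_lfc(self):
        rng = np.random.default_rng(11)
        counts = self._counts(rng, effect_idx=range(5), fold=10)
        deg = call_degs(counts, ["t1", "t2"], ["c1", "c2"])
        hits = deg.iloc[:5]
        assert (hits["deg_status"] == "up").all()
        assert hits["log2fc"].between(2.5, 4.2).all()

    def test_fold_change_gate_blocks_small_effects(self):
        # large counts: tiny p but |log2fc| < 1 -> ns (background genes keep
        # the library-size normalization from absorbing the effect)
        rows = {"g": [4500, 4500, 2500, 2500]}
        rows.update({f"bg{i}": [10_000] * 4 for i in range(50)})
        counts = pd.DataFrame.from_dict(
            rows, orient="index", columns=["t1", "t2", "c1", "c2"]
        )
        deg = call_degs(counts, ["t1", "t2"], ["c1", "c2"]).loc[["g"]]
        assert deg["p_value"].iloc[0] < 1e-9
        assert abs(deg["log2fc"].iloc[0]) < 1.0
        assert deg["deg_status"].iloc[0] == "ns"

    def test_swapping_groups_swaps_direction(self):
        rng = np.random.default_rng(12)
        counts = self._counts(rng, effect_idx=range(10), fold=6)
        fwd = call_degs(counts, ["t1", "t2"], ["c1", "c2"])
        rev = call_degs(counts, ["c1", "c2"], ["t1", "t2"])
        swap = {"up": "down", "down": "up", "ns": "ns"}
        assert fwd["deg_status"].map(swap).tolist() == rev["deg_status"].tolist()
        np.testing.assert_allclose(fwd["q_value"], rev["q_value"], rtol=1e-9)


class TestAse:
    def _mats(self, m_counts, p_counts):
        idx = [f"p{i}" for i in range(len(m_counts))]
        m = pd.DataFrame({"s1": m_counts, "s2": m_counts}, index=idx)
        p = pd.DataFrame({"s1": p_counts, "s2": p_counts}, index=idx)
        return m, p

    def test_balanced_counts_are_unbiased(self):
        m, p = self._mats([100] * 20, [100] * 20)
        res = classify_ase(m, p)
        assert (res["bias_class"] == "U").all()
        np.testing.assert_allclose(res["log2fc"], 0.0)

    def test_extreme_maternal_bias_detected(self):
        m, p = self._mats([200] + [100] * 20, [0] + [100] * 20)
        res = classify_ase(m, p)
        assert res["bias_class"].iloc[0] == "M"
        oracle = stats.binomtest(400, 400, 0.5).pvalue
        # library sizes are slightly asymmetric, so compare loosely
        assert res["p_value"].iloc[0] < 1e-50
        assert oracle < 1e-50

    def test_zero_pair_is_undefined_u(self):
        m, p = self._mats([0, 100], [0, 100])
        res = classify_ase(m, p)
        assert res["bias_class"].iloc[0] == "U"
        assert bool(res["undefined_log2fc"].iloc[0])
        assert np.isnan(res["log2fc"].iloc[0])

    def test_haplotype_relabel_swaps_classes_exactly(self):
        rng = np.random.default_rng(14)
        m = pd.DataFrame(rng.integers(0, 400, (50, 2)), columns=["s1", "s2"],
                         index=[f"p{i}" for i in range(50)])
        p = pd.DataFrame(rng.integers(0, 400, (50, 2)), columns=["s1", "s2"],
                         index=m.index)
        fwd = classify_ase(m, p)
        rev = classify_ase(p, m)
        swap = {"M": "P", "P": "M", "U": "U"}
        assert fwd["bias_class"].map(swap).tolist() == rev["bias_class"].tolist()
        defined = ~fwd["undefined_log2fc"]
        np.testing.assert_allclose(fwd.loc[defined, "log2fc"],
                                   -rev.loc[defined, "log2fc"], atol=1e-9)

    def test_binomial_tail_oracle_with_equal_libraries(self):
        # one strongly biased pair among balanced pairs keeps libraries equal
        m, p = self._mats([150, 50, 100], [50, 150, 100])
        res = classify_ase(m, p)
        oracle = stats.binomtest(300, 400, 0.5).pvalue
        assert res["p_value"].iloc[0] == pytest.approx(oracle, rel=1e-9)


class TestCrosstab:
    def test_all_unbiased_single_cell(self):
        cls = pd.Series(["U"] * 10, index=range(10))
        tab = crosstab_bias(cls, cls)
        assert tab.loc["U", "U"] == 10
        assert tab.to_numpy().sum() == 10

    def test_disjoint_assignments_have_zero_diagonal(self):
        a = pd.Series(["M", "P", "U"], index=range(3))
        b = pd.Series(["P", "U", "M"], index=range(3))
        tab = crosstab_bias(a, b)
        assert np.trace(tab.to_numpy()) == 0

    def test_margins_equal_class_totals(self):
        rng = np.random.default_rng(15)
        a = pd.Series(rng.choice(["M", "P", "U"], 60), index=range(60))
        b = pd.Series(rng.choice(["M", "P", "U"], 60), index=range(60))
        tab = crosstab_bias(a, b)
        assert tab.sum(axis=1).tolist() == a.value_counts().reindex(
            ["M", "P", "U"], fill_value=0).tolist()


class TestAseRecoveryFromSimulation:
    def test_clearly_biased_pairs_recovered_from_simulated_counts(self, tmp_path):
        """With the coupling sized so strongly biased pairs reach true
        |log2FC| >= 2, >= 90% of the expressed, clearly biased pairs are
        classed M/P with the correct direction.

        The false-positive side is bounded loosely: without dispersion
        modeling the exact binomial test is anti-conservative under
        negative-binomial counts (estimate noise floor ~0.46 log2 units at
        dispersion 0.1 with two replicates), so clearly unbiased pairs are
        miscalled at roughly the rate that noise floor implies, not at the
        nominal FDR. See the methods note on this fidelity limit.
        """
        import numpy as np
        from methaplo.simulate import simulate_allele_counts, simulate_study
        from tests.conftest import small_spec

        spec = small_spec(
            seed=13, chrom_length=400_000, n_genes=60,
            # 2 / 70 per divergence point makes |log2FC| reach 2 at delta 70
            asm_ase_coupling=2 / 70,
        )
        study, _ = simulate_study(spec, tmp_path)
        mats = simulate_allele_counts(study, tmp_path,
                                      expr_log_mean=np.log(120),
                                      expr_log_sd=0.8)
        cols = [c for c in mats["maternal"].columns if c.startswith("AZA0-7")]
        res = classify_ase(mats["maternal"][cols], mats["paternal"][cols])

        truth = study.truth["pairs"]
        lfc = {p: t["true_log2fc"] for p, t in truth.items()}
        cls = {p: t["true_bias_class"] for p, t in truth.items()}
        biased = [p for p in truth
                  if abs(lfc[p]) >= 2 and cls[p] in ("M", "P")]
        unbiased = [p for p in truth if abs(lfc[p]) <= 0.5 and cls[p] == "U"]
        assert len(biased) >= 5 and len(unbiased) >= 20
        correct = sum(res.loc[p, "bias_class"] == cls[p] for p in biased)
        assert correct / len(biased) >= 0.90
        false_pos = sum(res.loc[p, "bias_class"] != "U" for p in unbiased)
        assert false_pos / len(unbiased) <= 0.20
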