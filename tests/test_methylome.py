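"""Context classification, site calling and weighted-level summaries."""

import re

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methaplo.methylome import (
    call_methylated_sites,
    classify_context,
    context_map,
    context_share,
    estimate_conversion_error,
    interval_weighted_levels,
    methylation_level_histogram,
    revcomp,
    weighted_methylation_level,
)


def _sites(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                       "c_meth", "c_total"])


class TestContextClassification:
    @pytest.mark.parametrize(
        "seq,pos,strand,expected",
        [
            ("AACGTT", 2, "+", "CG"),
            ("AACAGT", 2, "+", "CHG"),
            ("AACATT", 2, "+", "CHH"),
            ("AAGTT", 2, "-", "CHH"),    # G on plus strand reads C-T-T on minus
            ("TTCGAA", 3, "-", "CG"),    # CpG is symmetric
            ("AACNGT", 2, "+", "none"),  # N inside the trinucleotide
            ("AAAAAC", 5, "+", "none"),  # C at the chromosome end
        ],
    )
    def test_trinucleotide_rules(self, seq, pos, strand, expected):
        assert classify_context(seq, pos, strand) == expected

    def test_non_cytosine_raises(self):
        with pytest.raises(ValueError):
            classify_context("AACGTT", 0, "+")

    def test_agrees_with_regex_oracle_on_random_sequence(self):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04],
                                 size=10_000))
        cm = context_map(seq)
        observed = {(int(r.pos), r.strand): r.context
                    for r in cm.itertuples(index=False)}
        expected = {}
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            for m in re.finditer("C(?=G[ACGT])", s):
                i = m.start()
                expected[(i if strand == "+" else len(seq) - 1 - i, strand)] = "CG"
            for m in re.finditer("C(?=[ACT]G)", s):
                i = m.start()
                expected[(i if strand == "+" else len(seq) - 1 - i, strand)] = "CHG"
            for m in re.finditer("C(?=[ACT][ACT])", s):
                i = m.start()
                expected[(i if strand == "+" else len(seq) - 1 - i, strand)] = "CHH"
        assert observed == expected

    def test_context_map_trinucleotides_match_sequence(self):
        seq = "ACGTACGTTCAGGCATT"
        cm = context_map(seq)
        for r in cm.itertuples(index=False):
            if r.strand == "+":
                assert seq[r.pos:r.pos + 3] == r.tri
            else:
                assert revcomp(seq[r.pos - 2:r.pos + 1]) == r.tri


class TestConversionError:
    def test_fully_converted_lambda(self):
        lam = _sites([("lambda", i, "+", "CG", 0, 20) for i in range(5)])
        assert estimate_conversion_error(lam)["pooled"] == 0.0

    def test_pooled_rate_is_count_ratio(self):
        lam = _sites([("lambda", 0, "+", "CG", 1, 100),
                      ("lambda", 1, "+", "CHH", 1, 100)])
        est = estimate_conversion_error(lam)
        assert est["pooled"] == pytest.approx(0.01)
        assert est["CG"] == pytest.approx(0.01)

    def test_no_coverage_is_an_error(self):
        lam = _sites([("lambda", 0, "+", "CG", 0, 0)])
        with pytest.raises(ValueError):
            estimate_conversion_error(lam)

    def test_simulated_lambda_within_three_se(self):
        rng = np.random.default_rng(7)
        n, depth, err = 2000, 20, 0.02
        counts = rng.binomial(depth, err, n)
        lam = _sites([("lambda", i, "+", "CHH", int(c), depth)
                      for i, c in enumerate(counts)])
        est = estimate_conversion_error(lam)["pooled"]
        se = np.sqrt(err * (1 - err) / (n * depth))
        assert abs(est - err) < 3 * se


class TestSiteCalling:
    def test_low_depth_stays_subthreshold(self):
        sites = _sites([("c", 0, "+", "CG", 4, 4)])
        out = call_methylated_sites(sites, 0.01, depth_min=5, fdr=0.05)
        assert out["call"].iloc[0] == "sub-threshold"

    def test_zero_methylated_reads_give_p_one(self):
        sites = _sites([("c", 0, "+", "CG", 0, 30)])
        out = call_methylated_sites(sites, 0.01)
        assert out["p_value"].iloc[0] == 1.0
        assert out["call"].iloc[0] == "unmethylated"

    def test_saturated_site_has_binomial_tail_p(self):
        sites = _sites([("c", 0, "+", "CG", 10, 10)])
        out = call_methylated_sites(sites, 0.01)
        assert out["p_value"].iloc[0] == pytest.approx(1e-20, rel=1e-9)
        assert out["call"].iloc[0] == "methylated"

    def test_p_values_match_exact_binomial_tails(self):
        rows = []
        for n in range(5, 51):
            for k in range(0, n + 1, 7):
                rows.append(("c", len(rows), "+", "CG", k, n))
        sites = _sites(rows)
        out = call_methylated_sites(sites, 0.03)
        for r in out.itertuples(index=False):
            oracle = sum(
                stats.binom.pmf(k, r.c_total, 0.03)
                for k in range(r.c_meth, r.c_total + 1)
            )
            assert r.p_value == pytest.approx(oracle, rel=1e-8, abs=1e-12)

    def test_bh_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        n = 10_000
        sites = _sites([
            ("c", i, "+", "CG", int(k), 20)
            for i, k in enumerate(rng.binomial(20, rng.uniform(0.01, 0.9, n)))
        ])
        out = call_methylated_sites(sites, 0.01)
        p = out["p_value"].to_numpy()
        order = np.argsort(p, kind="stable")
        ranked = p[order] * n / (np.arange(n) + 1)
        oracle = np.minimum.accumulate(ranked[::-1])[::-1]
        oracle_full = np.empty(n)
        oracle_full[order] = np.minimum(oracle, 1.0)
        np.testing.assert_allclose(out["q_value"].to_numpy(), oracle_full,
                                   rtol=1e-10)


class TestWeightedLevels:
    def test_two_site_formula(self):
        sites = _sites([("c", 10, "+", "CG", 5, 5), ("c", 20, "+", "CG", 0, 5)])
        region = weighted_methylation_level(sites, "c", 0, 100, "CG")
        assert region.level == 0.5
        assert region.n_sites == 2

    def test_single_site(self):
        sites = _sites([("c", 10, "+", "CG", 3, 4)])
        assert weighted_methylation_level(sites, "c", 0, 100, "CG").level == 0.75

    def test_empty_region_is_undefined(self):
        region = weighted_methylation_level(_sites([]), "c", 0, 100, "CG")
        assert not region.defined
        assert np.isnan(region.level)

    def test_matches_brute_force_on_random_sites(self):
        rng = np.random.default_rng(5)
        rows = [("c", int(p), "+", "CG", int(m), int(m + u))
                for p, m, u in zip(rng.integers(0, 1000, 50),
                                   rng.integers(0, 30, 50),
                                   rng.integers(1, 30, 50))]
        sites = _sites(rows)
        region = weighted_methylation_level(sites, "c", 0, 1000, "CG")
        num = sum(m for _, p, _, _, m, t in rows if 0 <= p < 1000)
        den = sum(t for _, p, _, _, m, t in rows if 0 <= p < 1000)
        assert region.level == pytest.approx(num / den)

    def test_equal_depth_equals_unweighted_mean(self):
        rng = np.random.default_rng(6)
        ks = rng.integers(0, 11, 40)
        sites = _sites([("c", i, "+", "CG", int(k), 10) for i, k in enumerate(ks)])
        region = weighted_methylation_level(sites, "c", 0, 100, "CG")
        assert region.level == pytest.approx(np.mean(ks / 10))

    def test_interval_levels_match_scalar_path(self):
        rng = np.random.default_rng(8)
        rows = [("c", int(p), "+", "CG", int(m), int(m + 1))
                for p, m in zip(rng.integers(0, 500, 80), rng.integers(0, 5, 80))]
        sites = _sites(rows)
        ivs = pd.DataFrame({"chrom": ["c", "c"], "start": [0, 100],
                            "end": [250, 400]})
        out = interval_weighted_levels(sites, ivs, context="CG")
        for i, (s, e) in enumerate([(0, 250), (100, 400)]):
            ref = weighted_methylation_level(sites, "c", s, e, "CG")
            assert out["level"].iloc[i] == pytest.approx(ref.level)
            assert out["n_sites"].iloc[i] == ref.n_sites


class TestHistogramAndShare:
    def test_boundary_levels_land_in_half_open_bins(self):
        sites = _sites([
            ("c", 0, "+", "CG", 10, 10),   # level 1.0 -> closed top bin
            ("c", 1, "+", "CG", 1, 10),    # level 0.10 -> second bin
            ("c", 2, "+", "CG", 0, 10),    # level 0 -> first bin
        ])
        hist = methylation_level_histogram(sites)
        assert hist.loc[9, "CG"] == 1
        assert hist.loc[1, "CG"] == 1
        assert hist.loc[0, "CG"] == 1
        assert hist["CG"].sum() == 3

    def test_uniform_levels_fill_bins_evenly(self):
        rng = np.random.default_rng(13)
        lv = rng.uniform(0, 1, 20_000)
        sites = _sites([("c", i, "+", "CHH", int(round(x * 100)), 100)
                        for i, x in enumerate(lv)])
        hist = methylation_level_histogram(sites)
        assert hist["CHH"].sum() == 20_000
        assert (hist["CHH"] > 1600).all() and (hist["CHH"] < 2400).all()

    def test_context_share_sums_to_one(self):
        sites = _sites([("c", i, "+", ctx, 10, 10)
                        for i, ctx in enumerate(["CG", "CG", "CHG", "CHH"])])
        out = call_methylated_sites(sites, 0.01)
        share = context_share(out)
        assert sum(share.values()) == pytest.approx(1.0)
        assert share["CG"] == pytest.approx(0.5)
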