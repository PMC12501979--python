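"""SV grouping, divergence grades, ASM detection and overlap statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methaplo.allele_sv import (
    compare_asmr_sv,
    fc_by_grade,
    grade_delta,
    group_sv_records,
    overlap_sv_alleles,
    sv_category_counts,
    sv_category_total,
    sv_location_test,
    validate_breakpoints,
)
from methaplo.io import GeneModel, SvRecord


def _sv(raw, length=100, copy_status="-", chrom="c", start=1000):
    return SvRecord(raw, chrom, start, start + length, chrom, start,
                    start + (1 if raw == "INS" else length),
                    copy_status=copy_status)


class TestSvGrouping:
    @pytest.mark.parametrize("raw,length,status,expected", [
        ("TRANS", 500, "-", "TRANS"),
        ("INVTR", 500, "-", "TRANS"),
        ("INV", 500, "-", "INV"),
        ("CPL", 500, "-", "AV"),
        ("DEL", 51, "-", "AV"),
        ("DEL", 50, "-", "short"),
        ("CPG", 500, "-", "PV"),
        ("INS", 51, "-", "PV"),
        ("INS", 50, "-", "short"),
        ("DUP", 500, "copygain", "PV"),
        ("DUP", 500, "copyloss", "AV"),
        ("INVDP", 500, "copygain", "PV"),
        ("INVDP", 500, "copyloss", "AV"),
        ("SYN", 5000, "-", "SYN"),
        ("SNP", 1, "-", "SNP"),
    ])
    def test_grouping_table(self, raw, length, status, expected):
        rec = _sv(raw, length, status)
        group_sv_records([rec])
        assert rec.grouped_category == expected

    def test_ins_query_length_drives_the_50bp_rule(self):
        rec = SvRecord("INS", "c", 100, 101, "c", 100, 160)  # 60 bp insertion
        group_sv_records([rec])
        assert rec.length == 60
        assert rec.grouped_category == "PV"

    def test_dup_without_copy_status_rejected(self):
        with pytest.raises(ValueError):
            group_sv_records([_sv("DUP", 500)])

    def test_category_partition_invariant(self):
        rng = np.random.default_rng(23)
        raws = rng.choice(["TRANS", "INVTR", "INV", "CPL", "DEL", "CPG", "INS",
                           "DUP", "INVDP"], 200)
        recs = []
        for raw in raws:
            status = rng.choice(["copygain", "copyloss"]) if raw in ("DUP", "INVDP") else "-"
            recs.append(_sv(str(raw), int(rng.integers(10, 400)), str(status)))
        group_sv_records(recs)
        counts = sv_category_counts(recs)
        assert counts.sum() == len(recs)
        assert all(r.grouped_category in
                   {"TRANS", "INV", "AV", "PV", "short"} for r in recs)

    def test_category_total_accounting(self):
        assert sv_category_total({"TRANS": 3, "INV": 1, "AV": 4, "PV": 2,
                                  "short": 99}) == 10


class TestGrades:
    @pytest.mark.parametrize("delta,context,grade", [
        (30, "CG", 1), (-30, "CG", 1), (25, "CG", 1), (24.9, "CG", 0),
        (50, "CG", 2), (74.9, "CHG", 2), (75, "CG", 3), (99.9, "CG", 3),
        (100, "CG", 0),
        (15, "CHH", 1), (34.9, "CHH", 1), (35, "CHH", 2), (54.9, "CHH", 2),
        (55, "CHH", 0), (60, "CHH", 0),
    ])
    def test_half_open_grade_boundaries(self, delta, context, grade):
        assert grade_delta(delta, context) == grade

    def test_vectorized_matches_scalar(self):
        deltas = np.array([10.0, 30.0, 60.0, 80.0, -90.0])
        vec = grade_delta(deltas, "CG")
        assert vec.tolist() == [grade_delta(float(d), "CG") for d in deltas]


class TestFcByGrade:
    def _bins(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "context",
                                           "pair_id", "delta", "is_asmr"])

    def test_pairs_grouped_by_best_grade(self):
        bins = self._bins([
            ("c", 0, 200, "CG", "p1", 30.0, True),
            ("c", 0, 200, "CG", "p2", 60.0, True),
            ("c", 0, 200, "CG", "p3", 85.0, True),
            ("c", 0, 200, "CG", "p4", 10.0, True),   # ungraded
        ])
        ase = pd.DataFrame({"bias_class": ["M", "M", "P", "M"],
                            "log2fc": [0.5, -1.5, 2.5, 3.0]},
                           index=["p1", "p2", "p3", "p4"])
        merged, tests = fc_by_grade(bins, ase, "CG")
        assert merged["grade"].tolist() == [1, 2, 3]
        assert merged["abs_log2fc"].tolist() == [0.5, 1.5, 2.5]
        assert len(tests) == 0  # all groups have a single member

    def test_single_pair_degenerate(self):
        bins = self._bins([("c", 0, 200, "CG", "p1", 30.0, True)])
        ase = pd.DataFrame({"bias_class": ["M"], "log2fc": [1.0]}, index=["p1"])
        merged, tests = fc_by_grade(bins, ase, "CG")
        assert len(merged) == 1 and len(tests) == 0


class TestWilcoxonAndChiSquare:
    def test_rank_sum_matches_enumeration_on_known_ranks(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        # enumeration oracle over all 20 assignments of ranks to group a
        more_extreme = 0
        obs = sum(a)
        for combo in itertools.combinations(range(1, 7), 3):
            s = sum(combo)
            if abs(s - 10.5) >= abs(obs - 10.5) - 1e-9:
                more_extreme += 1
        oracle = more_extreme / 20
        assert p == pytest.approx(oracle)

    def test_compare_asmr_sv_uses_that_exact_test(self):
        bins = pd.DataFrame({
            "chrom": "c", "start": [0, 100, 200, 5000, 5100, 5200],
            "end": [200, 300, 400, 5200, 5300, 5400], "context": "CG",
            "pair_id": "p", "delta": [10.0, 20.0, 30.0, 40.0, 50.0, 60.0],
            "is_asmr": True,
        })
        svs = [SvRecord("DEL", "c", 5000, 5400, "c", 5000, 5001,
                        grouped_category="AV")]
        out = compare_asmr_sv(bins, svs)
        row = out[out["context"] == "CG"].iloc[0]
        assert row["n_sv"] == 3 and row["n_non_sv"] == 3
        assert row["p_value"] == pytest.approx(0.1)
        assert row["median_sv"] == 50.0

    def test_identical_delta_sets_are_null(self):
        bins = pd.DataFrame({
            "chrom": "c", "start": [0, 5000], "end": [200, 5200],
            "context": "CG", "pair_id": "p", "delta": [30.0, 30.0],
            "is_asmr": True,
        })
        svs = [SvRecord("INS", "c", 5000, 5001, "c", 0, 400,
                        grouped_category="PV")]
        out = compare_asmr_sv(bins, svs)
        assert out["p_value"].iloc[0] == 1.0

    def test_chi_square_proportional_rows_are_null(self):
        res = sv_location_test(pd.DataFrame([[10, 20, 30], [1, 2, 3]]))
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_chi_square_closed_form_oracle(self):
        res = sv_location_test(pd.DataFrame([[10, 0, 0], [0, 10, 0]]))
        # informative 2x2 sub-table [[10,0],[0,10]]: chi2 = N = 20
        assert res["statistic"] == pytest.approx(20.0)

    def test_chi_square_df_two_for_full_table(self):
        res = sv_location_test(pd.DataFrame([[10, 5, 2], [3, 8, 6]]))
        assert res["df"] == 2
        obs = np.array([[10, 5, 2], [3, 8, 6]], dtype=float)
        exp = obs.sum(1, keepdims=True) * obs.sum(0) / obs.sum()
        assert res["statistic"] == pytest.approx(((obs - exp) ** 2 / exp).sum())


class TestSvOverlap:
    def test_intergenic_sv_flags_no_gene(self):
        genes = [GeneModel("g", "c", "+", 10_000, 12_000,
                           exons=[(10_000, 12_000)])]
        svs = [SvRecord("DEL", "c", 50_000, 50_100, "c", 50_000, 50_001,
                        grouped_category="AV")]
        counts, flags = overlap_sv_alleles(svs, genes, {"g"})
        assert counts["n_multi"].sum() == 0
        assert not flags["allele_sv"].any()

    def test_exon_intron_junction_counts_both(self):
        genes = [GeneModel("g", "c", "+", 10_000, 14_000,
                           exons=[(10_000, 11_000), (12_000, 14_000)])]
        svs = [SvRecord("DEL", "c", 10_900, 11_200, "c", 10_900, 10_901,
                        grouped_category="AV")]
        counts, flags = overlap_sv_alleles(svs, genes, {"g"})
        assert counts.loc["exon", "n_multi"] == 1
        assert counts.loc["intron", "n_multi"] == 1
        assert flags["allele_sv"].iloc[0]

    def test_random_placement_matches_interval_oracle(self):
        rng = np.random.default_rng(29)
        genes = [GeneModel(f"g{i}", "c", "+", s, s + 3000,
                           exons=[(s, s + 1000), (s + 2000, s + 3000)])
                 for i, s in enumerate(range(10_000, 80_000, 12_000))]
        svs = []
        for s in rng.integers(0, 90_000, 200):
            sv = SvRecord("DEL", "c", int(s), int(s) + 150, "c", int(s),
                          int(s) + 1, grouped_category="AV")
            svs.append(sv)
        counts, flags = overlap_sv_alleles(svs, genes, {g.gene_id for g in genes})
        flank = 2000
        oracle = 0
        for sv, g in itertools.product(svs, genes):
            if sv.ref_start < g.end + flank and sv.ref_end > g.start - flank:
                # promoter (upstream) overlap for + strand
                if sv.ref_start < g.start and sv.ref_end > g.start - flank:
                    oracle += 1
        assert counts.loc["promoter", "n_multi"] == oracle


class TestBreakpointValidation:
    def test_no_reads_no_support(self):
        reads = pd.DataFrame(columns=["chrom", "start", "end"])
        svs = [SvRecord("INV", "c", 1000, 2000, "c", 1000, 2000,
                        grouped_category="INV")]
        out = validate_breakpoints(reads, svs)
        assert out["support"].iloc[0] == 0

    def test_25kb_read_is_high_confidence_support(self):
        reads = pd.DataFrame([{"chrom": "c", "start": 0, "end": 25_000}])
        svs = [SvRecord("INV", "c", 10_000, 12_000, "c", 10_000, 12_000,
                        grouped_category="INV")]
        out = validate_breakpoints(reads, svs)
        assert out["support"].iloc[0] == 1
        assert out["support_hc"].iloc[0] == 1

    def test_19kb_read_supports_but_not_high_confidence(self):
        reads = pd.DataFrame([{"chrom": "c", "start": 0, "end": 19_000}])
        svs = [SvRecord("DEL", "c", 9_000, 9_100, "c", 9_000, 9_001,
                        grouped_category="AV")]
        out = validate_breakpoints(reads, svs)
        assert out["support"].iloc[0] == 1
        assert out["support_hc"].iloc[0] == 0

    def test_random_tiling_matches_stabbing_oracle(self):
        rng = np.random.default_rng(31)
        starts = rng.integers(0, 100_000, 300)
        lens = rng.integers(5_000, 30_000, 300)
        reads = pd.DataFrame({"chrom": "c", "start": starts,
                              "end": starts + lens})
        svs = [SvRecord("INV", "c", int(b), int(b) + 500, "c", int(b),
                        int(b) + 500, grouped_category="INV")
               for b in rng.integers(10_000, 90_000, 20)]
        out = validate_breakpoints(reads, svs)
        for row, sv in zip(out.itertuples(index=False), svs):
            oracle = min(
                sum(1 for s, e in zip(starts, starts + lens)
                    if s <= bp - 500 and e >= bp + 500)
                for bp in (sv.ref_start, sv.ref_end)
            )
            assert row.support == oracle
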