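"""End-to-end pipeline orchestration and the structured summary report.

``run_pipeline`` chains every stage on a simulated study directory:
methylation calling, genome-wide summaries, DMR detection and
intersections, feature annotation, metaplots, expression analysis, ASE/ASM
classification and SV integration — then writes one TSV per summary panel
plus a run manifest. All outputs are deterministically ordered and
formatted, so a re-run with the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import allele_sv as asv
from . import dmr as dmrmod
from . import expression as expr
from . import features as feat
from . import io as mio
from . import methylome as meth
from . import stats as st
from .config import CONTEXTS, RunConfig
from .simulate import SimulationSpec, simulate_study

log = logging.getLogger("methaplo")

FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A stage output required by the report is missing."""


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def per_gene_bin_levels(
    sites: pd.DataFrame,
    genes: list,
    config: RunConfig,
) -> pd.DataFrame:
    """Weighted level per (gene, metaplot bin, context) for one sample."""
    n_bins = 2 * config.flank_bins + config.body_bins
    flank_bp = config.flank_size // config.flank_bins
    by_chrom = {
        c: g.sort_values("pos", kind="mergesort") for c, g in sites.groupby("chrom")
    }
    rows = []
    for g in genes:
        grp = by_chrom.get(g.chrom)
        if grp is None or (g.end - g.start) < config.body_bins:
            continue
        pos_all = grp["pos"].to_numpy()
        lo = np.searchsorted(pos_all, g.start - config.flank_size)
        hi = np.searchsorted(pos_all, g.end + config.flank_size)
        win = grp.iloc[lo:hi]
        p = win["pos"].to_numpy()
        rel = np.full(p.size, -1, dtype=np.int64)
        up = p < g.start
        body = (p >= g.start) & (p < g.end)
        down = p >= g.end
        rel[up] = config.flank_bins - 1 - (g.start - 1 - p[up]) // flank_bp
        rel[body] = config.flank_bins + (
            (p[body] - g.start) * config.body_bins // (g.end - g.start)
        )
        rel[down] = config.flank_bins + config.body_bins + (p[down] - g.end) // flank_bp
        ok = (rel >= 0) & (rel < n_bins)
        rel = rel[ok]
        win = win.iloc[np.nonzero(ok)[0]]
        if g.strand == "-":
            rel = n_bins - 1 - rel
        ctx_arr = win["context"].to_numpy()
        for c in CONTEXTS:
            sel = ctx_arr == c
            if not sel.any():
                continue
            m = np.bincount(rel[sel], weights=win["c_meth"].to_numpy()[sel],
                            minlength=n_bins)
            t = np.bincount(rel[sel], weights=win["c_total"].to_numpy()[sel],
                            minlength=n_bins)
            nz = np.nonzero(t)[0]
            for b in nz:
                rows.append((g.gene_id, int(b), c, m[b] / t[b]))
    return pd.DataFrame(rows, columns=["gene_id", "bin", "context", "level"])


def _pool_reps(rep_frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum replicate counts site-wise (frames share site order by contract)."""
    pooled = rep_frames[0].copy()
    for other in rep_frames[1:]:
        if len(other) != len(pooled):
            raise PipelineError("replicate reports disagree on site universe")
        pooled["c_meth"] = pooled["c_meth"].to_numpy() + other["c_meth"].to_numpy()
        pooled["c_total"] = pooled["c_total"].to_numpy() + other["c_total"].to_numpy()
    return pooled


def run_pipeline(
    spec: SimulationSpec,
    outdir: str | Path,
    config: RunConfig | None = None,
    control: str = "AZA0-7",
) -> dict:
    """Simulate a study and run every analysis stage; write the report.

    Returns a dict of in-memory stage outputs (also used by the tests).
    """
    cfg = config or RunConfig()
    outdir = Path(outdir)
    simdir = outdir / "sim"
    repdir = outdir / "report"
    repdir.mkdir(parents=True, exist_ok=True)

    study, mtruth = simulate_study(spec, simdir)
    sample_names = [s.name for s in spec.samples]
    if control not in sample_names:
        control = next(s.name for s in spec.samples if s.role == "control")
    epimutants = [s.name for s in spec.samples if s.role == "epimutant"]

    genes = mio.read_gff3(simdir / "genes_hap1.gff3")
    tes = mio.read_te_gff3(simdir / "tes.gff3")
    pairs = mio.read_allele_pairs(simdir / "allele_pairs.tsv")
    svs = mio.read_syri_table(simdir / "syri.tsv")
    genome = mio.read_fasta(simdir / "hap1.fa")
    genes_by_id = {g.gene_id: g for g in genes}

    results: dict = {"config": cfg, "control": control}

    # ---- per-sample load, calling, windows, ASM --------------------------
    conv_rows = []
    summary_rows = []
    hist_frames = []
    share_rows = []
    pooled_sites: dict[str, pd.DataFrame] = {}
    win_by_sample: dict[str, pd.DataFrame] = {}
    asmr_by_sample: dict[str, pd.DataFrame] = {}
    chrom_lengths = {c: len(s) for c, s in genome.items()}

    for name in sample_names:
        reps = [
            mio.read_cytosine_report(
                simdir / "reports" / f"{name}_rep{r + 1}_hap1.tsv", cfg.depth_min
            )
            for r in range(spec.replicates)
        ]
        lam = _pool_reps([r[r["chrom"] == "lambda"].reset_index(drop=True)
                          for r in reps])
        err = meth.estimate_conversion_error(lam)
        conv_rows.append({"sample": name, **{f"error_{k}": v for k, v in err.items()}})
        gen_reps = [r[r["chrom"] != "lambda"].reset_index(drop=True) for r in reps]
        pooled = _pool_reps(gen_reps)
        called = meth.call_methylated_sites(
            pooled, err["pooled"], cfg.depth_min, cfg.q_threshold
        )
        pooled_sites[name] = called
        gsum = meth.genome_wide_levels(called, cfg.depth_min)
        gsum.insert(0, "sample", name)
        summary_rows.append(gsum)
        hist = meth.methylation_level_histogram(called, depth_min=cfg.depth_min)
        hist.insert(0, "sample", name)
        hist_frames.append(hist.reset_index())
        share = meth.context_share(called)
        share_rows.append({"sample": name, **share})
        win_by_sample[name] = dmrmod.window_replicate_counts(
            gen_reps, chrom_lengths, cfg.window_size, cfg.step_size
        )
        # ASM: maternal = hap1 gene space, paternal = hap2 allele reports
        pat_reps = [
            mio.read_cytosine_report(
                simdir / "reports" / f"{name}_rep{r + 1}_hap2pairs.tsv", cfg.depth_min
            )
            for r in range(spec.replicates)
        ]
        # paternal positions are lifted to hap1 coordinates through the
        # inter-haplotype alignment (anchor map), so bins tile one space
        pat_mapped = [_map_paternal_to_ref(p, study) for p in pat_reps]
        asmr_by_sample[name] = asv.detect_asmrs(
            gen_reps, pat_mapped, pairs, genes_by_id, cfg
        )
        del reps, gen_reps, pat_reps, pat_mapped

    _write(pd.DataFrame(conv_rows), repdir / "conversion_rates.tsv")
    _write(pd.concat(summary_rows, ignore_index=True),
           repdir / "panel3c_genome_levels.tsv")
    _write(pd.concat(hist_frames, ignore_index=True),
           repdir / "panel3d_level_histogram.tsv")
    _write(pd.DataFrame(share_rows), repdir / "panel3b_context_share.tsv")

    # ---- DMRs -------------------------------------------------------------
    dmr_sets: dict[str, pd.DataFrame] = {}
    dmr_count_rows = []
    comparisons = [(e, control) for e in epimutants]
    other_control = [s for s in sample_names
                     if s not in epimutants and s != control]
    null_comparison = (other_control[0], control) if other_control else None
    if null_comparison:
        comparisons.append(null_comparison)
    tested_by_comparison = {}
    for test_name, ctrl_name in comparisons:
        combined = _combine_windows(win_by_sample[test_name],
                                    win_by_sample[ctrl_name], spec.replicates)
        tested = dmrmod.test_windows_table(combined, spec.replicates,
                                           spec.replicates)
        tested_by_comparison[(test_name, ctrl_name)] = tested
        dmrs = dmrmod.call_dmrs(tested, cfg)
        if test_name in epimutants:
            dmr_sets[test_name] = dmrs
        for ctx in CONTEXTS:
            sub = dmrs[dmrs["context"] == ctx]
            dmr_count_rows.append({
                "comparison": f"{test_name}_vs_{ctrl_name}", "context": ctx,
                "n_dmrs": len(sub),
                "n_hyper": int((sub["direction"] == "hyper").sum()),
                "n_hypo": int((sub["direction"] == "hypo").sum()),
            })
    results["tested_windows"] = tested_by_comparison
    results["dmr_sets"] = dmr_sets
    _write(pd.DataFrame(dmr_count_rows), repdir / "panel4_dmr_counts.tsv")
    for name, dmrs in dmr_sets.items():
        mio.write_bed(
            [{"chrom": r.chrom, "start": r.start, "end": r.end,
              "level": r.level_test / 100} for r in dmrs.itertuples(index=False)],
            repdir / f"dmrs_{name}.bed",
        )

    clusters = dmrmod.intersect_dmr_sets(dmr_sets)
    subset_counts = dmrmod.intersection_subset_counts(clusters, sorted(dmr_sets))
    clusters_pos = dmrmod.intersect_dmr_sets(dmr_sets, same_direction=False)
    n_all_dir = int((clusters["n_samples"] == len(dmr_sets)).sum()) if len(clusters) else 0
    n_all_pos = int((clusters_pos["n_samples"] == len(dmr_sets)).sum()) if len(clusters_pos) else 0
    _write(
        subset_counts.rename_axis("subset").rename("n_clusters").reset_index(),
        repdir / "panel4a_dmr_intersections.tsv",
    )
    results["dmr_clusters"] = clusters
    results["shared_by_all"] = {"same_direction": n_all_dir,
                                "position_only": n_all_pos}

    # feature annotation of DMRs (panel 4B)
    prop_rows = []
    dmg_sets: dict[tuple, set] = {}
    for name, dmrs in dmr_sets.items():
        for ctx in CONTEXTS:
            for direction in ("hyper", "hypo"):
                sub = dmrs[(dmrs["context"] == ctx)
                           & (dmrs["direction"] == direction)]
                if len(sub):
                    ann = feat.annotate_regions(
                        sub[["chrom", "start", "end"]], genes, cfg.promoter_size
                    )
                    props = feat.feature_proportions(ann)
                else:
                    props = pd.Series(0.0, index=feat.FEATURE_PRIORITY)
                prop_rows.append({"sample": name, "context": ctx,
                                  "direction": direction, "n": len(sub),
                                  **props.to_dict()})
                dmg_sets[(name, ctx, direction)] = feat.call_dmgs(
                    sub, genes, cfg.flank_size
                )
    _write(pd.DataFrame(prop_rows), repdir / "panel4b_dmr_features.tsv")
    results["dmg_sets"] = dmg_sets

    common = dmrmod.common_dmr_levels(clusters, pooled_sites, min_shared=2,
                                      depth_min=cfg.depth_min)
    if len(common):
        _write(common[["sample", "context", "direction", "chrom", "start", "end",
                       "n_sites", "level"]],
               repdir / "panel4d_common_dmr_levels.tsv")

    # ---- metaplots --------------------------------------------------------
    gene_feat = pd.DataFrame(
        [{"chrom": g.chrom, "start": g.start, "end": g.end, "strand": g.strand}
         for g in genes]
    )
    te_feat = tes.copy()
    te_feat["strand"] = "+"
    meta_frames = []
    for name in sample_names:
        covered = pooled_sites[name]
        covered = covered[covered["c_total"] >= cfg.depth_min]
        for label, feats in (("genes", gene_feat), ("TEs", te_feat)):
            mp = feat.metaprofile(covered, feats, cfg.body_bins, cfg.flank_bins,
                                  cfg.flank_size)
            mp.insert(0, "sample", name)
            mp.insert(1, "feature_set", label)
            meta_frames.append(mp)
    metaplot = pd.concat(meta_frames, ignore_index=True)
    _write(metaplot[["sample", "feature_set", "context", "bin", "level",
                     "n_features"]], repdir / "panel3ef_metaplots.tsv")
    results["metaplot"] = metaplot

    # ---- expression -------------------------------------------------------
    counts = mio.read_count_matrix(simdir / "gene_counts.tsv")
    lengths = pd.Series({g.gene_id: g.union_exon_length for g in genes})
    tpm_cols = expr.compute_tpm(counts, lengths)
    sample_tpm = pd.DataFrame({
        name: tpm_cols[[f"{name}_rep{r + 1}" for r in range(spec.replicates)]]
        .mean(axis=1)
        for name in sample_names
    })
    ranks = expr.rank_expression(sample_tpm)
    _write(sample_tpm.reset_index().rename(columns={"index": "gene_id"}),
           repdir / "tpm.tsv")

    deg_tables = {}
    deg_rows = []
    for e in epimutants:
        deg = expr.call_degs(
            counts,
            [f"{e}_rep{r + 1}" for r in range(spec.replicates)],
            [f"{control}_rep{r + 1}" for r in range(spec.replicates)],
        )
        deg_tables[e] = deg
        deg_rows.append({"sample": e,
                         "n_up": int((deg["deg_status"] == "up").sum()),
                         "n_down": int((deg["deg_status"] == "down").sum())})
    _write(pd.DataFrame(deg_rows), repdir / "panel5d_deg_counts.tsv")
    results["deg_tables"] = deg_tables

    # gene-region methylation by expression rank (panels 5A-C)
    region_intervals = feat.gene_region_intervals(genes, cfg.flank_size)
    rank_rows = []
    gene_region_levels: dict[tuple, pd.DataFrame] = {}
    for name in sample_names:
        covered = pooled_sites[name]
        for region, ivs in region_intervals.items():
            for ctx in CONTEXTS:
                lv = meth.interval_weighted_levels(
                    covered, ivs, context=ctx, depth_min=cfg.depth_min
                )
                lv = lv.set_index(ivs["gene_id"])["level"]
                gene_region_levels[(name, region, ctx)] = lv
                summary, _pw, letters = st.meth_by_expression_rank(
                    lv, ranks[name], alpha=0.01
                )
                for row in summary.itertuples(index=False):
                    rank_rows.append({"sample": name, "region": region,
                                      "context": ctx, **row._asdict()})
    _write(pd.DataFrame(rank_rows), repdir / "panel5abc_meth_by_rank.tsv")
    results["gene_region_levels"] = gene_region_levels

    # methylation categories per rank group (gene body CG, per sample)
    cat_rows = []
    for name in sample_names:
        lv = gene_region_levels[(name, "body", "CG")].dropna()
        fr = st.category_fractions(lv, ranks[name].reindex(lv.index))
        fr.insert(0, "sample", name)
        cat_rows.append(fr.reset_index(names="group"))
    _write(pd.concat(cat_rows, ignore_index=True),
           repdir / "methylation_categories.tsv")

    # DMG x DEG enrichment
    universe = set(counts.index)
    fisher_rows = []
    for e in epimutants:
        deg_set = set(deg_tables[e].index[deg_tables[e]["deg_status"] != "ns"])
        for ctx in CONTEXTS:
            dmg = dmg_sets.get((e, ctx, "hyper"), set()) | dmg_sets.get(
                (e, ctx, "hypo"), set()
            )
            res = st.dmg_deg_enrichment(dmg, deg_set, universe)
            fisher_rows.append({"sample": e, "context": ctx,
                                "n_dmg": len(dmg & universe),
                                "n_deg": len(deg_set),
                                "p_value": res["p_value"],
                                "odds_ratio": res["odds_ratio"]})
    _write(pd.DataFrame(fisher_rows), repdir / "dmg_deg_enrichment.tsv")
    results["fisher"] = fisher_rows

    # bin-wise correlation (panel 5E) and TE fluctuation
    bin_frames = []
    for name in sample_names:
        bl = per_gene_bin_levels(
            pooled_sites[name][pooled_sites[name]["c_total"] >= cfg.depth_min],
            genes, cfg,
        )
        bl = bl.rename(columns={"level": name})
        bin_frames.append(bl.set_index(["gene_id", "bin", "context"]))
    bin_levels = pd.concat(bin_frames, axis=1).reset_index()
    corr = st.binwise_expression_correlation(
        bin_levels, sample_tpm, min_samples=min(6, len(sample_names))
    )
    sign_counts = st.correlation_sign_counts(corr)
    _write(sign_counts, repdir / "panel5e_correlation_counts.tsv")
    body_mask = (corr["bin"] >= cfg.flank_bins) & (
        corr["bin"] < cfg.flank_bins + cfg.body_bins
    )
    te_flags = pd.Series({g.gene_id: g.is_te_overlapping for g in genes})
    fluct = st.te_fluctuation(corr[body_mask], te_flags)
    _write(fluct, repdir / "te_fluctuation.tsv")
    results["correlation"] = corr
    results["sign_counts"] = sign_counts
    results["te_fluctuation"] = fluct

    # ---- ASE / ASM --------------------------------------------------------
    maternal = mio.read_count_matrix(simdir / "allele_counts_maternal.tsv")
    paternal = mio.read_count_matrix(simdir / "allele_counts_paternal.tsv")
    ase_by_sample = {}
    ase_rows = []
    for name in sample_names:
        cols = [f"{name}_rep{r + 1}" for r in range(spec.replicates)]
        ase = expr.classify_ase(maternal[cols], paternal[cols])
        ase_by_sample[name] = ase
        vc = ase["bias_class"].value_counts()
        ase_rows.append({"sample": name,
                         "n_M": int(vc.get("M", 0)), "n_P": int(vc.get("P", 0)),
                         "n_U": int(vc.get("U", 0))})
    _write(pd.DataFrame(ase_rows), repdir / "panel6a_ase_counts.tsv")
    results["ase"] = ase_by_sample

    cross_frames = []
    for e in epimutants:
        tab = expr.crosstab_bias(ase_by_sample[e]["bias_class"],
                                 ase_by_sample[control]["bias_class"])
        tab = tab.reset_index(names="epimutant_class")
        tab.insert(0, "sample", e)
        cross_frames.append(tab)
    _write(pd.concat(cross_frames, ignore_index=True),
           repdir / "panel6b_bias_crosstab.tsv")

    results["asmr"] = asmr_by_sample
    asmg_rows = []
    for name in sample_names:
        flags = asv.asmg_flags(asmr_by_sample[name], pairs)
        cls = ase_by_sample[name]["bias_class"].copy()
        cls.index = pairs["pair_id"]
        for c in ("M", "P", "U"):
            for is_asmg in (True, False):
                n = int(((cls == c) & (flags == is_asmg)).sum())
                asmg_rows.append({"sample": name, "bias_class": c,
                                  "asmg": is_asmg, "n": n})
    _write(pd.DataFrame(asmg_rows), repdir / "panel6c_ase_asmg.tsv")

    grade_frames = []
    grade_test_frames = []
    for name in sample_names:
        for ctx in ("CG", "CHG"):
            merged, tests = asv.fc_by_grade(asmr_by_sample[name],
                                            ase_by_sample[name], ctx)
            merged = merged.reset_index().rename(columns={"index": "pair_id"})
            merged.insert(0, "sample", name)
            merged.insert(1, "context", ctx)
            grade_frames.append(merged)
            if len(tests):
                tests.insert(0, "sample", name)
                tests.insert(1, "context", ctx)
                grade_test_frames.append(tests)
    _write(pd.concat(grade_frames, ignore_index=True),
           repdir / "panel6de_fc_by_grade.tsv")
    if grade_test_frames:
        _write(pd.concat(grade_test_frames, ignore_index=True),
               repdir / "panel6de_grade_tests.tsv")
    results["grade_tests"] = grade_test_frames

    # ---- SVs --------------------------------------------------------------
    grouped = asv.group_sv_records(svs)
    cat_counts = asv.sv_category_counts(grouped)
    _write(cat_counts.rename_axis("category").rename("n").reset_index(),
           repdir / "sv_category_counts.tsv")
    results["sv_counts"] = cat_counts

    pair_gene_ids = set(pairs["maternal_id"])
    feat_counts, gene_flags = asv.overlap_sv_alleles(grouped, genes,
                                                     pair_gene_ids,
                                                     cfg.flank_size)
    _write(feat_counts.reset_index(names="feature"),
           repdir / "panel7a_sv_features.tsv")
    results["sv_feature_counts"] = feat_counts

    ase_ck = ase_by_sample[control]["bias_class"].copy()
    ase_ck.index = pairs["maternal_id"].to_numpy()
    asmg_ck = asv.asmg_flags(asmr_by_sample[control], pairs)
    asmg_ck.index = pairs["maternal_id"].to_numpy()
    venn = {
        "total_pairs": len(pairs),
        "aseg": int((ase_ck != "U").sum()),
        "asmg": int(asmg_ck.sum()),
        "allele_sv": int(gene_flags["allele_sv"].sum()),
        "aseg_and_sv": int(((ase_ck != "U")
                            & gene_flags.set_index("gene_id")["allele_sv"]).sum()),
        "asmg_and_sv": int((asmg_ck
                            & gene_flags.set_index("gene_id")["allele_sv"]).sum()),
    }
    _write(pd.DataFrame([venn]), repdir / "panel7b_venn_counts.tsv")

    loc_table = _sv_location_table(grouped, genes, genes_by_id, pairs, ase_ck,
                                   cfg.flank_size)
    if (loc_table.to_numpy().sum(axis=1) > 0).all():
        chi = asv.sv_location_test(loc_table)
    else:
        chi = {"statistic": np.nan, "p_value": np.nan, "df": 2}
    _write(loc_table.reset_index(names="gene_class"),
           repdir / "panel7c_sv_location_table.tsv")
    _write(pd.DataFrame([chi]), repdir / "panel7c_sv_location_test.tsv")
    results["sv_location"] = {"table": loc_table, "test": chi}

    asmr_sv = asv.compare_asmr_sv(asmr_by_sample[control], grouped)
    _write(asmr_sv, repdir / "panel7d_asmr_sv.tsv")
    results["asmr_sv"] = asmr_sv

    reads = pd.read_csv(simdir / "hifi_reads.tsv", sep="\t")
    sv_only = [r for r in grouped
               if r.grouped_category in ("TRANS", "INV", "AV", "PV")]
    support = asv.validate_breakpoints(reads, sv_only)
    _write(support, repdir / "sv_breakpoint_support.tsv")
    results["sv_support"] = support

    # ---- manifest ---------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": spec.seed,
        "config": dataclasses.asdict(cfg),
        "n_samples": len(sample_names),
        "control": control,
        "replicates": spec.replicates,
        "n_genes": len(genes),
        "n_pairs": len(pairs),
        "n_sv_records": len(svs),
        "record_counts": {
            "dmrs": {k: len(v) for k, v in sorted(dmr_sets.items())},
            "asmr_bins": {k: int(v["is_asmr"].sum())
                          for k, v in sorted(asmr_by_sample.items())},
        },
    }
    with open(repdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    _check_report_complete(repdir)
    results["report_dir"] = repdir
    results["study"] = study
    results["truth"] = study.truth
    results["pooled_sites"] = pooled_sites
    return results


EXPECTED_PANELS = [
    "panel3b_context_share.tsv", "panel3c_genome_levels.tsv",
    "panel3d_level_histogram.tsv", "panel3ef_metaplots.tsv",
    "panel4_dmr_counts.tsv", "panel4a_dmr_intersections.tsv",
    "panel4b_dmr_features.tsv", "panel5abc_meth_by_rank.tsv",
    "panel5d_deg_counts.tsv", "panel5e_correlation_counts.tsv",
    "panel6a_ase_counts.tsv", "panel6b_bias_crosstab.tsv",
    "panel6c_ase_asmg.tsv", "panel6de_fc_by_grade.tsv",
    "panel7a_sv_features.tsv", "panel7b_venn_counts.tsv",
    "panel7c_sv_location_test.tsv", "panel7d_asmr_sv.tsv",
    "sv_category_counts.tsv", "sv_breakpoint_support.tsv",
    "conversion_rates.tsv", "manifest.json",
]


def _check_report_complete(repdir: Path) -> None:
    missing = [p for p in EXPECTED_PANELS if not (repdir / p).exists()]
    if missing:
        with open(repdir / "MISSING_PANELS.txt", "w") as fh:
            fh.write("\n".join(missing) + "\n")
        raise PipelineError(f"report incomplete, missing panels: {missing}")


def _map_paternal_to_ref(report: pd.DataFrame, study) -> pd.DataFrame:
    """Lift a hap2 allele-space report onto hap1 (reference) coordinates.

    Uses the inter-haplotype coordinate anchor map so maternal and paternal
    counts tile the same window space.
    """
    mapped = report.copy()
    pos = mapped["pos"].to_numpy().copy()
    for chrom in mapped["chrom"].unique():
        m = (mapped["chrom"] == chrom).to_numpy()
        pos[m] = study.query_to_ref(str(chrom), pos[m])
    mapped["pos"] = pos
    return mapped.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def _combine_windows(win_test: pd.DataFrame, win_ctrl: pd.DataFrame,
                     n_reps: int) -> pd.DataFrame:
    """Merge per-sample window tables into one test+control table."""
    key = ["chrom", "start", "end", "context"]
    a = win_test.set_index(key)
    b = win_ctrl.set_index(key)
    if not a.index.equals(b.index):
        raise PipelineError("window tables disagree between samples")
    out = a.copy()
    for r in range(n_reps):
        out[f"meth_{n_reps + r}"] = b[f"meth_{r}"]
        out[f"total_{n_reps + r}"] = b[f"total_{r}"]
    out["n_cyt"] = np.minimum(a["n_cyt"], b["n_cyt"])
    return out.reset_index()


def _sv_location_table(svs, genes, genes_by_id, pairs, ase_classes, flank):
    """2x3 table of SV counts at body/upstream/downstream for ASEG vs U."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            max(0, g.start - flank), g.end + flank, g
        )
    counts = {("ASEG", f): 0 for f in ("body", "upstream", "downstream")}
    counts.update({("unbiased", f): 0 for f in ("body", "upstream", "downstream")})
    for sv in svs:
        if sv.grouped_category not in ("TRANS", "INV", "AV", "PV"):
            continue
        tree = trees.get(sv.ref_chrom)
        if tree is None:
            continue
        for iv in tree.overlap(sv.ref_start, sv.ref_end):
            g = iv.data
            cls = ase_classes.get(g.gene_id)
            if cls is None:
                continue
            row = "ASEG" if cls in ("M", "P") else "unbiased"
            if g.strand == "+":
                up = (g.start - flank, g.start)
                down = (g.end, g.end + flank)
            else:
                up = (g.end, g.end + flank)
                down = (g.start - flank, g.start)
            if sv.ref_start < g.end and sv.ref_end > g.start:
                counts[(row, "body")] += 1
            if sv.ref_start < up[1] and sv.ref_end > up[0]:
                counts[(row, "upstream")] += 1
            if sv.ref_start < down[1] and sv.ref_end > down[0]:
                counts[(row, "downstream")] += 1
    tab = pd.DataFrame(
        {
            "body": [counts[("ASEG", "body")], counts[("unbiased", "body")]],
            "upstream": [counts[("ASEG", "upstream")],
                         counts[("unbiased", "upstream")]],
            "downstream": [counts[("ASEG", "downstream")],
                           counts[("unbiased", "downstream")]],
        },
        index=["ASEG", "unbiased"],
    )
    return tab
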