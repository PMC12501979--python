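"""Allele-specific methylation and structural-variant integration.

SyRI raw variant types are grouped into the major categories used for
inter-haplotype comparison: TRANS (incl. inverted translocations), INV,
AV (absent variations: losses/deletions), PV (present variations:
gains/insertions). Insertions/deletions of <= 50 bp are "short" variations
and excluded from the SV sets. DUP/INVDP resolve to PV or AV by whether the
query haplotype gained or lost the copy.

Allele-specific methylated regions (ASMRs) reuse the tiled-window test of
:mod:`methaplo.dmr` with maternal vs paternal counts, restricted to the
allele gene space (gene body +- 2 kb), at the same 25/25/15 point
thresholds and Q < 0.05. Per-bin deltas are maternal minus paternal levels
in percentage points.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .config import RunConfig
from .dmr import test_windows_table, window_replicate_counts
from .io import GeneModel, SvRecord

log = logging.getLogger("methaplo")

SV_CATEGORIES = ["SYN", "TRANS", "INV", "AV", "PV", "short"]

_GROUPING = {
    "TRANS": "TRANS",
    "INVTR": "TRANS",
    "INV": "INV",
    "CPL": "AV",
    "DEL": "AV",
    "CPG": "PV",
    "INS": "PV",
    "SYN": "SYN",
    "SNP": "SNP",
}


def group_sv_records(records: list[SvRecord]) -> list[SvRecord]:
    """Set ``grouped_category`` on every record (total, deterministic).

    INS/DEL of length <= 50 bp become "short"; DUP/INVDP map to PV on query
    copy gain and AV on query copy loss; SYN and SNP pass through.
    """
    for r in records:
        if r.raw_type in ("DUP", "INVDP"):
            if r.copy_status == "copygain":
                r.grouped_category = "PV"
            elif r.copy_status == "copyloss":
                r.grouped_category = "AV"
            else:
                raise ValueError(
                    f"{r.raw_type} record requires copy_status copygain/copyloss"
                )
        elif r.raw_type in ("INS", "DEL"):
            r.grouped_category = "short" if r.length <= 50 else _GROUPING[r.raw_type]
        elif r.raw_type in _GROUPING:
            r.grouped_category = _GROUPING[r.raw_type]
        else:
            raise ValueError(f"unknown SV type code {r.raw_type!r}")
    return records


def sv_category_counts(records: list[SvRecord]) -> pd.Series:
    """Counts per grouped category over non-SYN/SNP records."""
    cats = [r.grouped_category for r in records
            if r.grouped_category not in ("SYN", "SNP")]
    return pd.Series(cats).value_counts().reindex(
        ["TRANS", "INV", "AV", "PV", "short"], fill_value=0
    )


def sv_category_total(counts: dict[str, int] | pd.Series) -> int:
    """Total SV count from per-category counts (TRANS + INV + AV + PV)."""
    return int(sum(int(counts[c]) for c in ("TRANS", "INV", "AV", "PV")))


# ---------------------------------------------------------------------------
# ASMRs
# ---------------------------------------------------------------------------

def detect_asmrs(
    maternal_reps: list[pd.DataFrame],
    paternal_reps: list[pd.DataFrame],
    pairs: pd.DataFrame,
    genes: dict[str, GeneModel],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Tiled-window maternal-vs-paternal test within each pair's gene space.

    ``maternal_reps``/``paternal_reps`` are replicate site tables on hap1
    coordinates (paternal counts must already be mapped onto the maternal
    gene space so bins align). Bins use the same 200/100 tiling as DMRs,
    restricted to [gene start - flank, gene end + flank). Returns all tested
    bins with ``delta`` (= maternal - paternal level, percentage points),
    q-values, and an ``is_asmr`` flag; pair ids are attached per bin.
    """
    cfg = config or RunConfig()

    def _index(reps):
        return [
            {c: grp.sort_values("pos", kind="mergesort").reset_index(drop=True)
             for c, grp in df.groupby("chrom")}
            for df in reps
        ]

    m_idx = _index(maternal_reps)
    p_idx = _index(paternal_reps)

    def _clip(indexed, chrom, start, end):
        out = []
        for by_chrom in indexed:
            grp = by_chrom.get(chrom)
            if grp is None:
                out.append(pd.DataFrame(columns=["chrom", "pos", "context",
                                                 "c_meth", "c_total"]))
                continue
            pos = grp["pos"].to_numpy()
            lo, hi = np.searchsorted(pos, [start, end])
            sub = grp.iloc[lo:hi].copy()
            sub["pos"] = sub["pos"] - start
            sub["chrom"] = "local"
            out.append(sub)
        return out

    frames = []
    for pair in pairs.itertuples(index=False):
        g = genes[pair.maternal_id]
        start = max(0, g.start - cfg.flank_size)
        end = g.end + cfg.flank_size
        local_len = end - start
        wins = window_replicate_counts(
            _clip(m_idx, g.chrom, start, end) + _clip(p_idx, g.chrom, start, end),
            {"local": local_len}, cfg.window_size, cfg.step_size,
        )
        if wins.empty:
            continue
        wins["pair_id"] = pair.pair_id
        wins["chrom"] = g.chrom
        wins["start"] += start
        wins["end"] += start
        frames.append(wins)
    if not frames:
        return pd.DataFrame()
    table = pd.concat(frames, ignore_index=True)
    n_m, n_p = len(maternal_reps), len(paternal_reps)
    tested = test_windows_table(table, n_m, n_p)
    tested = tested.rename(columns={"level_test": "level_maternal",
                                    "level_control": "level_paternal",
                                    "diff": "delta"})
    tested = tested[tested["n_cyt"] > cfg.min_cytosines_per_window].copy()
    from statsmodels.stats.multitest import multipletests

    q = np.full(len(tested), np.nan)
    for ctx in ("CG", "CHG", "CHH"):
        m = (tested["context"] == ctx).to_numpy()
        if m.any():
            q[m] = multipletests(tested["p_value"].to_numpy()[m], method="fdr_bh")[1]
    tested["q_value"] = q
    thr = tested["context"].map(cfg.dmr_diff_thresholds).to_numpy(dtype=float)
    tested["is_asmr"] = (np.abs(tested["delta"].to_numpy()) > thr) & (
        q < cfg.q_threshold
    )
    log.info("ASMR scan: %d bins tested, %d ASMRs", len(tested),
             int(tested["is_asmr"].sum()))
    return tested.reset_index(drop=True)


def asmg_flags(asmr_bins: pd.DataFrame, pairs: pd.DataFrame) -> pd.Series:
    """Pair is an ASMG iff it owns >= 1 ASMR bin."""
    if asmr_bins.empty:
        return pd.Series(False, index=pairs["pair_id"])
    hits = set(asmr_bins.loc[asmr_bins["is_asmr"], "pair_id"])
    return pd.Series(
        [pid in hits for pid in pairs["pair_id"]], index=pairs["pair_id"]
    )


def grade_delta(delta: float | np.ndarray, context: str):
    """Divergence grade of |delta| (percentage points).

    CG/CHG: grades 1..3 for [25,50), [50,75), [75,100); CHH: grades 1..2
    for [15,35), [35,55). Values outside the grade ranges return 0
    (ungraded).
    """
    edges = [25, 50, 75, 100] if context in ("CG", "CHG") else [15, 35, 55]
    a = np.abs(np.asarray(delta, dtype=float))
    grade = np.zeros(a.shape, dtype=int)
    for i in range(len(edges) - 1):
        grade[(a >= edges[i]) & (a < edges[i + 1])] = i + 1
    if np.isscalar(delta) or np.asarray(delta).ndim == 0:
        return int(grade)
    return grade


def fc_by_grade(
    asmr_bins: pd.DataFrame,
    ase: pd.DataFrame,
    context: str,
    ase_classes: tuple = ("M", "P"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """|log2FC| distributions per divergence grade, with pairwise tests.

    Each ASMR bin of grade g contributes its pair's |log2FC| to grade g's
    distribution (the unit is the allele-specific methylated bin); only
    bins of ASE-biased pairs (classes in ``ase_classes``) are kept.
    Returns (per-bin grade table indexed by pair, pairwise Wilcoxon
    rank-sum table).
    """
    bins = asmr_bins[(asmr_bins["context"] == context) & asmr_bins["is_asmr"]].copy()
    bins["grade"] = grade_delta(bins["delta"].to_numpy(), context)
    bins = bins[bins["grade"] > 0]
    aseg = ase[ase["bias_class"].isin(ase_classes)]
    merged = bins[["pair_id", "grade"]].set_index("pair_id").join(
        aseg[["log2fc"]], how="inner"
    )
    merged["abs_log2fc"] = merged["log2fc"].abs()
    grades = sorted(merged["grade"].unique())
    tests = []
    for i, g1 in enumerate(grades):
        for g2 in grades[i + 1:]:
            a = merged.loc[merged["grade"] == g1, "abs_log2fc"]
            b = merged.loc[merged["grade"] == g2, "abs_log2fc"]
            if len(a) < 2 or len(b) < 2:
                continue
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            tests.append({"grade_a": g1, "grade_b": g2, "n_a": len(a),
                          "n_b": len(b), "median_a": a.median(),
                          "median_b": b.median(), "statistic": stat, "p_value": p})
    return merged, pd.DataFrame(tests)


# ---------------------------------------------------------------------------
# SV overlap statistics
# ---------------------------------------------------------------------------

def overlap_sv_alleles(
    svs: list[SvRecord],
    genes: list[GeneModel],
    pair_gene_ids: set[str],
    flank: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SV counts per feature class of paired-allele gene space (multi-label).

    Each SV counts once for every feature class it overlaps on the gene
    space of paired alleles: intron, exon, promoter (upstream ``flank``) and
    downstream (``flank`` past the TTS), strand-aware, on reference (hap1)
    coordinates. Returns (per-feature counts with both multi-label and
    once-per-SV tallies, per-gene SV flags).
    """
    trees: dict[str, IntervalTree] = {}
    paired = [g for g in genes if g.gene_id in pair_gene_ids]
    for g in paired:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            max(0, g.start - flank), g.end + flank, g
        )
    feat_counts = {f: 0 for f in ("exon", "intron", "promoter", "downstream")}
    sv_any = {f: 0 for f in feat_counts}
    gene_hits: dict[str, int] = {}
    for sv in svs:
        if sv.grouped_category in ("SYN", "SNP", "short", None):
            continue
        tree = trees.get(sv.ref_chrom)
        if tree is None:
            continue
        sv_features = set()
        for iv in tree.overlap(sv.ref_start, sv.ref_end):
            g: GeneModel = iv.data
            labels = _sv_gene_features(sv, g, flank)
            if labels:
                gene_hits[g.gene_id] = gene_hits.get(g.gene_id, 0) + 1
            for lab in labels:
                feat_counts[lab] += 1
                sv_features.add(lab)
        for lab in sv_features:
            sv_any[lab] += 1
    counts = pd.DataFrame(
        {"n_multi": pd.Series(feat_counts), "n_sv_once": pd.Series(sv_any)}
    )
    flags = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in paired],
            "n_svs": [gene_hits.get(g.gene_id, 0) for g in paired],
        }
    )
    flags["allele_sv"] = flags["n_svs"] > 0
    return counts, flags


def _sv_gene_features(sv: SvRecord, g: GeneModel, flank: int) -> list[str]:
    s, e = sv.ref_start, max(sv.ref_end, sv.ref_start + 1)
    labels = []
    if g.strand == "+":
        up = (max(0, g.start - flank), g.start)
        down = (g.end, g.end + flank)
    else:
        up = (g.end, g.end + flank)
        down = (max(0, g.start - flank), g.start)
    if s < up[1] and e > up[0]:
        labels.append("promoter")
    if s < down[1] and e > down[0]:
        labels.append("downstream")
    if s < g.end and e > g.start:
        exons = g.exons or [(g.start, g.end)]
        if any(s < ee and e > es for es, ee in exons):
            labels.append("exon")
        introns = [
            (ee, ns) for (_, ee), (ns, _) in zip(exons, exons[1:]) if ns > ee
        ]
        if any(s < ie and e > is_ for is_, ie in introns):
            labels.append("intron")
    return labels


def compare_asmr_sv(
    asmr_bins: pd.DataFrame, svs: list[SvRecord]
) -> pd.DataFrame:
    """Wilcoxon rank-sum of |delta| for ASMR-SV vs ASMR-non-SV, per context.

    An ASMR overlaps an SV when its window intersects any grouped SV's
    reference interval by >= 1 bp.
    """
    trees: dict[str, IntervalTree] = {}
    for sv in svs:
        if sv.grouped_category in ("SYN", "SNP", "short", None):
            continue
        trees.setdefault(sv.ref_chrom, IntervalTree()).addi(
            sv.ref_start, max(sv.ref_end, sv.ref_start + 1)
        )
    bins = asmr_bins[asmr_bins["is_asmr"]].copy()
    overlaps = []
    for row in bins.itertuples(index=False):
        tree = trees.get(row.chrom)
        overlaps.append(bool(tree.overlap(row.start, row.end)) if tree else False)
    bins["sv_overlap"] = overlaps
    rows = []
    for ctx, grp in bins.groupby("context"):
        a = grp.loc[grp["sv_overlap"], "delta"].abs()
        b = grp.loc[~grp["sv_overlap"], "delta"].abs()
        if len(a) == 0 or len(b) == 0:
            continue
        if a.nunique() == 1 and b.nunique() == 1 and a.iloc[0] == b.iloc[0]:
            stat, p = np.nan, 1.0
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"context": ctx, "n_sv": len(a), "n_non_sv": len(b),
                     "median_sv": float(a.median()),
                     "median_non_sv": float(b.median()),
                     "statistic": stat, "p_value": float(p)})
    return pd.DataFrame(rows)


def sv_location_test(table: pd.DataFrame) -> dict:
    """Chi-square test of SV feature-location proportions (2 x k table).

    Rows are gene classes (e.g. ASEG vs unbiased), columns feature classes
    (gene-body, upstream, downstream). Proportional rows give statistic 0,
    p = 1.
    """
    obs = np.asarray(table, dtype=float)
    # all-zero rows/columns carry no information and would zero the expecteds
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return {"statistic": 0.0, "p_value": 1.0, "df": 0}
    stat, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return {"statistic": float(stat), "p_value": float(p), "df": int(dof)}


def validate_breakpoints(
    read_intervals: pd.DataFrame,
    svs: list[SvRecord],
    min_flank: int = 500,
    hc_length: int = 20000,
) -> pd.DataFrame:
    """Per-SV breakpoint support from simulated long-read spans.

    A read supports a breakpoint when it covers [bp - min_flank,
    bp + min_flank); reads strictly longer than ``hc_length`` form the
    high-confidence subset. Both breakpoints (ref start and ref end) are
    checked; support is the minimum of the two.
    """
    rows = []
    by_chrom = {
        c: g.sort_values("start", kind="mergesort")
        for c, g in read_intervals.groupby("chrom")
    }
    for i, sv in enumerate(svs):
        grp = by_chrom.get(sv.ref_chrom)
        supports = []
        hc_supports = []
        for bp in (sv.ref_start, sv.ref_end):
            lo, hi = bp - min_flank, bp + min_flank
            if grp is None:
                supports.append(0)
                hc_supports.append(0)
                continue
            cover = (grp["start"] <= lo) & (grp["end"] >= hi)
            supports.append(int(cover.sum()))
            lengths = grp["end"] - grp["start"]
            hc_supports.append(int((cover & (lengths > hc_length)).sum()))
        rows.append({"sv_index": i, "raw_type": sv.raw_type,
                     "chrom": sv.ref_chrom, "ref_start": sv.ref_start,
                     "ref_end": sv.ref_end,
                     "support": min(supports),
                     "support_hc": min(hc_supports)})
    return pd.DataFrame(rows)
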