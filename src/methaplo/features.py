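"""Feature annotation of regions, DMG calling, metaplots, telomere search.

Feature labels follow a midpoint rule with a fixed priority: a region is
assigned the single label promoter > exon > intron > downstream >
intergenic, judged by where its midpoint falls relative to the gene models
(promoter = upstream 2 kb of the TSS, downstream = 2 kb past the TTS, both
strand-aware). Metaplots map each feature body onto 40 proportional bins
(reversed for minus-strand features) flanked by 20 fixed-width bins over
2 kb on each side, and report the weighted methylation level per bin pooled
over all features.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GeneModel
from .methylome import revcomp

log = logging.getLogger("methaplo")

FEATURE_PRIORITY = ["promoter", "exon", "intron", "downstream", "intergenic"]


def _gene_tree(genes: list[GeneModel], flank: int) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            max(0, g.start - flank), g.end + flank, g
        )
    return trees


def _label_for_gene(mid: int, g: GeneModel, flank: int) -> str | None:
    if g.strand == "+":
        up = (g.start - flank, g.start)
        down = (g.end, g.end + flank)
    else:
        up = (g.end, g.end + flank)
        down = (g.start - flank, g.start)
    if up[0] <= mid < up[1]:
        return "promoter"
    if g.start <= mid < g.end:
        for s, e in g.exons:
            if s <= mid < e:
                return "exon"
        return "intron"
    if down[0] <= mid < down[1]:
        return "downstream"
    return None


def annotate_region(
    start: int,
    end: int,
    chrom: str,
    genes: list[GeneModel] | dict[str, IntervalTree],
    flank: int = 2000,
) -> dict:
    """Single feature label for a region, chosen at its midpoint.

    Returns ``{"feature", "gene_id", "distance_to_tss"}``; gene_id is None
    for intergenic regions. Ties across genes resolve by label priority,
    then by the smaller |distance to TSS| (deterministic).
    """
    trees = genes if isinstance(genes, dict) else _gene_tree(genes, flank)
    mid = (start + end) // 2
    tree = trees.get(chrom)
    hits = tree[mid] if tree is not None else []
    best = None
    for iv in hits:
        g: GeneModel = iv.data
        label = _label_for_gene(mid, g, flank)
        if label is None:
            continue
        dist = mid - g.tss if g.strand == "+" else g.tss - mid
        key = (FEATURE_PRIORITY.index(label), abs(dist), g.gene_id)
        if best is None or key < best[0]:
            best = (key, label, g.gene_id, dist)
    if best is None:
        return {"feature": "intergenic", "gene_id": None, "distance_to_tss": None}
    return {"feature": best[1], "gene_id": best[2], "distance_to_tss": int(best[3])}


def annotate_regions(
    regions: pd.DataFrame, genes: list[GeneModel], flank: int = 2000
) -> pd.DataFrame:
    """Vector wrapper of :func:`annotate_region` over a chrom/start/end table."""
    trees = _gene_tree(genes, flank)
    ann = [
        annotate_region(int(r.start), int(r.end), str(r.chrom), trees, flank)
        for r in regions.itertuples(index=False)
    ]
    out = regions.reset_index(drop=True).copy()
    out["feature"] = [a["feature"] for a in ann]
    out["gene_id"] = [a["gene_id"] for a in ann]
    out["distance_to_tss"] = [a["distance_to_tss"] for a in ann]
    return out


def feature_proportions(annotated: pd.DataFrame) -> pd.Series:
    """Fraction of regions per feature label (sums to 1)."""
    counts = annotated["feature"].value_counts()
    props = counts.reindex(FEATURE_PRIORITY, fill_value=0) / max(len(annotated), 1)
    return props


def call_dmgs(
    dmrs: pd.DataFrame, genes: list[GeneModel], flank: int = 2000
) -> set[str]:
    """Genes overlapping >= 1 DMR within gene body or +-``flank`` bp."""
    hit: set[str] = set()
    if dmrs.empty:
        return hit
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            max(0, g.start - flank), g.end + flank, g.gene_id
        )
    for row in dmrs.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(row.start, row.end):
            hit.add(iv.data)
    return hit


# ---------------------------------------------------------------------------
# metaplots
# ---------------------------------------------------------------------------

def metaprofile(
    sites: pd.DataFrame,
    features: pd.DataFrame,
    body_bins: int = 40,
    flank_bins: int = 20,
    flank: int = 2000,
    contexts: tuple = ("CG", "CHG", "CHH"),
) -> pd.DataFrame:
    """Methylation metaplot over upstream flank, body, downstream flank.

    ``features`` needs chrom/start/end/strand. Bin indices run 0..79 in
    feature orientation: 0..flank_bins-1 upstream, then body, then
    downstream. Flank bins are fixed ``flank/flank_bins`` bp; body bins are
    proportional. Features shorter than ``body_bins`` bp are skipped.
    Per-bin level is the weighted level over all sites of all features
    mapped to that bin; per-bin (meth, total, n_features) are retained.
    """
    n_bins = 2 * flank_bins + body_bins
    flank_bp = flank // flank_bins
    acc_m = {c: np.zeros(n_bins) for c in contexts}
    acc_t = {c: np.zeros(n_bins) for c in contexts}
    n_feat = np.zeros(n_bins, dtype=int)
    n_skipped = 0

    by_chrom = {
        c: g.sort_values("pos", kind="mergesort") for c, g in sites.groupby("chrom")
    }
    for feat in features.itertuples(index=False):
        length = feat.end - feat.start
        if length < body_bins:
            n_skipped += 1
            continue
        grp = by_chrom.get(feat.chrom)
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, feat.start - flank)
        hi = np.searchsorted(pos, feat.end + flank)
        if hi == lo:
            continue
        window = grp.iloc[lo:hi]
        p = window["pos"].to_numpy()
        rel_bin = np.full(p.size, -1, dtype=np.int64)
        upstream = p < feat.start
        body = (p >= feat.start) & (p < feat.end)
        downstream = p >= feat.end
        rel_bin[upstream] = flank_bins - 1 - (feat.start - 1 - p[upstream]) // flank_bp
        rel_bin[body] = flank_bins + (p[body] - feat.start) * body_bins // length
        rel_bin[downstream] = (
            flank_bins + body_bins + (p[downstream] - feat.end) // flank_bp
        )
        ok = (rel_bin >= 0) & (rel_bin < n_bins)
        rel_bin = rel_bin[ok]
        window = window.iloc[np.nonzero(ok)[0]]
        if getattr(feat, "strand", "+") == "-":
            rel_bin = n_bins - 1 - rel_bin
        n_feat[np.unique(rel_bin)] += 1
        ctx_arr = window["context"].to_numpy()
        for c in contexts:
            sel = ctx_arr == c
            if not sel.any():
                continue
            acc_m[c] += np.bincount(rel_bin[sel],
                                    weights=window["c_meth"].to_numpy()[sel],
                                    minlength=n_bins)
            acc_t[c] += np.bincount(rel_bin[sel],
                                    weights=window["c_total"].to_numpy()[sel],
                                    minlength=n_bins)
    if n_skipped:
        log.info("metaprofile: skipped %d features shorter than %d bp",
                 n_skipped, body_bins)
    rows = []
    for c in contexts:
        with np.errstate(invalid="ignore", divide="ignore"):
            level = np.where(acc_t[c] > 0, acc_m[c] / np.maximum(acc_t[c], 1), np.nan)
        for b in range(n_bins):
            rows.append({"context": c, "bin": b, "sum_c_meth": acc_m[c][b],
                         "sum_c_total": acc_t[c][b], "level": level[b],
                         "n_features": n_feat[b]})
    return pd.DataFrame(rows)


def gene_region_intervals(
    genes: list[GeneModel], flank: int = 2000
) -> dict[str, pd.DataFrame]:
    """Strand-aware upstream / body / downstream intervals per gene."""
    rows = {"upstream": [], "body": [], "downstream": []}
    for g in genes:
        if g.strand == "+":
            up = (max(0, g.start - flank), g.start)
            down = (g.end, g.end + flank)
        else:
            up = (g.end, g.end + flank)
            down = (max(0, g.start - flank), g.start)
        rows["upstream"].append({"gene_id": g.gene_id, "chrom": g.chrom,
                                 "start": up[0], "end": up[1]})
        rows["body"].append({"gene_id": g.gene_id, "chrom": g.chrom,
                             "start": g.start, "end": g.end})
        rows["downstream"].append({"gene_id": g.gene_id, "chrom": g.chrom,
                                   "start": down[0], "end": down[1]})
    return {k: pd.DataFrame(v) for k, v in rows.items()}


# ---------------------------------------------------------------------------
# telomeres
# ---------------------------------------------------------------------------

def find_telomeres(
    genome: dict[str, str],
    motif: str = "TTTAGGG",
    window: int = 1000,
    min_copies: int = 10,
) -> pd.DataFrame:
    """Flag telomeric chromosome ends by terminal motif copy number.

    The start of a chromosome carries the reverse complement of the repeat
    (CCCTAAA for the plant telomere motif); the terminal end carries the
    motif itself. An end is telomeric iff >= ``min_copies`` occurrences fall
    within the terminal ``window`` bp.
    """
    rc = revcomp(motif)
    rows = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        start_copies = seq[:window].count(rc)
        end_copies = seq[-window:].count(motif)
        rows.append({"chrom": chrom, "end": "start", "copies": start_copies,
                     "telomeric": start_copies >= min_copies})
        rows.append({"chrom": chrom, "end": "terminal", "copies": end_copies,
                     "telomeric": end_copies >= min_copies})
    return pd.DataFrame(rows)
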