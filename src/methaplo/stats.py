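"""Cross-cutting statistics linking methylation and expression.

Covers the per-rank-group methylation comparisons (with compact letter
displays from pairwise Wilcoxon rank-sum tests), methylation-level
categories, DMG-in-DEG Fisher enrichment, bin-wise Pearson correlation of
methylation and expression across samples, and the TE "fluctuation"
analysis (SD of per-bin correlation coefficients along each gene).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio

METH_CATEGORIES = ["zero", "LML", "MML", "HML"]


def categorize_levels(levels: pd.Series | np.ndarray) -> pd.Series:
    """Methylation-level categories with exact boundary semantics.

    zero: level = 0; LML: 0 < level <= 10%; MML: 10% < level <= 20%;
    HML: level > 20%. Levels are fractions in [0, 1].
    """
    lv = pd.Series(levels, dtype=float)
    if ((lv < 0) | (lv > 1)).any():
        raise ValueError("levels must be fractions in [0, 1]")
    out = pd.Series("HML", index=lv.index, dtype=object)
    out[lv <= 0.20] = "MML"
    out[lv <= 0.10] = "LML"
    out[lv == 0.0] = "zero"
    out[lv.isna()] = None
    return out


def category_fractions(levels: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Fractions of zero/LML/MML/HML within each group (rows sum to 1)."""
    cats = categorize_levels(levels)
    tab = pd.crosstab(groups, cats)
    tab = tab.reindex(columns=METH_CATEGORIES, fill_value=0)
    return tab.div(tab.sum(axis=1), axis=0)


# ---------------------------------------------------------------------------
# rank-group comparisons with compact letters
# ---------------------------------------------------------------------------

def pairwise_wilcoxon(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise two-sided Wilcoxon rank-sum tests between groups."""
    rows = []
    for a, b in combinations(sorted(groups), 2):
        xa, xb = np.asarray(groups[a]), np.asarray(groups[b])
        if len(xa) == 0 or len(xb) == 0:
            continue
        if np.array_equal(np.sort(xa), np.sort(xb)):
            stat, p = np.nan, 1.0
        else:
            stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append({"group_a": a, "group_b": b, "statistic": stat,
                     "p_value": float(p)})
    return pd.DataFrame(rows)


def compact_letters(
    groups: dict[str, np.ndarray], pairwise: pd.DataFrame, alpha: float = 0.01
) -> dict[str, str]:
    """Compact letter display from the pairwise significance pattern.

    Letters are the maximal cliques of the non-significance graph, ordered
    by group median: groups share a letter iff they sit in a common clique,
    so sharing a letter implies pairwise non-significance and every
    non-significant pair shares at least one letter.
    """
    names = sorted(groups, key=lambda g: (np.median(groups[g]), g))
    ns = {frozenset((a, b)): True for a in names for b in names if a != b}
    for row in pairwise.itertuples(index=False):
        ns[frozenset((row.group_a, row.group_b))] = row.p_value >= alpha

    def compatible(subset):
        return all(ns[frozenset((a, b))] for a, b in combinations(subset, 2))

    cliques = []
    n = len(names)
    for mask in range(1, 1 << n):
        subset = [names[i] for i in range(n) if mask >> i & 1]
        if compatible(subset):
            cliques.append(frozenset(subset))
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    maximal.sort(key=lambda c: min(names.index(g) for g in c))
    letters = {g: "" for g in names}
    for i, clique in enumerate(maximal):
        ch = chr(ord("a") + i)
        for g in clique:
            letters[g] += ch
    return letters


def meth_by_expression_rank(
    gene_levels: pd.Series,
    rank_groups: pd.Series,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Level distributions per expression rank group with letter display.

    ``gene_levels`` are per-gene weighted levels (fractions) for one region
    and context; ``rank_groups`` maps the same genes to N/L/LM/MH/H.
    Returns (summary table, pairwise test table, letters).
    """
    df = pd.DataFrame({"level": gene_levels, "group": rank_groups}).dropna()
    groups = {g: grp["level"].to_numpy() for g, grp in df.groupby("group")}
    groups = {g: v for g, v in groups.items() if len(v) > 0}
    pw = pairwise_wilcoxon(groups)
    letters = compact_letters(groups, pw, alpha=alpha)
    summary = pd.DataFrame(
        [
            {"group": g, "n": len(v), "median": float(np.median(v)),
             "mean": float(np.mean(v)), "letters": letters[g]}
            for g, v in sorted(groups.items())
        ]
    )
    return summary, pw, letters


# ---------------------------------------------------------------------------
# enrichment and correlation
# ---------------------------------------------------------------------------

def dmg_deg_enrichment(
    dmg_set: set[str], deg_set: set[str], universe: set[str]
) -> dict:
    """One-tailed Fisher's exact test of DEG x DMG overlap.

    Upper-tail hypergeometric p on the 2x2 table plus the conditional
    maximum-likelihood odds ratio.
    """
    dmg = dmg_set & universe
    deg = deg_set & universe
    both = len(dmg & deg)
    deg_only = len(deg) - both
    dmg_only = len(dmg) - both
    neither = len(universe) - both - deg_only - dmg_only
    table = np.array([[both, deg_only], [dmg_only, neither]])
    p = stats.fisher_exact(table, alternative="greater")[1]
    try:
        or_ = odds_ratio(table, kind="conditional").statistic
    except ValueError:
        or_ = np.nan
    return {"table": table.tolist(), "p_value": float(p),
            "odds_ratio": float(or_)}


def binwise_expression_correlation(
    bin_levels: pd.DataFrame,
    tpm: pd.DataFrame,
    min_samples: int = 6,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson r between per-bin methylation and the gene's TPM across samples.

    ``bin_levels`` has one row per (gene_id, bin, context) and one column
    per sample (levels as fractions; NaN = uncovered); ``tpm`` is genes x
    samples. Bins with fewer than ``min_samples`` complete observations or
    constant methylation are excluded (r undefined). Significance at raw
    p < ``alpha``; a BH-adjusted flag is also emitted.
    """
    samples = [c for c in tpm.columns if c in bin_levels.columns]
    meta = bin_levels[["gene_id", "bin", "context"]].reset_index(drop=True)
    x = bin_levels[samples].to_numpy(dtype=float)
    y = tpm.loc[meta["gene_id"], samples].to_numpy(dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = ok.sum(axis=1)
    xm = np.where(ok, x, 0.0)
    ym = np.where(ok, y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = xm.sum(axis=1) / n
        my = ym.sum(axis=1) / n
        dx = np.where(ok, x - mx[:, None], 0.0)
        dy = np.where(ok, y - my[:, None], 0.0)
        sxx = (dx**2).sum(axis=1)
        syy = (dy**2).sum(axis=1)
        r = (dx * dy).sum(axis=1) / np.sqrt(sxx * syy)
    valid = (n >= min_samples) & (sxx > 0) & (syy > 0)
    r = np.where(valid, r, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-12, 1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), df=np.maximum(n - 2, 1))
    p = np.where(valid, p, np.nan)
    out = meta.copy()
    out["n"] = n
    out["r"] = r
    out["p_value"] = p
    out["significant"] = (p < alpha) & valid
    from statsmodels.stats.multitest import multipletests

    qflag = np.zeros(len(out), dtype=bool)
    if valid.any():
        qflag[valid] = multipletests(p[valid], method="fdr_bh")[1] < alpha
    out["significant_bh"] = qflag
    return out


def correlation_sign_counts(corr: pd.DataFrame) -> pd.DataFrame:
    """Counts of significantly positive/negative bins per context."""
    sig = corr[corr["significant"]]
    rows = []
    for ctx, grp in sig.groupby("context"):
        rows.append({"context": ctx,
                     "n_positive": int((grp["r"] > 0).sum()),
                     "n_negative": int((grp["r"] < 0).sum())})
    return pd.DataFrame(rows)


def te_fluctuation(
    corr: pd.DataFrame, te_flags: pd.Series, min_genes: int = 10
) -> pd.DataFrame:
    """Per-gene SD of body-bin correlation coefficients, TE vs non-TE genes.

    ``corr`` is the output of :func:`binwise_expression_correlation`
    restricted to body bins; ``te_flags`` maps gene_id -> bool. Class
    distributions are compared by Wilcoxon rank-sum per context.
    """
    rows = []
    for ctx, grp in corr.groupby("context"):
        sd = grp.groupby("gene_id")["r"].apply(
            lambda v: float(np.std(v.dropna(), ddof=0)) if v.notna().sum() >= 2
            else np.nan
        ).dropna()
        flags = te_flags.reindex(sd.index)
        a = sd[flags.fillna(False).astype(bool)]
        b = sd[~flags.fillna(False).astype(bool)]
        if len(a) < min_genes or len(b) < min_genes:
            rows.append({"context": ctx, "n_te": len(a), "n_non_te": len(b),
                         "median_te": float(a.median()) if len(a) else np.nan,
                         "median_non_te": float(b.median()) if len(b) else np.nan,
                         "statistic": np.nan, "p_value": np.nan})
            continue
        if np.array_equal(np.sort(a), np.sort(b)):
            stat, p = np.nan, 1.0
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"context": ctx, "n_te": len(a), "n_non_te": len(b),
                     "median_te": float(a.median()),
                     "median_non_te": float(b.median()),
                     "statistic": stat, "p_value": float(p)})
    return pd.DataFrame(rows)
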