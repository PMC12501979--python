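"""Tiled-window differentially methylated region (DMR) detection.

Windows of 200 bp tiled every 100 bp are tested between a test sample and a
control, per context, on replicate-level (methylated, total) read counts.
The test is a likelihood-ratio test of a binomial GLM with a group factor;
because the group-model MLEs are the pooled within-group proportions, the
LRT reduces to a G-test on the pooled 2x2 table (chi-square, df=1), which is
evaluated in closed form. When either group has a single replicate the test
falls back to Fisher's exact test on the pooled table.

A window is a DMR iff its absolute level difference exceeds the context
threshold (25/25/15 percentage points for CG/CHG/CHH) and its
Benjamini-Hochberg q-value (per context within the comparison) is below
0.05. Direction is ``hypo`` when the test sample is lower.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import CONTEXTS, RunConfig

log = logging.getLogger("methaplo")


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def tile_windows(chrom_length: int, window: int = 200, step: int = 100) -> list[tuple[int, int]]:
    """Sliding windows [0,w), [s, s+w), ...

    A chromosome shorter than one window yields a single whole-chromosome
    window. A final partial window is emitted only when it is strictly
    longer than ``step`` (a tail of exactly ``step`` bp adds no window).
    """
    if window < step or step <= 0:
        raise ValueError("require window >= step > 0")
    if chrom_length <= 0:
        return []
    if chrom_length < window:
        return [(0, chrom_length)]
    starts = list(range(0, chrom_length - window + 1, step))
    wins = [(s, s + window) for s in starts]
    tail_start = starts[-1] + step
    if chrom_length - tail_start > step:
        wins.append((tail_start, chrom_length))
    return wins


def assign_windows(
    pos: np.ndarray, chrom_length: int, window: int = 200, step: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Map positions to the indices of every window containing them.

    Returns ``(site_index, window_index)`` arrays, one row per
    site-in-window membership, consistent with :func:`tile_windows`.
    """
    wins = tile_windows(chrom_length, window, step)
    n_win = len(wins)
    if n_win == 0 or pos.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    max_per = window // step + 1
    site_idx = []
    win_idx = []
    for k in range(max_per):
        j = pos // step - k
        ok = (j >= 0) & (j < n_win)
        if not ok.any():
            continue
        jj = j[ok]
        starts = np.array([wins[i][0] for i in range(n_win)])
        ends = np.array([wins[i][1] for i in range(n_win)])
        inside = (pos[ok] >= starts[jj]) & (pos[ok] < ends[jj])
        site_idx.append(np.nonzero(ok)[0][inside])
        win_idx.append(jj[inside])
    return np.concatenate(site_idx), np.concatenate(win_idx)


def window_replicate_counts(
    rep_sites: list[pd.DataFrame],
    chrom_lengths: dict[str, int],
    window: int = 200,
    step: int = 100,
) -> pd.DataFrame:
    """Per-window, per-context (meth, total) sums for each replicate.

    Returns one row per (chrom, start, end, context) with columns
    ``meth_0, total_0, meth_1, ...`` and ``n_cyt`` (cytosines of that
    context covered in the replicate-pooled counts).
    """
    pieces = []
    for chrom, length in sorted(chrom_lengths.items()):
        wins = tile_windows(length, window, step)
        if not wins:
            continue
        starts = np.array([w[0] for w in wins])
        ends = np.array([w[1] for w in wins])
        for ctx in CONTEXTS:
            acc = None
            for r, sites in enumerate(rep_sites):
                sub = sites[(sites["chrom"] == chrom) & (sites["context"] == ctx)]
                pos = sub["pos"].to_numpy()
                si, wi = assign_windows(pos, length, window, step)
                m = np.bincount(wi, weights=sub["c_meth"].to_numpy()[si],
                                minlength=len(wins)).astype(np.int64)
                t = np.bincount(wi, weights=sub["c_total"].to_numpy()[si],
                                minlength=len(wins)).astype(np.int64)
                cov = sub["c_total"].to_numpy()[si] > 0
                nc = np.bincount(wi[cov], minlength=len(wins))
                if acc is None:
                    acc = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                                        "context": ctx})
                    acc["n_cyt"] = 0
                acc[f"meth_{r}"] = m
                acc[f"total_{r}"] = t
                acc["n_cyt"] = np.maximum(acc["n_cyt"], nc)
            if acc is not None:
                pieces.append(acc)
    if not pieces:
        return pd.DataFrame()
    return pd.concat(pieces, ignore_index=True)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def _binomial_lrt(m1, t1, m2, t2):
    """Closed-form G-test LRT p-values; df=1. Inputs are pooled group counts."""
    m1 = np.asarray(m1, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    t2 = np.asarray(t2, dtype=float)

    def _ll(m, t):
        u = t - m
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(t > 0, m / np.maximum(t, 1), 0.0)
            out = np.where(m > 0, m * np.log(np.maximum(p, 1e-300)), 0.0)
            out += np.where(u > 0, u * np.log(np.maximum(1 - p, 1e-300)), 0.0)
        return out

    pooled_m = m1 + m2
    pooled_t = t1 + t2
    g = 2.0 * (_ll(m1, t1) + _ll(m2, t2) - _ll(pooled_m, pooled_t))
    g = np.maximum(g, 0.0)
    return stats.chi2.sf(g, df=1)


def test_window(
    test_reps: list[tuple[int, int]], control_reps: list[tuple[int, int]]
) -> tuple[float, float]:
    """Difference (test - control, percentage points) and p-value for one window.

    Replicates are (c_meth, c_total) sums. With >= 2 replicates in both
    groups the binomial-GLM LRT is used; otherwise Fisher's exact test on
    the pooled 2x2 table.
    """
    m1 = sum(m for m, _ in test_reps)
    t1 = sum(t for _, t in test_reps)
    m2 = sum(m for m, _ in control_reps)
    t2 = sum(t for _, t in control_reps)
    if t1 == 0 or t2 == 0:
        raise ValueError("zero total counts in a group; window should be skipped")
    diff = 100.0 * (m1 / t1 - m2 / t2)
    if min(len(test_reps), len(control_reps)) < 2:
        table = [[m1, t1 - m1], [m2, t2 - m2]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        p = float(_binomial_lrt(m1, t1, m2, t2))
    return diff, p


def test_windows_table(
    windows: pd.DataFrame, n_test: int, n_control: int
) -> pd.DataFrame:
    """Vectorized window testing over a :func:`window_replicate_counts` table.

    Test replicate columns are ``meth_0..meth_{n_test-1}``; control columns
    follow. Windows with zero total in either group are dropped (logged).
    """
    m1 = sum(windows[f"meth_{r}"].to_numpy() for r in range(n_test))
    t1 = sum(windows[f"total_{r}"].to_numpy() for r in range(n_test))
    m2 = sum(windows[f"meth_{r}"].to_numpy() for r in range(n_test, n_test + n_control))
    t2 = sum(windows[f"total_{r}"].to_numpy() for r in range(n_test, n_test + n_control))
    ok = (t1 > 0) & (t2 > 0)
    n_skipped = int((~ok).sum())
    if n_skipped:
        log.info("skipping %d windows with zero coverage in a group", n_skipped)
    out = windows.loc[ok].reset_index(drop=True).copy()
    m1, t1, m2, t2 = m1[ok], t1[ok], m2[ok], t2[ok]
    out["level_test"] = 100.0 * m1 / t1
    out["level_control"] = 100.0 * m2 / t2
    out["diff"] = out["level_test"] - out["level_control"]
    if min(n_test, n_control) < 2:
        out["p_value"] = [
            float(stats.fisher_exact([[a, b - a], [c, d - c]])[1])
            for a, b, c, d in zip(m1, t1, m2, t2)
        ]
    else:
        out["p_value"] = _binomial_lrt(m1, t1, m2, t2)
    return out


def call_dmrs(
    tested: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Apply the window filter, per-context BH correction and thresholds.

    Returns only windows meeting both criteria, with ``q_value`` and
    ``direction`` (hyper/hypo) columns. The cytosine filter keeps windows
    with strictly more than ``min_cytosines_per_window`` covered cytosines.
    """
    cfg = config or RunConfig()
    tested = tested[tested["n_cyt"] > cfg.min_cytosines_per_window].copy()
    if tested.empty:
        tested["q_value"] = []
        tested["direction"] = []
        return tested
    q = np.full(len(tested), np.nan)
    ctx_arr = tested["context"].to_numpy()
    for ctx in CONTEXTS:
        mask = ctx_arr == ctx
        if mask.any():
            q[mask] = multipletests(tested["p_value"].to_numpy()[mask],
                                    method="fdr_bh")[1]
    tested["q_value"] = q
    thr = tested["context"].map(cfg.dmr_diff_thresholds).to_numpy(dtype=float)
    keep = (np.abs(tested["diff"].to_numpy()) > thr) & (q < cfg.q_threshold)
    out = tested.loc[keep].copy()
    out["direction"] = np.where(out["diff"] < 0, "hypo", "hyper")
    log.info("called %d DMRs from %d tested windows", len(out), len(tested))
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# cross-epimutant intersections
# ---------------------------------------------------------------------------

def intersect_dmr_sets(
    dmr_sets: dict[str, pd.DataFrame], same_direction: bool = True
) -> pd.DataFrame:
    """Cluster DMRs across samples by >= 1 bp overlap (UpSet semantics).

    DMRs from different samples are merged into one cluster when their
    windows overlap within the same context (and, by default, the same
    direction). One row per cluster with per-sample membership flags.
    """
    names = sorted(dmr_sets)
    frames = []
    for name in names:
        df = dmr_sets[name]
        if df.empty:
            continue
        cols = ["chrom", "start", "end", "context"]
        sub = df[cols + (["direction"] if same_direction else [])].copy()
        if not same_direction:
            sub["direction"] = "any"
        sub["sample"] = name
        frames.append(sub)
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "context", "direction"] + names
        )
    allw = pd.concat(frames, ignore_index=True)
    clusters = []
    for (ctx, direction, chrom), grp in allw.groupby(
        ["context", "direction", "chrom"], sort=True
    ):
        grp = grp.sort_values(["start", "end"], kind="mergesort")
        cur_start = cur_end = None
        members: set = set()
        for row in grp.itertuples(index=False):
            if cur_start is None or row.start >= cur_end:
                if cur_start is not None:
                    clusters.append((chrom, cur_start, cur_end, ctx, direction,
                                     frozenset(members)))
                cur_start, cur_end, members = row.start, row.end, {row.sample}
            else:
                cur_end = max(cur_end, row.end)
                members.add(row.sample)
        if cur_start is not None:
            clusters.append((chrom, cur_start, cur_end, ctx, direction,
                             frozenset(members)))
    rows = []
    for chrom, s, e, ctx, direction, members in clusters:
        row = {"chrom": chrom, "start": s, "end": e, "context": ctx,
               "direction": direction, "n_samples": len(members)}
        for name in names:
            row[name] = name in members
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        ["context", "direction", "chrom", "start"], kind="mergesort"
    ).reset_index(drop=True)
    return out


def intersection_subset_counts(clusters: pd.DataFrame, names: list[str]) -> pd.Series:
    """UpSet-style counts per membership subset, plus fraction shared by all."""
    if clusters.empty:
        return pd.Series(dtype=int)
    keys = clusters[names].apply(
        lambda r: "&".join(n for n in names if r[n]), axis=1
    )
    return keys.value_counts().sort_index()


def common_dmr_levels(
    clusters: pd.DataFrame,
    sample_sites: dict[str, pd.DataFrame],
    min_shared: int = 2,
    depth_min: int = 0,
) -> pd.DataFrame:
    """Recompute each common DMR's weighted level in every sample.

    Common DMRs are clusters shared by >= ``min_shared`` samples. Clusters
    with zero coverage in a sample are excluded from that sample's
    distribution (level NaN).
    """
    from .methylome import interval_weighted_levels

    common = clusters[clusters["n_samples"] >= min_shared]
    out = []
    for sample, sites in sorted(sample_sites.items()):
        for ctx in CONTEXTS:
            sub = common[common["context"] == ctx]
            if sub.empty:
                continue
            lv = interval_weighted_levels(
                sites, sub[["chrom", "start", "end"]], context=ctx,
                depth_min=depth_min,
            )
            lv["context"] = ctx
            lv["direction"] = sub["direction"].to_numpy()
            lv["sample"] = sample
            out.append(lv)
    if not out:
        return pd.DataFrame()
    res = pd.concat(out, ignore_index=True)
    n_uncovered = int(res["level"].isna().sum())
    if n_uncovered:
        log.info("%d common-DMR x sample combinations had zero coverage", n_uncovered)
    return res
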