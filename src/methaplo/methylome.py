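"""Per-site methylation calling and weighted methylation summaries.

Cytosine sites are carried as a pandas DataFrame with columns
``chrom, pos, strand, context, c_meth, c_total`` (0-based positions,
``c_meth`` = reads supporting methylation, ``c_total`` = covering reads).
Calling adds ``p_value, q_value, call`` where ``call`` is one of
``methylated / unmethylated / sub-threshold``.

The weighted methylation level of a region is

    sum_i C_i / sum_i (C_i + T_i)

over its cytosines, i.e. total methylated read support divided by total
coverage — deeper sites carry proportionally more weight than in a plain
mean of per-site levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import CONTEXTS

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "c_meth", "c_total"]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class RegionMethylation:
    chrom: str
    start: int
    end: int
    context: str
    n_sites: int
    sum_c_meth: int
    sum_c_total: int

    @property
    def defined(self) -> bool:
        return self.sum_c_total > 0

    @property
    def level(self) -> float:
        """Weighted methylation level; NaN when the region has no coverage."""
        if not self.defined:
            return float("nan")
        return self.sum_c_meth / self.sum_c_total


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------

def context_map(seq: str) -> pd.DataFrame:
    """Vectorized context classification of every cytosine in ``seq``.

    Returns a DataFrame with ``pos, strand, context, tri`` covering both
    strands (a C on the minus strand is a G in ``seq``). Sites whose
    trinucleotide runs off the chromosome end or contains an N get no row:
    their context is undefined and they are excluded from all statistics.
    """
    b = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    n = b.size
    records = []
    for strand in "+-":
        if strand == "+":
            is_c = b == ord("C")
            pos = np.nonzero(is_c)[0]
            pos = pos[pos + 2 < n]
            n1 = b[pos + 1]
            n2 = b[pos + 2]
        else:
            is_c = b == ord("G")  # C on the minus strand
            pos = np.nonzero(is_c)[0]
            pos = pos[pos - 2 >= 0]
            # downstream on the minus strand runs leftwards; complement bases
            n1 = _complement_codes(b[pos - 1])
            n2 = _complement_codes(b[pos - 2])
        valid = (n1 != ord("N")) & (n2 != ord("N"))
        pos, n1, n2 = pos[valid], n1[valid], n2[valid]
        ctx = np.where(
            n1 == ord("G"), "CG", np.where(n2 == ord("G"), "CHG", "CHH")
        )
        tri = np.char.add(
            "C", np.char.add(n1.view("S1").astype("U1"), n2.view("S1").astype("U1"))
        )
        records.append(
            pd.DataFrame({"pos": pos, "strand": strand, "context": ctx, "tri": tri})
        )
    out = pd.concat(records, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)


def _complement_codes(codes: np.ndarray) -> np.ndarray:
    out = codes.copy()
    for a, b_ in zip(b"ACGT", b"TGCA"):
        out[codes == a] = b_
    return out


def classify_context(seq: str, pos: int, strand: str) -> str:
    """Context of the cytosine at ``pos`` on ``strand``; "none" at boundaries.

    Raises ``ValueError`` if the addressed base is not a C on that strand.
    """
    seq = seq.upper()
    base = seq[pos]
    expected = "C" if strand == "+" else "G"
    if base != expected:
        raise ValueError(
            f"base at {pos}{strand} is {base!r}, not a cytosine on that strand"
        )
    if strand == "+":
        if pos + 2 >= len(seq):
            return "none"
        n1, n2 = seq[pos + 1], seq[pos + 2]
    else:
        if pos - 2 < 0:
            return "none"
        n1 = seq[pos - 1].translate(_COMPLEMENT)
        n2 = seq[pos - 2].translate(_COMPLEMENT)
    if "N" in (n1, n2):
        return "none"
    if n1 == "G":
        return "CG"
    if n2 == "G":
        return "CHG"
    return "CHH"


# ---------------------------------------------------------------------------
# conversion-rate estimation and site calling
# ---------------------------------------------------------------------------

def estimate_conversion_error(lambda_sites: pd.DataFrame) -> dict:
    """Apparent methylation rate of the unmethylated lambda spike-in.

    Every read supporting methylation on lambda is a bisulfite conversion
    failure, so the pooled rate sum(C)/sum(C+T) estimates 1 - conversion
    rate. Returned per context and pooled under the key ``pooled``.
    """
    covered = lambda_sites[lambda_sites["c_total"] > 0]
    if covered.empty:
        raise ValueError("no covered lambda sites; cannot estimate conversion error")
    out = {"pooled": float(covered["c_meth"].sum() / covered["c_total"].sum())}
    for ctx, grp in covered.groupby("context"):
        out[str(ctx)] = float(grp["c_meth"].sum() / grp["c_total"].sum())
    return out


def call_methylated_sites(
    sites: pd.DataFrame,
    error_rate: float,
    depth_min: int = 5,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Binomial test of each site against the conversion error rate.

    Sites with depth >= ``depth_min`` get an upper-tail binomial p-value
    P(X >= c_meth | c_total, error_rate); Benjamini-Hochberg q-values are
    computed jointly over all tested sites and a site is called methylated
    iff q < ``fdr``. Sites below the depth cutoff keep call="sub-threshold".
    """
    if not 0 < error_rate < 1:
        raise ValueError("error_rate must be in (0, 1)")
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    out = sites.copy()
    tested = (out["c_total"] >= depth_min).to_numpy()
    p = np.full(len(out), np.nan)
    k = out["c_meth"].to_numpy()
    ntot = out["c_total"].to_numpy()
    p[tested] = stats.binom.sf(k[tested] - 1, ntot[tested], error_rate)
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    call = np.where(tested, np.where(q < fdr, "methylated", "unmethylated"),
                    "sub-threshold")
    out["p_value"] = p
    out["q_value"] = q
    out["call"] = call
    return out


# ---------------------------------------------------------------------------
# weighted levels and genome-wide summaries
# ---------------------------------------------------------------------------

def weighted_methylation_level(
    sites: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    context: str | None = None,
    depth_min: int = 0,
) -> RegionMethylation:
    """Weighted level of ``[start, end)`` on ``chrom`` for one context."""
    mask = (
        (sites["chrom"] == chrom)
        & (sites["pos"] >= start)
        & (sites["pos"] < end)
        & (sites["c_total"] >= depth_min)
    )
    if context is not None:
        mask &= sites["context"] == context
    sub = sites.loc[mask]
    return RegionMethylation(
        chrom=chrom,
        start=start,
        end=end,
        context=context or "all",
        n_sites=int(len(sub)),
        sum_c_meth=int(sub["c_meth"].sum()),
        sum_c_total=int(sub["c_total"].sum()),
    )


def genome_wide_levels(sites: pd.DataFrame, depth_min: int = 5) -> pd.DataFrame:
    """Per-context weighted level plus methylated-site fractions.

    ``frac_methylated_covered`` uses covered (depth-passing) cytosines as the
    denominator; ``frac_methylated_all`` uses every cytosine in the table.
    Both are reported because a "percentage of methylated sites" is ambiguous
    between the two denominators.
    """
    rows = []
    for ctx in CONTEXTS:
        sub = sites[sites["context"] == ctx]
        covered = sub[sub["c_total"] >= depth_min]
        total_cov = covered["c_total"].sum()
        level = covered["c_meth"].sum() / total_cov if total_cov else np.nan
        n_meth = (
            int((covered["call"] == "methylated").sum())
            if "call" in covered
            else np.nan
        )
        rows.append(
            {
                "context": ctx,
                "n_sites": len(sub),
                "n_covered": len(covered),
                "weighted_level": level,
                "n_methylated": n_meth,
                "frac_methylated_covered": (
                    n_meth / len(covered) if len(covered) else np.nan
                ),
                "frac_methylated_all": n_meth / len(sub) if len(sub) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def methylation_level_histogram(
    sites: pd.DataFrame, n_levels: int = 10, depth_min: int = 5
) -> pd.DataFrame:
    """Counts of covered sites in ``n_levels`` equal level bins per context.

    Bins are [0,10%), [10,20%), ..., [90,100%] — the top bin is closed so a
    fully methylated site lands in the last bin.
    """
    covered = sites[sites["c_total"] >= depth_min]
    level = covered["c_meth"] / covered["c_total"]
    idx = np.minimum((level * n_levels).astype(int), n_levels - 1)
    out = pd.DataFrame(
        0,
        index=pd.RangeIndex(n_levels, name="level_bin"),
        columns=list(CONTEXTS),
    )
    tab = pd.crosstab(idx, covered["context"])
    for ctx in tab.columns:
        out.loc[tab.index, ctx] = tab[ctx]
    return out


def interval_weighted_levels(
    sites: pd.DataFrame,
    intervals: pd.DataFrame,
    context: str | None = None,
    depth_min: int = 0,
) -> pd.DataFrame:
    """Weighted level of many intervals at once (cumulative-sum lookup).

    ``intervals`` needs chrom/start/end columns; the result carries
    ``n_sites, sum_c_meth, sum_c_total, level`` aligned to its rows.
    """
    sub = sites
    if context is not None:
        sub = sub[sub["context"] == context]
    if depth_min:
        sub = sub[sub["c_total"] >= depth_min]
    n = np.zeros(len(intervals), dtype=np.int64)
    cm = np.zeros(len(intervals), dtype=np.int64)
    ct = np.zeros(len(intervals), dtype=np.int64)
    for chrom, grp in sub.groupby("chrom", sort=False):
        sel = np.nonzero((intervals["chrom"] == chrom).to_numpy())[0]
        if sel.size == 0:
            continue
        grp = grp.sort_values("pos", kind="mergesort")
        pos = grp["pos"].to_numpy()
        cum_m = np.concatenate([[0], np.cumsum(grp["c_meth"].to_numpy())])
        cum_t = np.concatenate([[0], np.cumsum(grp["c_total"].to_numpy())])
        lo = np.searchsorted(pos, intervals["start"].to_numpy()[sel], side="left")
        hi = np.searchsorted(pos, intervals["end"].to_numpy()[sel], side="left")
        n[sel] = hi - lo
        cm[sel] = cum_m[hi] - cum_m[lo]
        ct[sel] = cum_t[hi] - cum_t[lo]
    out = intervals.reset_index(drop=True).copy()
    out["n_sites"] = n
    out["sum_c_meth"] = cm
    out["sum_c_total"] = ct
    with np.errstate(invalid="ignore", divide="ignore"):
        out["level"] = np.where(ct > 0, cm / np.maximum(ct, 1), np.nan)
    return out


def context_share(sites: pd.DataFrame) -> dict:
    """Fractions of methylated calls falling in CG / CHG / CHH."""
    meth = sites[sites["call"] == "methylated"]
    n = len(meth)
    if n == 0:
        return {ctx: float("nan") for ctx in CONTEXTS}
    counts = meth["context"].value_counts()
    return {ctx: float(counts.get(ctx, 0)) / n for ctx in CONTEXTS}
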