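"""Expression quantification and allele-specific expression (ASE).

TPM is the standard within-sample normalization (count/length rates scaled
to one million). Expression rank groups follow fixed TPM boundaries:
N (TPM = 0), L (0 < TPM <= 1), LM (1 < TPM <= 7), MH (7 < TPM <= 100),
H (TPM > 100).

Differential expression and ASE use exact binomial rate-ratio tests on
library-size-normalized pooled counts (BH-corrected), gated by a
|log2 fold-change| threshold with a pseudocount of 1 on normalized means.
No dispersion modeling is attempted; see the methods note for what that
omission implies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

RANK_GROUPS = ["N", "L", "LM", "MH", "H"]


def compute_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """TPM matrix (genes x samples) from raw counts and union-exon lengths."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:3].tolist()
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("zero or negative gene length")
    rate = counts.div(lengths, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def rank_expression(tpm: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Assign the N/L/LM/MH/H rank group per gene (per sample)."""
    def _rank(x: float) -> str:
        if x == 0:
            return "N"
        if x <= 1:
            return "L"
        if x <= 7:
            return "LM"
        if x <= 100:
            return "MH"
        return "H"

    if isinstance(tpm, pd.Series):
        return tpm.map(_rank)
    return tpm.map(_rank)


def _rate_ratio_test(x1, n1, x2, n2):
    """Exact conditional binomial test of two Poisson rates.

    Conditional on the total x1 + x2, x1 ~ Binomial(x1 + x2, n1/(n1+n2))
    under the null of equal rates. Vectorized two-sided p-values.
    """
    x1 = np.asarray(x1, dtype=np.int64)
    x2 = np.asarray(x2, dtype=np.int64)
    tot = x1 + x2
    prop = n1 / (n1 + n2)
    p = np.ones(x1.shape, dtype=float)
    nz = tot > 0
    # two-sided via summing tail probabilities not exceeding the observed one
    for i in np.nonzero(nz)[0]:
        p[i] = stats.binomtest(int(x1[i]), int(tot[i]), prop).pvalue
    return p


def call_degs(
    counts: pd.DataFrame,
    test_samples: list[str],
    control_samples: list[str],
    lfc: float = 1.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Differential expression: exact rate-ratio test + fold-change gate.

    Counts are pooled within group and normalized by total library size;
    log2fc uses a pseudocount of 1 on the normalized means. A gene is a DEG
    iff q < ``fdr`` and |log2fc| > ``lfc``; all-zero genes are ``ns``.
    """
    x1 = counts[test_samples].sum(axis=1).to_numpy()
    x2 = counts[control_samples].sum(axis=1).to_numpy()
    n1 = counts[test_samples].to_numpy().sum()
    n2 = counts[control_samples].to_numpy().sum()
    scale = (n1 + n2) / 2
    mean1 = x1 / n1 * scale
    mean2 = x2 / n2 * scale
    log2fc = np.log2((mean1 + 1) / (mean2 + 1))
    p = _rate_ratio_test(x1, n1, x2, n2)
    q = multipletests(p, method="fdr_bh")[1]
    status = np.where(
        (q < fdr) & (np.abs(log2fc) > lfc),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    status[(x1 + x2) == 0] = "ns"
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "q_value": q, "deg_status": status},
        index=counts.index,
    )


def classify_ase(
    maternal: pd.DataFrame,
    paternal: pd.DataFrame,
    fdr: float = 0.05,
    lfc: float = 1.0,
) -> pd.DataFrame:
    """Allele-specific expression classes per allele pair.

    Counts are pooled across samples per allele; the test is an exact
    binomial test of maternal reads against the expected maternal
    proportion given the library-size-normalized allele totals. Classes:
    M (maternal-biased), P (paternal-biased), U (unbiased: not significant
    or |log2fc| below ``lfc``). Pairs with zero total counts are U with an
    undefined log2fc flag.
    """
    if not maternal.index.equals(paternal.index):
        raise ValueError("maternal/paternal tables must share the pair index")
    xm = maternal.sum(axis=1).to_numpy()
    xp = paternal.sum(axis=1).to_numpy()
    nm = maternal.to_numpy().sum()
    np_ = paternal.to_numpy().sum()
    scale = (nm + np_) / 2
    mean_m = xm / nm * scale
    mean_p = xp / np_ * scale
    log2fc = np.log2((mean_m + 1) / (mean_p + 1))
    p = _rate_ratio_test(xm, nm, xp, np_)
    q = multipletests(p, method="fdr_bh")[1]
    biased = (q < fdr) & (np.abs(log2fc) >= lfc)
    cls = np.where(biased, np.where(log2fc > 0, "M", "P"), "U")
    undefined = (xm + xp) == 0
    cls[undefined] = "U"
    out = pd.DataFrame(
        {
            "maternal_total": xm,
            "paternal_total": xp,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "bias_class": cls,
            "undefined_log2fc": undefined,
        },
        index=maternal.index,
    )
    out.loc[undefined, "log2fc"] = np.nan
    return out


def crosstab_bias(
    epimutant_classes: pd.Series, control_classes: pd.Series
) -> pd.DataFrame:
    """3x3 table of (epimutant class x control class) over the same pairs."""
    if not epimutant_classes.index.equals(control_classes.index):
        raise ValueError("class series must share the same pair universe")
    order = ["M", "P", "U"]
    tab = pd.crosstab(epimutant_classes, control_classes)
    return tab.reindex(index=order, columns=order, fill_value=0)
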