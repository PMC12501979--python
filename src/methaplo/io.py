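"""Readers and writers for the external text formats.

Conventions: everything is 0-based half-open in memory; cytosine reports,
GFF3 and SyRI tables are 1-based inclusive on disk (Bismark/GFF3
convention); BED is 0-based half-open on disk. CG sites are kept per
strand, not collapsed to symmetric CpG pairs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import CONTEXTS

log = logging.getLogger("methaplo")

SYRI_TYPES = frozenset(
    {"SYN", "INV", "TRANS", "INVTR", "DUP", "INVDP", "CPL", "CPG", "INS", "DEL", "SNP"}
)

CYTOSINE_REPORT_COLUMNS = [
    "chrom", "pos", "strand", "count_methylated", "count_unmethylated",
    "context", "tri",
]


class FormatError(ValueError):
    """Malformed or out-of-contract input file content."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open
    end: int
    exons: list = field(default_factory=list)
    is_te_overlapping: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = self.start
        for s, e in self.exons:
            if s < prev_end or e > self.end or e <= s:
                raise ValueError(f"{self.gene_id}: bad exon structure")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def union_exon_length(self) -> int:
        return sum(e - s for s, e in self.exons) or (self.end - self.start)


@dataclass
class SvRecord:
    raw_type: str
    ref_chrom: str
    ref_start: int  # 0-based half-open
    ref_end: int
    query_chrom: str
    query_start: int
    query_end: int
    copy_status: str = "-"  # copygain / copyloss for DUP/INVDP, else "-"
    grouped_category: str | None = None

    @property
    def length(self) -> int:
        return max(self.ref_end - self.ref_start, self.query_end - self.query_start)


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

def read_cytosine_report(path: str | Path, min_depth: int = 5) -> pd.DataFrame:
    """Read a Bismark-style per-cytosine report.

    Columns on disk: chrom, 1-based position, strand, count_methylated,
    count_unmethylated, context (CG/CHG/CHH), trinucleotide. Sub-threshold
    sites (depth < ``min_depth``) are flagged, never dropped — filtering is
    the caller's decision.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=CYTOSINE_REPORT_COLUMNS,
            dtype={
                "chrom": str, "pos": np.int64, "strand": str,
                "count_methylated": np.int64, "count_unmethylated": np.int64,
                "context": str, "tri": str,
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: malformed cytosine report: {exc}") from exc
    if df.empty:
        out = pd.DataFrame(
            columns=["chrom", "pos", "strand", "context", "tri",
                     "c_meth", "c_total", "sub_threshold"]
        )
        return out
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 1
        raise FormatError(
            f"{path}: unknown context {df.loc[bad, 'context'].iloc[0]!r} at line {line}"
        )
    neg = (df["count_methylated"] < 0) | (df["count_unmethylated"] < 0)
    if neg.any():
        line = int(np.nonzero(neg.to_numpy())[0][0]) + 1
        raise FormatError(f"{path}: negative read count at line {line}")
    if (df["pos"] < 1).any():
        raise FormatError(f"{path}: positions must be 1-based (>= 1)")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"] - 1,  # to 0-based
            "strand": df["strand"],
            "context": df["context"],
            "tri": df["tri"],
            "c_meth": df["count_methylated"],
            "c_total": df["count_methylated"] + df["count_unmethylated"],
        }
    )
    out["sub_threshold"] = out["c_total"] < min_depth
    log.info("read %d cytosine sites from %s (min_depth=%d, %d sub-threshold)",
             len(out), path, min_depth, int(out["sub_threshold"].sum()))
    return out


def write_cytosine_report(sites: pd.DataFrame, path: str | Path) -> None:
    """Inverse of :func:`read_cytosine_report` (1-based on disk)."""
    df = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"] + 1,
            "strand": sites["strand"],
            "count_methylated": sites["c_meth"],
            "count_unmethylated": sites["c_total"] - sites["c_meth"],
            "context": sites["context"],
            "tri": sites.get("tri", pd.Series(["CNN"] * len(sites))),
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# SyRI-style structural-variant tables
# ---------------------------------------------------------------------------

_SYRI_COLUMNS = [
    "ref_chrom", "ref_start", "ref_end", "query_chrom", "query_start",
    "query_end", "type", "copy_status",
]


def read_syri_table(path: str | Path) -> list[SvRecord]:
    """Read a SyRI-style variant table (1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=0)
    missing = set(_SYRI_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.type not in SYRI_TYPES:
            raise FormatError(f"{path}: unknown SV type code {row.type!r} at line {i}")
        records.append(
            SvRecord(
                raw_type=row.type,
                ref_chrom=str(row.ref_chrom),
                ref_start=int(row.ref_start) - 1,
                ref_end=int(row.ref_end),
                query_chrom=str(row.query_chrom),
                query_start=int(row.query_start) - 1,
                query_end=int(row.query_end),
                copy_status=str(row.copy_status),
            )
        )
    log.info("read %d SyRI records from %s", len(records), path)
    return records


def write_syri_table(records: list[SvRecord], path: str | Path) -> None:
    rows = [
        {
            "ref_chrom": r.ref_chrom,
            "ref_start": r.ref_start + 1,
            "ref_end": r.ref_end,
            "query_chrom": r.query_chrom,
            "query_start": r.query_start + 1,
            "query_end": r.query_end,
            "type": r.raw_type,
            "copy_status": r.copy_status,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_SYRI_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(intervals, path: str | Path) -> None:
    """Write intervals as 5-column BED, score = level x 1000 (rounded).

    ``intervals`` is an iterable of objects or mappings carrying
    chrom/start/end and optionally ``level`` (fraction). Output is sorted by
    (chrom, start) for determinism.
    """
    rows = []
    for iv in intervals:
        get = iv.get if isinstance(iv, dict) else lambda k, d=None: getattr(iv, k, d)
        level = get("level", None)
        if level is None or (isinstance(level, float) and np.isnan(level)):
            score = 0
        else:
            score = int(round(float(level) * 1000))
        rows.append((str(get("chrom")), int(get("start")), int(get("end")), ".", score))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name", "score"]
    try:
        return pd.read_csv(path, sep="\t", header=None, names=cols)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=cols)


# ---------------------------------------------------------------------------
# FASTA and GFF3
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(genes: list[GeneModel], path: str | Path, source: str = "methaplo") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f"ID={g.gene_id};te_overlap={int(g.is_te_overlapping)}"
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr["ID"]
                genes[gid] = GeneModel(
                    gene_id=gid, chrom=chrom, strand=strand,
                    start=int(start) - 1, end=int(end),
                    is_te_overlapping=bool(int(attr.get("te_overlap", "0"))),
                )
            elif ftype == "exon":
                exons.setdefault(attr["Parent"], []).append((int(start) - 1, int(end)))
    out = []
    for gid, g in genes.items():
        g.exons = sorted(exons.get(gid, []))
        out.append(g)
    out.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return out


def write_te_gff3(tes: pd.DataFrame, path: str | Path) -> None:
    """TE intervals (chrom, start, end, family) as repeat_region features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        df = tes.sort_values(["chrom", "start"], kind="mergesort")
        for i, row in enumerate(df.itertuples(index=False), 1):
            fh.write(
                f"{row.chrom}\tmethaplo\trepeat_region\t{row.start + 1}\t{row.end}"
                f"\t.\t+\t.\tID=te{i};family={row.family}\n"
            )


def read_te_gff3(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            attr = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            rows.append(
                {"chrom": parts[0], "start": int(parts[3]) - 1, "end": int(parts[4]),
                 "family": attr.get("family", "unknown")}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "family"])


# ---------------------------------------------------------------------------
# tables, matrices, truth
# ---------------------------------------------------------------------------

def read_allele_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("pair_id", "maternal_id", "paternal_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return df


def write_allele_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_count_matrix(mat: pd.DataFrame, path: str | Path) -> None:
    mat.to_csv(path, sep="\t")


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=_jsonify)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonify(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
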