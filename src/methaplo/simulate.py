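"""Synthetic haplotype-resolved epimutant study generator.

Generates everything the pipeline consumes: a two-haplotype toy genome with
genes, TEs, SNPs and structural variants (plus telomeric repeat arrays and
an unmethylated lambda spike-in), per-sample x replicate cytosine count
reports with the statistical structure of plant WGBS data, and allele-level
expression count matrices — together with a ground-truth record that makes
parameter-recovery tests possible.

Statistical structure emulated:

* site-level CG/CHG methylation is bimodal (high mode near 0.95, low mode
  near 0.03); CHH is dominated by the low mode;
* TE cytosines are shifted toward the high mode, gene bodies are
  CG-enriched, and levels dip near the TSS/TTS;
* epimutants are demethylated region-wise (coherent 200-2000 bp patches,
  per context, density calibrated to the requested genome-wide reduction
  in percentage points);
* known DMRs are implanted with a stated margin above the detection
  threshold;
* allele pairs carry latent per-context methylation divergences; pairs
  overlapping SVs get larger CG/CHG divergence (and smaller CHH);
* allele expression log2 fold-change = coupling x (CG divergence) + noise,
  with negative-binomial counts; gene expression couples negatively to
  gene-body CG methylation both across genes and across samples.

Read counts are binomial at Poisson-distributed per-site depth; lambda
sites emit counts at the bisulfite conversion error rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .config import CONTEXTS
from .io import GeneModel, SvRecord
from .methylome import context_map, revcomp

log = logging.getLogger("methaplo")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TELOMERE_MOTIF = "TTTAGGG"


@dataclass
class SampleSpec:
    name: str
    role: str  # control | epimutant
    demethylation: dict = field(default_factory=lambda: {"CG": 0.0, "CHG": 0.0, "CHH": 0.0})


def default_samples() -> list[SampleSpec]:
    """Two untreated controls plus four epimutants of varying strength.

    The strongest epimutant loses 10.78 / 5.88 points genome-wide in
    CG / CHG; the others are moderate.
    """
    return [
        SampleSpec("AZA0-3", "control"),
        SampleSpec("AZA0-7", "control"),
        SampleSpec("AZA25-7", "epimutant", {"CG": 3.0, "CHG": 2.0, "CHH": 0.8}),
        SampleSpec("AZA50-11", "epimutant", {"CG": 10.78, "CHG": 5.88, "CHH": 2.0}),
        SampleSpec("AZA100-5", "epimutant", {"CG": 2.5, "CHG": 2.0, "CHH": 0.5}),
        SampleSpec("AZA100-14", "epimutant", {"CG": 4.0, "CHG": 3.0, "CHH": 1.0}),
    ]


@dataclass
class SimulationSpec:
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 200
    te_fraction: float = 0.12
    snp_rate: float = 0.01
    sv_counts: dict = field(default_factory=lambda: {
        "INS": 12, "DEL": 12, "INV": 4, "TRANS": 5, "INVTR": 2,
        "DUP": 3, "INVDP": 2, "CPL": 3, "CPG": 3,
    })
    n_short_indels: int = 40
    n_allele_svs: int = 40
    samples: list = field(default_factory=default_samples)
    replicates: int = 2
    mean_depth: float = 20.0
    conversion_error: float = 0.01
    asm_ase_coupling: float = 0.025  # log2FC per percentage point of CG divergence
    ase_noise_sd: float = 0.15
    nb_dispersion: float = 0.1
    expr_meth_coupling: float = 6.0  # log2FC per unit drop in gene-body CG level
    asm_fraction: float = 0.35
    sv_divergence: bool = True
    n_implants: dict = field(default_factory=lambda: {"CG": 40, "CHG": 20, "CHH": 15})
    implant_delta: dict = field(default_factory=lambda: {"CG": 40.0, "CHG": 40.0, "CHH": 25.0})
    implant_hyper_fraction: float = 0.2
    implant_length: int = 400
    telomere_copies: int = 30
    lambda_length: int = 20_000
    hifi_depth: float = 12.0
    hifi_mean_length: float = 19_557.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.conversion_error <= 0.05:
            raise ValueError("conversion_error must be in (0, 0.05]")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2 for DMR testing")
        for s in self.samples:
            for v in s.demethylation.values():
                if not 0 <= v <= 100:
                    raise ValueError("demethylation strengths must be in [0, 100]")
        if self.n_chroms < 1 or self.chrom_length < 20_000:
            raise ValueError("need at least one chromosome of >= 20 kb")


@dataclass
class SimulatedStudy:
    spec: SimulationSpec
    hap1: dict
    hap2: dict
    genes_hap1: list
    genes_hap2: list
    tes: pd.DataFrame
    svs: list
    pairs: pd.DataFrame
    anchors: dict  # chrom -> (ref_pts, query_pts)
    truth: dict

    def ref_to_query(self, chrom: str, pos) -> np.ndarray:
        r, q = self.anchors[chrom]
        return np.rint(np.interp(pos, r, q)).astype(np.int64)

    def query_to_ref(self, chrom: str, pos) -> np.ndarray:
        r, q = self.anchors[chrom]
        return np.rint(np.interp(pos, q, r)).astype(np.int64)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

def simulate_genomes(spec: SimulationSpec) -> SimulatedStudy:
    """Build hap1, derive hap2 by SNP/indel/SV editing, and record the truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tel = TELOMERE_MOTIF * spec.telomere_copies
    tel_len = len(tel)
    margin = tel_len + 1500

    hap1: dict[str, str] = {}
    genes: list[GeneModel] = []
    te_rows = []
    genes_per_chrom = spec.n_genes // spec.n_chroms

    for ci in range(spec.n_chroms):
        chrom = f"chr{ci + 1}"
        core = _random_seq(rng, spec.chrom_length - 2 * tel_len)
        seq = revcomp(tel) + core + tel
        # genes at jittered regular anchors in the proximal 60% of the
        # interior; the distal 40% stays gene-free (repeat/SV territory)
        usable = int(0.6 * (spec.chrom_length - 2 * margin))
        pitch = usable / max(genes_per_chrom, 1)
        seq_genes = []
        for gi in range(genes_per_chrom):
            glen = int(rng.integers(1500, 4500))
            start = int(margin + gi * pitch + rng.integers(0, max(int(pitch) - glen - 2500, 1)))
            end = start + glen
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _random_exons(rng, start, end)
            seq_genes.append(GeneModel(
                gene_id=f"g{ci + 1}_{gi + 1}", chrom=chrom, strand=strand,
                start=start, end=end, exons=exons,
            ))
        genes.extend(seq_genes)
        # gene-TEs: TE covering most of the body for ~30% of genes
        for g in seq_genes:
            if rng.random() < 0.30:
                g.is_te_overlapping = True
                span = g.end - g.start
                te_rows.append({"chrom": chrom,
                                "start": g.start + span // 10,
                                "end": g.end - span // 10,
                                "family": str(rng.choice(["LTR", "LINE"]))})
        # intergenic TEs up to the target fraction
        target = spec.te_fraction * spec.chrom_length
        placed = sum(r["end"] - r["start"] for r in te_rows if r["chrom"] == chrom)
        gene_iv = sorted((g.start - 200, g.end + 200) for g in seq_genes)
        attempts = 0
        while placed < target and attempts < 10_000:
            attempts += 1
            tl = int(rng.integers(500, 4000))
            s = int(rng.integers(margin, spec.chrom_length - margin - tl))
            if any(s < e and s + tl > b for b, e in gene_iv):
                continue
            te_rows.append({"chrom": chrom, "start": s, "end": s + tl,
                            "family": str(rng.choice(["LTR", "LINE", "DNA"]))})
            placed += tl
        hap1[chrom] = seq

    tes = pd.DataFrame(te_rows, columns=["chrom", "start", "end", "family"])
    pairs = pd.DataFrame({
        "pair_id": [g.gene_id for g in genes],
        "maternal_id": [g.gene_id for g in genes],
        "paternal_id": [g.gene_id.replace("g", "h", 1) for g in genes],
    })

    # latent per-pair methylation divergence (maternal - paternal, points)
    n_pairs = len(pairs)
    is_asm = rng.random(n_pairs) < spec.asm_fraction
    sign = np.where(rng.random(n_pairs) < 0.5, 1.0, -1.0)
    delta_cg = np.where(is_asm, sign * rng.uniform(20, 90, n_pairs),
                        rng.normal(0, 6, n_pairs))
    truth: dict = {"pairs": {}, "implants": [], "samples": {}, "telomeres": {}}

    # structural variants -------------------------------------------------
    edits: dict[str, list] = {c: [] for c in hap1}
    svs: list[SvRecord] = []
    gene_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        gene_by_chrom.setdefault(g.chrom, []).append(g)

    def _free_intergenic(chrom, length, pad=2500):
        """A start position whose [s, s+length) avoids genes +- pad and edits."""
        for _ in range(400):
            s = int(rng.integers(margin, spec.chrom_length - margin - length))
            if any(s < g.end + pad and s + length > g.start - pad
                   for g in gene_by_chrom[chrom]):
                continue
            if any(s < e["pos"] + e["del_len"] + 100 and s + length > e["pos"] - 100
                   for e in edits[chrom]):
                continue
            return s
        raise ValueError("sv_counts exceed genome capacity")

    chrom_cycle = sorted(hap1)

    def _pick_chrom(i):
        return chrom_cycle[i % len(chrom_cycle)]

    i_sv = 0
    for raw_type, count in sorted(spec.sv_counts.items()):
        for _ in range(count):
            chrom = _pick_chrom(i_sv)
            i_sv += 1
            seq = hap1[chrom]
            if raw_type in ("INS", "CPG"):
                ln = int(rng.integers(60, 2000))
                pos = _free_intergenic(chrom, 1)
                ins = _random_seq(rng, ln)
                edits[chrom].append({"pos": pos, "del_len": 0, "ins": ins,
                                     "sv": len(svs)})
                svs.append(SvRecord(raw_type, chrom, pos, pos + 1, chrom, 0, 0))
            elif raw_type in ("DEL", "CPL"):
                ln = int(rng.integers(60, 2000))
                pos = _free_intergenic(chrom, ln)
                edits[chrom].append({"pos": pos, "del_len": ln, "ins": "",
                                     "sv": len(svs)})
                svs.append(SvRecord(raw_type, chrom, pos, pos + ln, chrom, 0, 0))
            elif raw_type == "INV":
                ln = int(rng.integers(2000, 8000))
                pos = _free_intergenic(chrom, ln)
                edits[chrom].append({"pos": pos, "del_len": ln,
                                     "ins": revcomp(seq[pos:pos + ln]),
                                     "sv": len(svs)})
                svs.append(SvRecord(raw_type, chrom, pos, pos + ln, chrom, 0, 0))
            elif raw_type in ("TRANS", "INVTR"):
                ln = int(rng.integers(1000, 4000))
                src = _free_intergenic(chrom, ln)
                edits[chrom].append({"pos": src, "del_len": ln, "ins": "",
                                     "sv": None})
                dest = _free_intergenic(chrom, 1)
                frag = seq[src:src + ln]
                if raw_type == "INVTR":
                    frag = revcomp(frag)
                edits[chrom].append({"pos": dest, "del_len": 0, "ins": frag,
                                     "sv": len(svs)})
                svs.append(SvRecord(raw_type, chrom, src, src + ln, chrom, 0, 0))
            elif raw_type in ("DUP", "INVDP"):
                ln = int(rng.integers(500, 3000))
                src = _free_intergenic(chrom, ln)
                gain = rng.random() < 0.5
                frag = seq[src:src + ln]
                if raw_type == "INVDP":
                    frag = revcomp(frag)
                if gain:  # query carries an extra copy
                    dest = _free_intergenic(chrom, 1)
                    edits[chrom].append({"pos": dest, "del_len": 0, "ins": frag,
                                         "sv": len(svs)})
                else:  # query lost a copy: delete the region
                    edits[chrom].append({"pos": src, "del_len": ln, "ins": "",
                                         "sv": len(svs)})
                svs.append(SvRecord(raw_type, chrom, src, src + ln, chrom, 0, 0,
                                    copy_status="copygain" if gain else "copyloss"))
            else:
                raise ValueError(f"unsupported sv_counts type {raw_type!r}")

    # allele-space SVs: indels in introns (biased to divergent pairs) or flanks
    asm_idx = np.nonzero(is_asm)[0]
    other_idx = np.nonzero(~is_asm)[0]
    sv_pair_rows = []
    for k in range(spec.n_allele_svs):
        in_intron = k % 2 == 0
        if in_intron:
            pool = asm_idx if (rng.random() < 0.75 and asm_idx.size) else other_idx
        else:
            pool = asm_idx if (rng.random() < 0.5 and asm_idx.size) else other_idx
        if pool.size == 0:
            continue
        gi = int(rng.choice(pool))
        g = genes[gi]
        ln = int(rng.integers(60, 300))
        if in_intron:
            introns = [(e1, s2) for (_, e1), (s2, _) in zip(g.exons, g.exons[1:])
                       if s2 - e1 > ln + 40]
            if not introns:
                continue
            a, b = introns[int(rng.integers(len(introns)))]
            pos = int(rng.integers(a + 20, b - ln - 20))
        else:
            if rng.random() < 0.5 and g.start - 1800 > margin:
                pos = int(rng.integers(g.start - 1800, g.start - 300))
            else:
                pos = g.end + int(rng.integers(200, 1700))
            # flank SVs must not cut into any gene body (keeps exon mapping clean)
            if any(pos < gg.end + 50 and pos + ln > gg.start - 50
                   for gg in gene_by_chrom[g.chrom]):
                continue
        if any(pos < e["pos"] + e["del_len"] + 20 and pos + ln > e["pos"] - 20
               for e in edits[g.chrom]):
            continue
        raw = "DEL" if rng.random() < 0.5 else "INS"
        if raw == "DEL":
            edits[g.chrom].append({"pos": pos, "del_len": ln, "ins": "",
                                   "sv": len(svs)})
            svs.append(SvRecord(raw, g.chrom, pos, pos + ln, g.chrom, 0, 0))
            sv_pair_rows.append((gi, pos, pos + ln))
        else:
            edits[g.chrom].append({"pos": pos, "del_len": 0,
                                   "ins": _random_seq(rng, ln), "sv": len(svs)})
            svs.append(SvRecord(raw, g.chrom, pos, pos + 1, g.chrom, 0, 0))
            sv_pair_rows.append((gi, pos, pos + 1))

    # short indels (<= 50 bp, intergenic)
    for k in range(spec.n_short_indels):
        chrom = _pick_chrom(k)
        ln = int(rng.integers(1, 51))
        try:
            pos = _free_intergenic(chrom, max(ln, 1), pad=300)
        except ValueError:
            continue
        if rng.random() < 0.5:
            edits[chrom].append({"pos": pos, "del_len": ln, "ins": "",
                                 "sv": len(svs)})
            svs.append(SvRecord("DEL", chrom, pos, pos + ln, chrom, 0, 0))
        else:
            edits[chrom].append({"pos": pos, "del_len": 0,
                                 "ins": _random_seq(rng, ln), "sv": len(svs)})
            svs.append(SvRecord("INS", chrom, pos, pos + 1, chrom, 0, 0))

    # SNPs in unedited territory
    snp_records = []
    for chrom in chrom_cycle:
        seq = hap1[chrom]
        n_snps = rng.binomial(spec.chrom_length - 2 * tel_len, spec.snp_rate)
        cand = rng.integers(tel_len, spec.chrom_length - tel_len, size=n_snps)
        cand = np.unique(cand)
        blocked = np.zeros(spec.chrom_length, dtype=bool)
        for e in edits[chrom]:
            blocked[e["pos"]:e["pos"] + max(e["del_len"], 1)] = True
        cand = cand[~blocked[cand]]
        for pos in cand:
            old = seq[pos]
            if old == "N":
                continue
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            edits[chrom].append({"pos": int(pos), "del_len": 1, "ins": new,
                                 "sv": len(svs)})
            svs.append(SvRecord("SNP", chrom, int(pos), int(pos) + 1, chrom, 0, 0))
            snp_records.append((chrom, int(pos)))

    # apply edits, build hap2 and the coordinate anchors -------------------
    hap2: dict[str, str] = {}
    anchors: dict[str, tuple] = {}
    for chrom in chrom_cycle:
        seq = hap1[chrom]
        evs = sorted(edits[chrom], key=lambda e: (e["pos"], e["del_len"]))
        parts = []
        r_pts = [0]
        q_pts = [0]
        cur = 0
        q = 0
        for e in evs:
            pre = seq[cur:e["pos"]]
            parts.append(pre)
            q += len(pre)
            r_pts.append(e["pos"])
            q_pts.append(q)
            q_start = q
            parts.append(e["ins"])
            q += len(e["ins"])
            cur = e["pos"] + e["del_len"]
            r_pts.append(cur)
            q_pts.append(q)
            if e["sv"] is not None:
                sv = svs[e["sv"]]
                if sv.query_end == 0:
                    sv.query_start = q_start
                    sv.query_end = max(q, q_start + 1)
        tail = seq[cur:]
        parts.append(tail)
        q += len(tail)
        r_pts.append(len(seq))
        q_pts.append(q)
        hap2[chrom] = "".join(parts)
        r_arr = np.array(r_pts, dtype=np.int64)
        q_arr = np.array(q_pts, dtype=np.int64)
        keep = np.concatenate([[True], np.diff(r_arr) >= 0])
        anchors[chrom] = (r_arr[keep], q_arr[keep])

    # SYN blocks between consecutive non-SNP edits
    for chrom in chrom_cycle:
        bounds = sorted(
            (e["pos"], e["pos"] + e["del_len"]) for e in edits[chrom]
            if e["del_len"] > 50 or len(e["ins"]) > 50
        )
        prev = 0
        r_arr, q_arr = anchors[chrom]
        for s, e in bounds + [(len(hap1[chrom]), len(hap1[chrom]))]:
            if s - prev > 1000:
                qs = int(np.interp(prev, r_arr, q_arr))
                qe = int(np.interp(s, r_arr, q_arr))
                svs.append(SvRecord("SYN", chrom, prev, s, chrom, qs, qe))
            prev = max(prev, e)

    study = SimulatedStudy(
        spec=spec, hap1=hap1, hap2=hap2, genes_hap1=genes, genes_hap2=[],
        tes=tes, svs=svs, pairs=pairs, anchors=anchors, truth=truth,
    )

    # map genes onto hap2
    genes2 = []
    for g in genes:
        s2, e2 = study.ref_to_query(g.chrom, [g.start, g.end])
        exons2 = [tuple(study.ref_to_query(g.chrom, [a, b])) for a, b in g.exons]
        genes2.append(GeneModel(
            gene_id=g.gene_id.replace("g", "h", 1), chrom=g.chrom,
            strand=g.strand, start=int(s2), end=int(e2),
            exons=[(int(a), int(b)) for a, b in exons2],
            is_te_overlapping=g.is_te_overlapping,
        ))
    study.genes_hap2 = genes2

    # per-pair truth: SV overlap and final divergence
    sv_overlap = np.zeros(n_pairs, dtype=bool)
    sv_iv_by_pair: dict[int, tuple] = {}
    for gi, sv_s, sv_e in sv_pair_rows:
        sv_overlap[gi] = True
        sv_iv_by_pair.setdefault(gi, (sv_s, sv_e))
    if spec.sv_divergence:
        boost = sv_overlap & is_asm
        delta_cg = np.where(boost, np.sign(delta_cg) * np.clip(np.abs(delta_cg) + 15, 45, 95),
                            delta_cg)
        # SV pairs that were not divergent become moderately divergent
        newly = sv_overlap & ~is_asm
        delta_cg = np.where(newly, sign * rng.uniform(35, 75, n_pairs), delta_cg)
        is_asm = is_asm | sv_overlap
    delta_chg = 0.7 * delta_cg
    chh_sign = np.where(rng.random(n_pairs) < 0.5, 1.0, -1.0)
    delta_chh = np.where(
        is_asm & ~sv_overlap, chh_sign * rng.uniform(8, 20, n_pairs),
        np.where(is_asm & sv_overlap, chh_sign * rng.uniform(0, 6, n_pairs),
                 rng.normal(0, 2, n_pairs)),
    ) if spec.sv_divergence else np.where(
        is_asm, chh_sign * rng.uniform(8, 20, n_pairs), rng.normal(0, 2, n_pairs)
    )
    for i, row in enumerate(pairs.itertuples(index=False)):
        truth["pairs"][row.pair_id] = {
            "is_asm": bool(is_asm[i]),
            "sv_overlap": bool(sv_overlap[i]),
            "sv_interval": list(sv_iv_by_pair.get(i, ())) or None,
            "delta": {"CG": float(delta_cg[i]), "CHG": float(delta_chg[i]),
                      "CHH": float(delta_chh[i])},
        }
    truth["telomeres"] = {c: ["start", "terminal"] for c in chrom_cycle}
    truth["n_snps"] = len(snp_records)
    return study


def _random_exons(rng, start, end):
    n_ex = int(rng.integers(3, 7))
    length = end - start
    cuts = np.sort(rng.choice(np.arange(200, length - 200, 10),
                              size=2 * (n_ex - 1), replace=False))
    bounds = [start] + (start + cuts).tolist() + [end]
    exons = []
    for i in range(0, len(bounds) - 1, 2):
        exons.append((int(bounds[i]), int(bounds[i + 1])))
    return exons


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

_MIX_WEIGHTS = {  # high / low / mid mode weights per context
    "CG": (0.42, 0.50, 0.08),
    "CHG": (0.21, 0.65, 0.14),
    "CHH": (0.02, 0.95, 0.03),
}


def _draw_mixture(rng: np.random.Generator, contexts: np.ndarray) -> np.ndarray:
    """Bimodal site-level methylation: high mode ~0.95, low mode ~0.03."""
    n = contexts.size
    lv = np.empty(n)
    u = rng.random(n)
    high = rng.beta(40, 2.1, n)
    low = rng.beta(0.5, 16, n)
    low_chh = rng.beta(0.3, 20, n)
    mid = rng.uniform(0.1, 0.9, n)
    for ctx, (wh, wl, _) in _MIX_WEIGHTS.items():
        m = contexts == ctx
        lo = low_chh if ctx == "CHH" else low
        lv[m] = np.where(u[m] < wh, high[m],
                         np.where(u[m] < wh + wl, lo[m], mid[m]))
    return np.clip(lv, 0.0, 0.995)


def _interval_mask(pos: np.ndarray, intervals, length: int) -> np.ndarray:
    cov = np.zeros(length + 1, dtype=np.int32)
    for s, e in intervals:
        cov[max(0, s)] += 1
        cov[min(length, e)] -= 1
    return np.cumsum(cov)[:-1][pos] > 0


@dataclass
class MethylomeTruth:
    """In-memory truth-side arrays (hap1 site tables + per-sample levels)."""
    sites: dict            # chrom -> DataFrame(pos, strand, context, tri)
    baseline: dict         # chrom -> np.ndarray of true levels
    sample_levels: dict    # sample -> chrom -> np.ndarray
    paternal_sites: dict   # pair_id -> DataFrame(pos, strand, context, tri, ref_pos)
    paternal_levels: dict  # sample -> pair_id -> np.ndarray
    lambda_sites: pd.DataFrame
    report_paths: dict     # (sample, rep, "hap1"|"hap2") -> Path


def simulate_methylome(study: SimulatedStudy, outdir: str | Path) -> MethylomeTruth:
    """Draw true site levels, apply divergences/implants/demethylation, emit reports."""
    spec = study.spec
    rng = np.random.default_rng(spec.seed + 1)
    outdir = Path(outdir)
    (outdir / "reports").mkdir(parents=True, exist_ok=True)

    sites: dict[str, pd.DataFrame] = {}
    baseline: dict[str, np.ndarray] = {}
    chrom_order = sorted(study.hap1)
    gene_by_chrom: dict[str, list] = {}
    for g in study.genes_hap1:
        gene_by_chrom.setdefault(g.chrom, []).append(g)

    for chrom in chrom_order:
        seq = study.hap1[chrom]
        cm = context_map(seq)
        pos = cm["pos"].to_numpy()
        ctx = cm["context"].to_numpy()
        lv = _draw_mixture(rng, ctx)
        L = len(seq)
        te_iv = [(r.start, r.end) for r in study.tes.itertuples(index=False)
                 if r.chrom == chrom]
        body_iv = [(g.start, g.end) for g in gene_by_chrom.get(chrom, [])]
        dip_iv = []
        for g in gene_by_chrom.get(chrom, []):
            dip_iv.append((g.start - 200, g.start + 200))
            dip_iv.append((g.end - 200, g.end + 200))
        if te_iv:
            in_te = _interval_mask(pos, te_iv, L)
            # TE hypermethylation: strong in CG/CHG, moderate in CHH
            m = in_te & (ctx != "CHH") & (rng.random(pos.size) < 0.5)
            lv[m] = rng.beta(40, 2.1, int(m.sum()))
            m = in_te & (ctx == "CHH") & (rng.random(pos.size) < 0.3)
            lv[m] = rng.beta(2, 8, int(m.sum()))
        if body_iv:
            m = (_interval_mask(pos, body_iv, L) & (ctx == "CG")
                 & (rng.random(pos.size) < 0.3))
            lv[m] = rng.beta(40, 2.1, int(m.sum()))
        if dip_iv:
            lv[_interval_mask(pos, dip_iv, L)] *= 0.25
        sites[chrom] = cm
        baseline[chrom] = lv

    genes1 = {g.gene_id: g for g in study.genes_hap1}
    genes2 = {g.gene_id: g for g in study.genes_hap2}

    # --- allele divergence patches (constitutive, shared by all samples) ---
    flank = 2000
    for row in study.pairs.itertuples(index=False):
        info = study.truth["pairs"][row.pair_id]
        g1 = genes1[row.maternal_id]
        lo, hi = max(0, g1.start - flank), g1.end + flank
        patches: dict[str, list] = {}
        for ctx_name in CONTEXTS:
            d = info["delta"][ctx_name]
            if abs(d) < 5:
                patches[ctx_name] = []
                continue
            n_patch = int(rng.integers(1, 3 if ctx_name == "CHH" else 4))
            ivs = []
            sv_iv = info.get("sv_interval")
            if sv_iv and spec.sv_divergence and ctx_name in ("CG", "CHG"):
                # SV-linked divergence is local to the variant itself
                s = max(lo, sv_iv[0] - 200)
                e = min(hi, sv_iv[1] + 200)
                if e - s >= 100:
                    ivs.append((s, e))
            for _ in range(n_patch - len(ivs)):
                ln = int(rng.integers(200, 600 if ctx_name == "CHH" else 1000))
                s = int(rng.integers(lo, max(hi - ln, lo + 1)))
                ivs.append((s, s + ln))
            patches[ctx_name] = ivs
            # set the maternal side so the divergence is realisable
            cm = sites[g1.chrom]
            posv = cm["pos"].to_numpy()
            ctxv = cm["context"].to_numpy()
            m = np.zeros(posv.size, dtype=bool)
            for s, e in ivs:
                m |= (posv >= s) & (posv < e)
            m &= ctxv == ctx_name
            if ctx_name == "CHH":
                peak = min(abs(d) / 100 + 0.12, 0.9)
            else:
                peak = min(max(0.55 + abs(d) / 200, abs(d) / 100 + 0.07), 0.95)
            m0 = peak if d > 0 else peak + d / 100
            baseline[g1.chrom][m] = np.clip(
                m0 + rng.normal(0, 0.02, int(m.sum())), 0.005, 0.995
            )
        info["patches"] = {c: [list(iv) for iv in v] for c, v in patches.items()}

    # --- paternal (hap2) allele-space site tables -------------------------
    maternal_interp = {}
    for chrom in chrom_order:
        cm = sites[chrom]
        maternal_interp[chrom] = {
            c: (cm.loc[cm["context"] == c, "pos"].to_numpy(),
                baseline[chrom][(cm["context"] == c).to_numpy()])
            for c in CONTEXTS
        }
    paternal_sites: dict[str, pd.DataFrame] = {}
    paternal_base: dict[str, np.ndarray] = {}
    for row in study.pairs.itertuples(index=False):
        info = study.truth["pairs"][row.pair_id]
        g1 = genes1[row.maternal_id]
        g2 = genes2[row.paternal_id]
        lo2, hi2 = max(0, g2.start - flank), g2.end + flank
        sub = context_map(study.hap2[g2.chrom][lo2:hi2])
        sub["pos"] = sub["pos"] + lo2
        sub["chrom"] = g2.chrom
        ref_pos = study.query_to_ref(g2.chrom, sub["pos"].to_numpy())
        sub["ref_pos"] = ref_pos
        lv = np.empty(len(sub))
        ctxv = sub["context"].to_numpy()
        for c in CONTEXTS:
            mc = ctxv == c
            xs, ys = maternal_interp[g1.chrom][c]
            if xs.size:
                lv[mc] = np.interp(ref_pos[mc], xs, ys)
            else:
                lv[mc] = 0.03
        lv += rng.normal(0, 0.01, lv.size)
        # apply the divergence inside the patches
        for c in CONTEXTS:
            d = info["delta"][c]
            ivs = info["patches"].get(c, [])
            if not ivs or abs(d) < 5:
                continue
            m = np.zeros(lv.size, dtype=bool)
            for s, e in ivs:
                m |= (ref_pos >= s) & (ref_pos < e)
            m &= ctxv == c
            lv[m] = lv[m] - d / 100
        paternal_sites[row.pair_id] = sub
        paternal_base[row.pair_id] = np.clip(lv, 0.005, 0.995)

    # --- implanted DMRs ---------------------------------------------------
    epimutants = [s for s in spec.samples if s.role == "epimutant"]
    blocked = {c: [(g.start - 2200, g.end + 2200) for g in gene_by_chrom.get(c, [])]
               for c in chrom_order}
    implant_targets: dict[str, list] = {s.name: [] for s in spec.samples}
    tel_len = len(TELOMERE_MOTIF) * spec.telomere_copies
    for s in epimutants:
        for ctx_name in CONTEXTS:
            n_imp = spec.n_implants.get(ctx_name, 0)
            delta = spec.implant_delta[ctx_name]
            for j in range(n_imp):
                chrom = chrom_order[j % len(chrom_order)]
                L = len(study.hap1[chrom])
                for _ in range(200):
                    st = int(rng.integers(tel_len + 1000, L - tel_len - 1000
                                          - spec.implant_length))
                    iv = (st, st + spec.implant_length)
                    if any(iv[0] < e and iv[1] > b for b, e in blocked[chrom]):
                        continue
                    break
                else:
                    continue
                blocked[chrom].append((iv[0] - 500, iv[1] + 500))
                hyper = (j % max(int(1 / max(spec.implant_hyper_fraction, 1e-9)), 1)
                         == 0) if spec.implant_hyper_fraction > 0 else False
                base_lv = 0.08 if hyper else 0.88
                cm = sites[chrom]
                posv = cm["pos"].to_numpy()
                m = ((posv >= iv[0]) & (posv < iv[1])
                     & (cm["context"].to_numpy() == ctx_name))
                baseline[chrom][m] = np.clip(
                    base_lv + rng.normal(0, 0.015, int(m.sum())), 0.005, 0.995
                )
                target = base_lv + (delta / 100 if hyper else -delta / 100)
                implant_targets[s.name].append(
                    {"chrom": chrom, "start": iv[0], "end": iv[1],
                     "context": ctx_name, "level": target,
                     "direction": "hyper" if hyper else "hypo"}
                )
                study.truth["implants"].append(
                    {"sample": s.name, "context": ctx_name, "chrom": chrom,
                     "start": iv[0], "end": iv[1], "delta": float(delta),
                     "direction": "hyper" if hyper else "hypo",
                     "baseline_level": base_lv}
                )

    # --- per-sample level arrays ------------------------------------------
    all_implant_iv = {c: [] for c in chrom_order}
    for imps in implant_targets.values():
        for imp in imps:
            all_implant_iv[imp["chrom"]].append((imp["start"] - 300, imp["end"] + 300))

    sample_levels: dict[str, dict[str, np.ndarray]] = {}
    paternal_levels: dict[str, dict[str, np.ndarray]] = {}
    for s in spec.samples:
        lv_s = {c: baseline[c].copy() for c in chrom_order}
        pat_s = {pid: arr.copy() for pid, arr in paternal_base.items()}
        truth_s = {"demethylation": dict(s.demethylation), "achieved_reduction": {},
                   "patch_coverage_bp": {}}
        if s.role == "epimutant":
            for ctx_name in CONTEXTS:
                strength = s.demethylation.get(ctx_name, 0.0)
                if strength <= 0:
                    truth_s["achieved_reduction"][ctx_name] = 0.0
                    truth_s["patch_coverage_bp"][ctx_name] = 0
                    continue
                drop, cov_bp = _apply_demethylation(
                    rng, study, sites, lv_s, pat_s, paternal_sites,
                    ctx_name, strength / 100, all_implant_iv,
                )
                truth_s["achieved_reduction"][ctx_name] = float(100 * drop)
                truth_s["patch_coverage_bp"][ctx_name] = int(cov_bp)
            for imp in implant_targets[s.name]:
                cm = sites[imp["chrom"]]
                posv = cm["pos"].to_numpy()
                m = ((posv >= imp["start"]) & (posv < imp["end"])
                     & (cm["context"].to_numpy() == imp["context"]))
                lv_s[imp["chrom"]][m] = np.clip(
                    imp["level"] + rng.normal(0, 0.01, int(m.sum())), 0.005, 0.995
                )
        sample_levels[s.name] = lv_s
        paternal_levels[s.name] = pat_s
        study.truth["samples"][s.name] = truth_s

    # --- gene-body CG level per sample (drives the expression coupling) ---
    for s in spec.samples:
        lv_s = sample_levels[s.name]
        vals = {}
        for row in study.pairs.itertuples(index=False):
            g = genes1[row.maternal_id]
            cm = sites[g.chrom]
            posv = cm["pos"].to_numpy()
            m = ((posv >= g.start) & (posv < g.end)
                 & (cm["context"].to_numpy() == "CG"))
            vals[row.maternal_id] = float(lv_s[g.chrom][m].mean()) if m.any() else 0.0
        study.truth["samples"][s.name]["gene_cg_level"] = vals

    # --- emission ----------------------------------------------------------
    lam_seq = _random_seq(np.random.default_rng(spec.seed + 2), spec.lambda_length)
    lam = context_map(lam_seq)
    lam["chrom"] = "lambda"
    report_paths = {}
    for s in spec.samples:
        for r in range(spec.replicates):
            frames = []
            for chrom in chrom_order:
                cm = sites[chrom]
                lv = sample_levels[s.name][chrom]
                frames.append(_emit_counts(rng, cm, chrom, lv, spec))
            frames.append(_emit_counts(rng, lam, "lambda",
                                       np.zeros(len(lam)), spec))
            hap1_df = pd.concat(frames, ignore_index=True)
            p1 = outdir / "reports" / f"{s.name}_rep{r + 1}_hap1.tsv"
            mio.write_cytosine_report(hap1_df, p1)
            report_paths[(s.name, r, "hap1")] = p1
            pat_frames = []
            for row in study.pairs.itertuples(index=False):
                sub = paternal_sites[row.pair_id]
                lv = paternal_levels[s.name][row.pair_id]
                pat_frames.append(
                    _emit_counts(rng, sub, str(sub["chrom"].iloc[0]) if len(sub)
                                 else "chr1", lv, spec)
                )
            hap2_df = pd.concat(pat_frames, ignore_index=True)
            hap2_df = hap2_df.sort_values(["chrom", "pos", "strand"],
                                          kind="mergesort")
            p2 = outdir / "reports" / f"{s.name}_rep{r + 1}_hap2pairs.tsv"
            mio.write_cytosine_report(hap2_df, p2)
            report_paths[(s.name, r, "hap2")] = p2
    return MethylomeTruth(
        sites=sites, baseline=baseline, sample_levels=sample_levels,
        paternal_sites=paternal_sites, paternal_levels=paternal_levels,
        lambda_sites=lam, report_paths=report_paths,
    )


def _apply_demethylation(rng, study, sites, lv_s, pat_s, paternal_sites,
                         ctx_name, target_drop, implant_iv):
    """Patch-wise demethylation until the genome-wide mean drops by target.

    Patches are 200-2000 bp, avoid implant zones, multiply levels by 0.08
    and also hit the paternal allele arrays through their hap1 coordinates.
    Coverage is capped at 85% of the genome.
    """
    chrom_order = sorted(sites)
    pos_by = {c: sites[c]["pos"].to_numpy() for c in chrom_order}
    ctx_by = {c: (sites[c]["context"] == ctx_name).to_numpy() for c in chrom_order}
    n_total = sum(int(m.sum()) for m in ctx_by.values())
    total_len = sum(len(study.hap1[c]) for c in chrom_order)
    cov_bp = 0
    removed = 0.0  # cumulative drop in the summed level, tracked per patch
    applied_patches = []
    tries = 0
    while (removed / n_total < target_drop and cov_bp <= 0.85 * total_len
           and tries < 100_000):
        tries += 1
        ci = int(rng.integers(len(chrom_order)))
        chrom = chrom_order[ci]
        L = len(study.hap1[chrom])
        ln = int(rng.integers(200, 2000))
        st = int(rng.integers(0, max(L - ln, 1)))
        if any(st < e and st + ln > b for b, e in implant_iv[chrom]):
            continue
        lo, hi = np.searchsorted(pos_by[chrom], [st, st + ln])
        if hi == lo:
            continue
        idx = np.nonzero(ctx_by[chrom][lo:hi])[0] + lo
        if idx.size == 0:
            continue
        before = lv_s[chrom][idx].sum()
        lv_s[chrom][idx] *= 0.08
        removed += before * 0.92
        cov_bp += ln
        applied_patches.append((chrom, st, st + ln))
    # replay the same patches on the paternal allele arrays
    patch_by_chrom: dict[str, np.ndarray] = {}
    for c in chrom_order:
        arr = np.array([(s0, e0) for pc, s0, e0 in applied_patches if pc == c],
                       dtype=np.int64).reshape(-1, 2)
        patch_by_chrom[c] = arr
    for pid, sub in paternal_sites.items():
        if not len(sub):
            continue
        ref_pos = sub["ref_pos"].to_numpy()
        chrom = str(sub["chrom"].iloc[0])
        arr = patch_by_chrom.get(chrom)
        if arr is None or not len(arr):
            continue
        lo, hi = int(ref_pos.min()), int(ref_pos.max()) + 1
        near = arr[(arr[:, 0] < hi) & (arr[:, 1] > lo)]
        if not len(near):
            continue
        ctxm = (sub["context"] == ctx_name).to_numpy()
        for s0, e0 in near:
            m = (ref_pos >= s0) & (ref_pos < e0) & ctxm
            if m.any():
                pat_s[pid][m] *= 0.08
    return removed / n_total, cov_bp


def _emit_counts(rng, cm: pd.DataFrame, chrom: str, levels: np.ndarray,
                 spec: SimulationSpec) -> pd.DataFrame:
    depth = rng.poisson(spec.mean_depth, len(cm))
    apparent = levels + (1.0 - levels) * spec.conversion_error
    c_meth = rng.binomial(depth, np.clip(apparent, 0, 1))
    return pd.DataFrame({
        "chrom": chrom,
        "pos": cm["pos"].to_numpy(),
        "strand": cm["strand"].to_numpy(),
        "context": cm["context"].to_numpy(),
        "tri": cm["tri"].to_numpy(),
        "c_meth": c_meth,
        "c_total": depth,
    })


# ---------------------------------------------------------------------------
# expression and allele counts
# ---------------------------------------------------------------------------

def simulate_allele_counts(
    study: SimulatedStudy,
    outdir: str | Path,
    expr_log_mean: float = 4.0,
    expr_log_sd: float = 2.5,
) -> dict:
    """Gene- and allele-level RNA count matrices with ASE/ASM coupling.

    Baseline gene abundance is log-normal, negatively coupled to the gene's
    baseline CG body methylation (the 12% most methylated genes are
    silenced). The allele log2 fold-change is
    ``asm_ase_coupling x deltaCG + noise``; epimutant samples additionally
    respond to their own demethylation (expression rises where gene CG
    methylation fell) and carry explicit DEG effects for 10% of genes.
    Counts are negative binomial (dispersion ``nb_dispersion``).
    """
    spec = study.spec
    rng = np.random.default_rng(spec.seed + 3)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs = study.pairs
    n = len(pairs)
    gene_ids = pairs["maternal_id"].tolist()
    control = next(s.name for s in spec.samples if s.role == "control")

    f_base = np.array([
        study.truth["samples"][control]["gene_cg_level"][g] for g in gene_ids
    ])
    silence_cut = np.quantile(f_base, 0.88)
    silenced = f_base >= silence_cut
    base = np.exp(rng.normal(expr_log_mean + 1.5 - 3.0 * f_base, expr_log_sd))
    base[silenced] = 0.0

    delta_cg = np.array([study.truth["pairs"][p]["delta"]["CG"]
                         for p in pairs["pair_id"]])
    true_lfc = spec.asm_ase_coupling * delta_cg + rng.normal(0, spec.ase_noise_sd, n)
    true_class = np.where(silenced | (base < 5), "U",
                          np.where(np.abs(true_lfc) < 1, "U",
                                   np.where(true_lfc > 0, "M", "P")))

    deg_effect = {}
    for s in spec.samples:
        if s.role == "epimutant":
            eff = np.zeros(n)
            hit = rng.random(n) < 0.10
            eff[hit] = (np.where(rng.random(int(hit.sum())) < 0.5, 1, -1)
                        * rng.uniform(1.2, 2.5, int(hit.sum())))
            deg_effect[s.name] = eff
        else:
            deg_effect[s.name] = np.zeros(n)

    disp = spec.nb_dispersion
    cols = {}
    mat_cols = {}
    pat_cols = {}
    truth_deg = {}
    for s in spec.samples:
        f_s = np.array([
            study.truth["samples"][s.name]["gene_cg_level"][g] for g in gene_ids
        ])
        meth_lfc = spec.expr_meth_coupling * (f_base - f_s)
        sample_lfc = deg_effect[s.name] + meth_lfc
        truth_deg[s.name] = sample_lfc
        mean_total = base * np.power(2.0, sample_lfc)
        mean_m = mean_total / 2 * np.power(2.0, true_lfc / 2)
        mean_p = mean_total / 2 * np.power(2.0, -true_lfc / 2)
        for r in range(spec.replicates):
            col = f"{s.name}_rep{r + 1}"
            cm = _nb_draw(rng, mean_m, disp)
            cp = _nb_draw(rng, mean_p, disp)
            mat_cols[col] = cm
            pat_cols[col] = cp
            cols[col] = cm + cp
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    maternal = pd.DataFrame(mat_cols, index=pd.Index(pairs["pair_id"], name="pair_id"))
    paternal = pd.DataFrame(pat_cols, index=pd.Index(pairs["pair_id"], name="pair_id"))
    mio.write_count_matrix(counts, outdir / "gene_counts.tsv")
    mio.write_count_matrix(maternal, outdir / "allele_counts_maternal.tsv")
    mio.write_count_matrix(paternal, outdir / "allele_counts_paternal.tsv")
    for i, pid in enumerate(pairs["pair_id"]):
        study.truth["pairs"][pid]["true_log2fc"] = float(true_lfc[i])
        study.truth["pairs"][pid]["true_bias_class"] = str(true_class[i])
    study.truth["deg_true_lfc"] = {
        s: {g: float(v) for g, v in zip(gene_ids, arr)}
        for s, arr in truth_deg.items()
    }
    study.truth["library_sizes"] = {c: int(v.sum()) for c, v in cols.items()}
    return {"counts": counts, "maternal": maternal, "paternal": paternal}


def _nb_draw(rng, mean, dispersion):
    """Negative binomial via gamma-Poisson mixture; mean 0 stays 0."""
    lam = np.where(mean > 0,
                   rng.gamma(1.0 / dispersion, np.maximum(mean, 1e-12) * dispersion),
                   0.0)
    return rng.poisson(lam)


def simulate_read_spans(study: SimulatedStudy) -> pd.DataFrame:
    """Long-read alignment spans for SV breakpoint validation.

    Reads tile each hap1 chromosome at ``hifi_depth``; lengths are normal
    around ``hifi_mean_length`` (sd 6 kb, floor 2 kb) so a realistic
    fraction exceeds the 20 kb high-confidence cutoff.
    """
    spec = study.spec
    rng = np.random.default_rng(spec.seed + 4)
    rows = []
    for chrom in sorted(study.hap1):
        L = len(study.hap1[chrom])
        n_reads = int(spec.hifi_depth * L / spec.hifi_mean_length)
        lengths = np.maximum(rng.normal(spec.hifi_mean_length, 6000, n_reads),
                             2000).astype(int)
        starts = rng.integers(-lengths // 2, L - lengths // 2, n_reads)
        for st, ln in zip(starts, lengths):
            rows.append({"chrom": chrom, "start": int(max(st, 0)),
                         "end": int(min(st + ln, L))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-call emission of the whole study
# ---------------------------------------------------------------------------

def simulate_study(spec: SimulationSpec, outdir: str | Path) -> tuple[SimulatedStudy, MethylomeTruth]:
    """Generate genomes, methylomes, counts and reads; write all inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_genomes(spec)
    mio.write_fasta(study.hap1, outdir / "hap1.fa")
    mio.write_fasta(study.hap2, outdir / "hap2.fa")
    mio.write_gff3(study.genes_hap1, outdir / "genes_hap1.gff3")
    mio.write_gff3(study.genes_hap2, outdir / "genes_hap2.gff3")
    mio.write_te_gff3(study.tes, outdir / "tes.gff3")
    mio.write_syri_table(study.svs, outdir / "syri.tsv")
    mio.write_allele_pairs(study.pairs, outdir / "allele_pairs.tsv")
    meth = simulate_methylome(study, outdir)
    simulate_allele_counts(study, outdir)
    reads = simulate_read_spans(study)
    reads.to_csv(outdir / "hifi_reads.tsv", sep="\t", index=False)
    mio.write_truth(study.truth, outdir / "truth.json")
    log.info("simulated study written to %s", outdir)
    return study, meth
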