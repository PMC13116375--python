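"""Format plumbing: BED, BEDPE, GFF-lite, liftover-block TSV, dense contact
matrices with a JSON sidecar, minimal VCF 4.2 and interaction tables.

All interval formats are 0-based half-open on disk (BED convention);
GFF-lite is converted from 1-based inclusive on read.  Numeric output uses
6 significant digits for reproducible diffs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chromatin import ContactMatrix
from .core import AnchoredPair, Interval, LiftoverBlock, LiftoverMap
from .sv import SVRecord

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# BED / BEDPE
# ---------------------------------------------------------------------------

def read_bed(path) -> list[Interval]:
    """BED3/BED6 (tab-separated, 0-based half-open)."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if start >= end:
            raise ValueError(f"{path}:{ln}: start {start} >= end {end}")
        meta = {}
        if len(parts) > 3 and parts[3]:
            meta["name"] = parts[3]
        if len(parts) > 4 and parts[4]:
            meta["score"] = float(parts[4])
        if len(parts) > 5 and parts[5]:
            meta["strand"] = parts[5]
        out.append(Interval(chrom, start, end, meta=meta))
    return out


def write_bed(intervals: Sequence[Interval], path, extra_cols=()) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if extra_cols or iv.meta.get("name") or "score" in iv.meta:
                fields.append(str(iv.meta.get("name", iv.genome_id or ".")))
                fields.append(FLOAT_FMT % iv.meta.get("score", 0.0))
                fields.append(str(iv.meta.get("strand", ".")))
            for col in extra_cols:
                val = iv.meta.get(col, ".")
                fields.append(FLOAT_FMT % val if isinstance(val, float) else str(val))
            fh.write("\t".join(fields) + "\n")


def read_bedpe(path) -> list[AnchoredPair]:
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        p = line.rstrip("\n").split("\t")
        if len(p) < 6:
            raise ValueError(f"{path}:{ln}: BEDPE needs >= 6 columns")
        a1 = Interval(p[0], int(p[1]), int(p[2]))
        a2 = Interval(p[3], int(p[4]), int(p[5]))
        score = float(p[7]) if len(p) > 7 and p[7] not in (".", "") else 0.0
        out.append(AnchoredPair(a1, a2, score=score))
    return out


def write_bedpe(loops: Sequence[AnchoredPair], path,
                labels: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, loop in enumerate(loops):
            fields = [loop.anchor1.chrom, str(loop.anchor1.start),
                      str(loop.anchor1.end), loop.anchor2.chrom,
                      str(loop.anchor2.start), str(loop.anchor2.end),
                      loop.genome_id or f"loop_{i}", FLOAT_FMT % loop.score]
            if labels is not None:
                fields.append(labels[i])
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# GFF-lite (gene records with strand; 1-based inclusive on disk)
# ---------------------------------------------------------------------------

def read_gff_genes(path) -> list[Interval]:
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        p = line.rstrip("\n").split("\t")
        if len(p) < 9:
            raise ValueError(f"{path}:{ln}: GFF needs 9 columns")
        if p[2] != "gene":
            continue
        start, end = int(p[3]) - 1, int(p[4])   # to 0-based half-open
        if start >= end:
            raise ValueError(f"{path}:{ln}: empty gene span")
        attrs = dict(kv.split("=", 1) for kv in p[8].split(";") if "=" in kv)
        out.append(Interval(p[0], start, end, meta={
            "strand": p[6], "gene_id": attrs.get("ID", f"gene_{ln}")}))
    return out


def write_gff_genes(genes: Sequence[Interval], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(genes):
            gid = g.meta.get("gene_id", f"gene_{i}")
            fh.write("\t".join([
                g.chrom, "panchrom3d", "gene", str(g.start + 1), str(g.end),
                ".", g.meta.get("strand", "+"), ".", f"ID={gid}"]) + "\n")


# ---------------------------------------------------------------------------
# Liftover block TSV
# ---------------------------------------------------------------------------

LIFTOVER_COLS = ["src_chrom", "src_start", "src_end",
                 "tgt_chrom", "tgt_start", "tgt_end"]


def read_liftover_map(path) -> LiftoverMap:
    df = pd.read_csv(path, sep="\t")
    missing = set(LIFTOVER_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    blocks = []
    for r in df.itertuples():
        if r.src_end - r.src_start != r.tgt_end - r.tgt_start:
            raise ValueError(f"{path}: block lengths differ at {r.src_start}")
        blocks.append(LiftoverBlock(r.src_chrom, int(r.src_start),
                                    int(r.src_end), r.tgt_chrom,
                                    int(r.tgt_start)))
    return LiftoverMap(blocks)


def write_liftover_map(lift_map: LiftoverMap, path) -> None:
    rows = [(b.src_chrom, b.src_start, b.src_end, b.tgt_chrom, b.tgt_start,
             b.tgt_end) for b in lift_map.blocks]
    pd.DataFrame(rows, columns=LIFTOVER_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dense contact matrix + sidecar
# ---------------------------------------------------------------------------

def write_contact_matrix(cm: ContactMatrix, path) -> None:
    path = Path(path)
    np.savetxt(path, cm.matrix, fmt=FLOAT_FMT, delimiter="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"chrom": cm.chrom, "bin_size": cm.bin_size,
         "n_bins": cm.n_bins}) + "\n")


def read_contact_matrix(path) -> ContactMatrix:
    path = Path(path)
    m = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    return ContactMatrix(chrom=meta["chrom"], bin_size=int(meta["bin_size"]),
                         matrix=m)


# ---------------------------------------------------------------------------
# Minimal VCF 4.2 (SVTYPE/END/SVLEN INFO; GT:DP:GQ FORMAT)
# ---------------------------------------------------------------------------

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}


def write_sv_vcf(svs: Sequence[SVRecord], path,
                 samples: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if samples:
            cols += ["FORMAT", *samples]
        fh.write("\t".join(cols) + "\n")
        for sv in svs:
            info = f"SVTYPE={sv.sv_type};END={sv.end};SVLEN={sv.size}"
            row = [sv.chrom, str(sv.start + 1), sv.sv_id or ".", "N",
                   f"<{sv.sv_type}>", ".", "PASS", info]
            if samples:
                row.append("GT:DP:GQ")
                for s in samples:
                    gt, dp, gq = (sv.genotypes or {}).get(s, (None, 0, 0))
                    row.append(f"{_GT_STR.get(gt, './.')}:{dp}:{gq}")
            fh.write("\t".join(row) + "\n")


def read_sv_vcf(path) -> tuple[list[SVRecord], list[str]]:
    """Read a minimal SV VCF through cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out = []
    for var in vcf:
        svtype = var.INFO.get("SVTYPE")
        end = int(var.INFO.get("END", var.POS))
        svlen = abs(int(var.INFO.get("SVLEN", end - var.POS + 1)))
        start = var.POS - 1
        if svtype == "INS":
            end = start + 1
        genotypes = None
        if samples:
            genotypes = {}
            gts = var.genotypes          # [allele1, allele2, phased]
            dps = var.format("DP")
            gqs = var.format("GQ")
            for i, s in enumerate(samples):
                alleles = [a for a in gts[i][:2] if a >= 0]
                gt = sum(alleles) if len(alleles) == 2 else None
                dp = int(dps[i][0]) if dps is not None else 0
                gq = int(gqs[i][0]) if gqs is not None else 0
                genotypes[s] = (gt, dp, gq)
        out.append(SVRecord(var.CHROM, start, max(end, start + 1), svtype,
                            svlen, sv_id=var.ID or "", genotypes=genotypes))
    return out, samples


# ---------------------------------------------------------------------------
# Interaction tables / generic TSV
# ---------------------------------------------------------------------------

INTERACTION_COLS = ["bait_chrom", "bait_start", "bait_end",
                    "oe_chrom", "oe_start", "oe_end", "score_wt", "score_mt"]


def read_interaction_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(INTERACTION_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
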