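"""Readers, writers and alignment utilities.

Canonical pileup dialect
------------------------
A tab-separated file with a header line and columns::

    chrom  pos  ref  A_plus  A_minus  C_plus  C_minus  G_plus  G_minus  T_plus  T_minus

``pos`` is 1-based; counts include only bases whose quality met the caller's
floor.  samtools-mpileup text output (6 columns, no header) is detected
automatically and converted, applying the base-quality floor from the
Phred+33 quality string.

VCF is parsed with pysam (4.x semantics: genotype from the first sample's
GT, depth from the DP format or info field).  BED intervals are half-open
0-based and converted to 1-based closed positions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cohort import SnpSet
from .pipeline import COUNT_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "combine_aligner_reads",
    "read_pileup_counts",
    "write_pileup_counts",
    "read_vcf_variants",
    "write_vcf_variants",
    "read_snp_positions",
    "read_bed_intervals",
    "write_results",
    "write_run_dir",
]

PILEUP_COLUMNS = ["chrom", "pos", "ref", *COUNT_COLUMNS]


# ---------------------------------------------------------------------------
# dual-aligner read combination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read as reported by one aligner."""

    read_id: str
    chrom: str
    pos: int
    strand: str
    score: float
    aligner: str  # "aligner_a" | "aligner_b"

    @property
    def location(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


def _dedupe(records: Iterable[AlignmentRecord]) -> dict:
    """Per input: keep max score per (read, location); warn on duplicates."""
    best: dict[tuple, AlignmentRecord] = {}
    for rec in records:
        key = (rec.read_id, rec.location)
        if key in best:
            logger.warning("duplicate record for read %s at %s; keeping max score", rec.read_id, rec.location)
            if rec.score > best[key].score:
                best[key] = rec
        else:
            best[key] = rec
    out: dict[str, list[AlignmentRecord]] = {}
    for rec in best.values():
        out.setdefault(rec.read_id, []).append(rec)
    return out


def combine_aligner_reads(
    reads_a: Sequence[AlignmentRecord], reads_b: Sequence[AlignmentRecord]
) -> list[AlignmentRecord]:
    """Merge the outputs of two aligners into one record per read.

    Rules: a read mapped by only one aligner is retained as-is; a read
    mapped to the same location by both keeps the higher-scoring record; a
    read mapped to different locations keeps the single highest-scoring
    record across both aligners.  Score ties break deterministically toward
    aligner_a, then lexicographically smaller location.
    """
    by_read_a = _dedupe(reads_a)
    by_read_b = _dedupe(reads_b)
    out = []
    for read_id in sorted(set(by_read_a) | set(by_read_b)):
        cands = by_read_a.get(read_id, []) + by_read_b.get(read_id, [])
        cands.sort(key=lambda r: (-r.score, r.aligner != "aligner_a", r.location))
        out.append(cands[0])
    return out


# ---------------------------------------------------------------------------
# pileup counts
# ---------------------------------------------------------------------------

def read_pileup_counts(path, min_base_quality: int = 25) -> pd.DataFrame:
    """Read per-site stranded base counts (canonical TSV or mpileup text).

    The canonical dialect is assumed to be pre-filtered at the quality
    floor; mpileup text is filtered here using the Phred+33 quality string.
    Malformed lines are skipped with line-numbered warnings; a file with no
    parseable content raises.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("chrom\t"):
        df = pd.read_csv(path, sep="\t")
        missing = set(PILEUP_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing pileup columns {sorted(missing)}")
        return df[PILEUP_COLUMNS]
    return _parse_mpileup(path, min_base_quality)


def _parse_mpileup(path: Path, min_base_quality: int) -> pd.DataFrame:
    rows = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                logger.warning("%s:%d: expected >=6 mpileup fields, got %d; skipped",
                               path, lineno, len(fields))
                n_bad += 1
                continue
            chrom, pos_s, ref, _depth, bases, quals = fields[:6]
            try:
                pos = int(pos_s)
                counts = _parse_mpileup_bases(ref.upper(), bases, quals, min_base_quality)
            except ValueError as exc:
                logger.warning("%s:%d: %s; skipped", path, lineno, exc)
                n_bad += 1
                continue
            rows.append({"chrom": chrom, "pos": pos, "ref": ref.upper(), **counts})
    if not rows:
        if n_bad:
            raise ValueError(f"{path}: no parseable mpileup lines")
        logger.warning("%s: empty pileup file", path)
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)


def _parse_mpileup_bases(ref: str, bases: str, quals: str, min_bq: int) -> dict:
    """Walk an mpileup base string, pairing base calls with quality chars."""
    counts = {c: 0 for c in COUNT_COLUMNS}
    if ref not in "ACGT":
        raise ValueError(f"unknown reference base {ref!r}")
    i = 0  # index into bases
    q = 0  # index into quals
    L = len(bases)
    while i < L:
        ch = bases[i]
        if ch == "^":
            i += 2  # start-of-read marker + mapping quality char
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            i += 1
            num = ""
            while i < L and bases[i].isdigit():
                num += bases[i]
                i += 1
            i += int(num)  # skip the inserted/deleted sequence
            continue
        # every remaining symbol consumes one quality character
        if q >= len(quals):
            raise ValueError("base/quality string length mismatch")
        bq = ord(quals[q]) - 33
        q += 1
        i += 1
        if ch in "*><":
            continue  # deletion placeholder / reference skip
        if ch == ".":
            base, strand = ref, "plus"
        elif ch == ",":
            base, strand = ref, "minus"
        elif ch in "ACGTN":
            base, strand = ch, "plus"
        elif ch in "acgtn":
            base, strand = ch.upper(), "minus"
        else:
            raise ValueError(f"unexpected pileup symbol {ch!r}")
        if base == "N" or bq < min_bq:
            continue
        counts[f"{base}_{strand}"] += 1
    return counts


def write_pileup_counts(df: pd.DataFrame, path) -> None:
    df[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF / BED
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE
"""


def read_vcf_variants(path) -> pd.DataFrame:
    """Parse a VCF into rows ``chrom, pos, ref, alt, genotype, depth, qual``.

    Genotype comes from the first sample's GT (``hom`` when both alleles are
    the first ALT, ``het`` when exactly one is); depth from the sample DP.
    Multi-allelic records contribute their first ALT only.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alt = rec.alts[0] if rec.alts else None
            gt = None
            depth = None
            if rec.samples:
                smp = rec.samples[0]
                alleles = smp.get("GT")
                if alleles is not None and None not in alleles:
                    n_alt = sum(1 for a in alleles if a == 1)
                    gt = "hom" if n_alt == len(alleles) and n_alt > 0 else (
                        "het" if n_alt > 0 else "ref")
                depth = smp.get("DP")
            if depth is None:
                try:
                    depth = rec.info.get("DP")
                except ValueError:  # DP not declared in this header
                    depth = None
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": alt,
                    "genotype": gt,
                    "depth": depth,
                    "qual": rec.qual if rec.qual is not None else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "genotype", "depth", "qual"])


def write_vcf_variants(df: pd.DataFrame, path) -> None:
    """Write variant rows (as produced by the simulator) to a VCF text file."""
    contigs = "".join(
        f"##contig=<ID={c}>\n" for c in pd.unique(df["chrom"].astype(str))
    )
    gt_map = {"hom": "1/1", "het": "0/1", "ref": "0/0"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs))
        for row in df.itertuples(index=False):
            r = row._asdict()
            fh.write(
                f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t"
                f"{float(r['qual']):g}\tPASS\t.\tGT:DP\t{gt_map[str(r['genotype'])]}:{int(r['depth'])}\n"
            )


def read_snp_positions(path) -> SnpSet:
    """Load a known-SNP position set from VCF or BED (by extension/content)."""
    path = Path(path)
    suffixes = {s.lower() for s in path.suffixes}
    if ".vcf" in suffixes:
        df = read_vcf_variants(path)
        alleles: dict = {}
        for row in df.itertuples(index=False):
            alleles.setdefault((str(row.chrom), int(row.pos)), set()).add((str(row.ref), str(row.alt)))
        return SnpSet(alleles.keys(), alleles)
    # BED3+: half-open intervals, every covered position is a member
    positions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d: short BED line skipped", path, lineno)
                continue
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            positions.extend((chrom, p) for p in range(start + 1, end + 1))
    return SnpSet(positions)


def read_bed_intervals(path) -> pd.DataFrame:
    """Read a BED-derived gene interval table for annotation.

    Columns used: chrom, start, end, name, (score), (strand), (region) -
    a 7th column, when present, is taken as the region class.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rows.append(
                {
                    "chrom": f[0],
                    "start": int(f[1]),
                    "end": int(f[2]),
                    "name": f[3] if len(f) > 3 else "",
                    "strand": f[5] if len(f) > 5 else ".",
                    "region": f[6] if len(f) > 6 else "",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand", "region"])


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------

def write_results(tables: dict[str, pd.DataFrame], out_dir, manifest_extra: dict | None = None) -> dict:
    """Write named result tables as TSVs plus a JSON manifest.

    Returns the manifest dict.  Tables round-trip: ``pd.read_csv(path,
    sep="\\t")`` reproduces the frame.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"tables": {}, **(manifest_extra or {})}
    for name, df in tables.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        manifest["tables"][name] = {"file": p.name, "n_rows": int(len(df))}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def write_run_dir(sim, out_dir) -> Path:
    """Write a simulated cohort to disk in the formats the pipeline reads.

    Layout: per-sample pileup TSVs, per-sample VCFs, ``snps.bed``,
    ``expression.tsv``, ``survival.tsv``, truth tables, a cohort manifest
    TSV for the CLI and a JSON manifest recording the config.
    """
    from dataclasses import asdict

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for indiv in sim.truth.individuals:
        entry = {"individual": indiv}
        for tissue in ("normal", "tumor"):
            for assay in ("rna", "dna"):
                fn = f"{indiv}_{tissue}_{assay}.counts.tsv"
                write_pileup_counts(sim.counts[(indiv, tissue, assay)], out / fn)
                entry[f"{assay}_{tissue}"] = fn
            fn = f"{indiv}_{tissue}.vcf"
            write_vcf_variants(sim.variants[(indiv, tissue)], out / fn)
            entry[f"vcf_{tissue}"] = fn
        manifest_rows.append(entry)
    pd.DataFrame(manifest_rows).to_csv(out / "cohort_manifest.tsv", sep="\t", index=False)

    snp_rows = sorted((c, p) for c, p in sim.snp_set._positions)
    with open(out / "snps.bed", "w") as fh:
        for c, p in snp_rows:
            fh.write(f"{c}\t{p - 1}\t{p}\n")
    sim.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    sim.survival.to_csv(out / "survival.tsv", sep="\t", index=False)
    sim.truth.sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    sim.truth.edited.reset_index().to_csv(out / "truth_edited.tsv", sep="\t", index=False)
    sim.truth.genotype.reset_index().to_csv(out / "truth_genotype.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        cfg = asdict(sim.config)
        cfg["carrier_prob_range"] = list(cfg["carrier_prob_range"])
        json.dump({"config": cfg, "clinical_sites": [list(s) for s in sim.truth.clinical_sites]},
                  fh, indent=2, sort_keys=True)
    return out
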