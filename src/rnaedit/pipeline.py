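"""Per-individual RNA-editing discovery.

The pipeline consumes per-site, per-strand allele counts from RNA and DNA of
a sample (normal or tumor), applies the candidate filters (A-reference with
G as the sole alternative allele, minimum depth, strand bias), removes loci
called as homozygous A>G DNA variants in the same sample, applies the
zero-confidence filter on the DNA read counts, and then runs either the
matched tumor-normal comparison (odds ratio + Fisher exact test on the 2x2
RNA allele-count table) or the single-sample RNA-vs-DNA comparison.

Count tables are pandas DataFrames in the canonical pileup dialect (see
:mod:`rnaedit.io`): columns ``chrom, pos, ref`` plus per-strand base counts
``A_plus, A_minus, C_plus, C_minus, G_plus, G_minus, T_plus, T_minus``, one
row per covered site, 1-based coordinates, counts restricted to bases at or
above the base-quality floor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SiteKey",
    "AlleleCounts",
    "SampleSiteRecord",
    "DnaVariant",
    "CandidateSite",
    "FilterConfig",
    "extract_ag_candidates",
    "attach_dna_counts",
    "accept_dna_variants",
    "subtract_dna_variants",
    "zero_confidence_filter",
    "matched_discovery",
    "single_sample_discovery",
    "run_matched_individual",
    "run_single_sample",
]

COUNT_COLUMNS = [
    "A_plus", "A_minus", "C_plus", "C_minus",
    "G_plus", "G_minus", "T_plus", "T_minus",
]

Direction = Literal["tumor_enriched", "normal_enriched", "insignificant"]


@dataclass(frozen=True, order=True)
class SiteKey:
    """Genomic address of a candidate locus (1-based, fully closed)."""

    chrom: str
    pos: int
    ref: str = "A"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in {"A", "C", "G", "T"}:
            raise ValueError(f"ref base must be one of A/C/G/T, got {self.ref!r}")


@dataclass(frozen=True)
class AlleleCounts:
    """Stranded read counts for the reference and alternative allele."""

    ref_plus: int = 0
    ref_minus: int = 0
    alt_plus: int = 0
    alt_minus: int = 0

    def __post_init__(self):
        for f in ("ref_plus", "ref_minus", "alt_plus", "alt_minus"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")

    @property
    def ref_total(self) -> int:
        return self.ref_plus + self.ref_minus

    @property
    def alt_total(self) -> int:
        return self.alt_plus + self.alt_minus

    @property
    def total(self) -> int:
        return self.ref_total + self.alt_total


@dataclass
class SampleSiteRecord:
    """Per-site state of one assay pair (RNA + DNA) in one sample."""

    site: SiteKey
    rna: AlleleCounts
    dna: AlleleCounts | None = None
    strand_bias_p: float = math.nan
    dna_zero_conf: float = math.nan
    flipped_strand: bool = False  # True when a T>C antisense locus was normalized


@dataclass(frozen=True)
class DnaVariant:
    """An accepted DNA variant call (used for subtraction)."""

    site: SiteKey
    alt_base: str
    genotype: Literal["hom", "het"]
    depth: int
    qual: float


@dataclass
class CandidateSite:
    """Matched-sample comparison result at one site for one individual."""

    site: SiteKey
    individual: str
    normal: SampleSiteRecord | None = None
    tumor: SampleSiteRecord | None = None
    or_raw: float = math.nan
    or_haldane: float = math.nan
    fisher_p: float = math.nan
    direction: Direction = "insignificant"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filter cascade.

    Defaults follow the published protocol: sites need more than 4 reads
    (``min_reads = 5``) at base quality >= 25, moderate strand bias
    (Fisher p >= 0.01), a DNA zero-confidence score of at least 10 at
    alpha = 0.05, and a matched comparison with OR outside (0.5, 2.0) and
    Fisher p <= 0.05; DNA variants require more than 4 reads and calling
    quality >= 50 to be subtracted.
    """

    min_base_quality: int = 25
    min_reads: int = 5
    strand_bias_alpha: float = 0.01
    zero_conf_threshold: float = 10.0
    zero_conf_alpha: float = 0.05
    or_high: float = 2.0
    or_low: float = 0.5
    fisher_alpha: float = 0.05
    dna_min_reads: int = 5
    dna_min_qual: float = 50.0
    include_tc_strand: bool = False
    max_third_allele_fraction: float = 0.0

    def __post_init__(self):
        if not (0 < self.or_low < 1 < self.or_high):
            raise ValueError("need or_low < 1 < or_high with or_low > 0")
        for f in ("min_reads", "dna_min_reads", "zero_conf_threshold"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        for f in ("strand_bias_alpha", "zero_conf_alpha", "fisher_alpha"):
            v = getattr(self, f)
            if not (0 < v < 1):
                raise ValueError(f"{f} must lie in (0, 1)")


# ---------------------------------------------------------------------------
# candidate extraction
# ---------------------------------------------------------------------------

def _row_counts(row: Mapping, ref: str, alt: str) -> AlleleCounts:
    return AlleleCounts(
        ref_plus=int(row[f"{ref}_plus"]),
        ref_minus=int(row[f"{ref}_minus"]),
        alt_plus=int(row[f"{alt}_plus"]),
        alt_minus=int(row[f"{alt}_minus"]),
    )


def extract_ag_candidates(
    pileup_rows: pd.DataFrame, config: FilterConfig = FilterConfig()
) -> list[SampleSiteRecord]:
    """Select A-reference loci whose only alternative allele is G.

    A row survives when the reference base is A, no base other than A or G
    carries reads (beyond ``max_third_allele_fraction`` of the total), the
    total count is at least ``min_reads``, and the strand-bias Fisher p is at
    least ``strand_bias_alpha``.  With ``include_tc_strand`` the antisense
    representation (T reference, sole alternative C) is also admitted,
    normalized into ref/alt counts with strands swapped and flagged.

    Malformed rows (negative counts, unknown reference base) are skipped with
    a logged warning carrying the row index.
    """
    required = {"chrom", "pos", "ref", *COUNT_COLUMNS}
    missing = required - set(pileup_rows.columns)
    if missing:
        raise ValueError(f"pileup table lacks columns: {sorted(missing)}")

    df = pileup_rows
    counts = df[COUNT_COLUMNS].to_numpy()
    bad = (counts < 0).any(axis=1)
    total = counts.sum(axis=1)
    ref = df["ref"].to_numpy(dtype=object)

    a_tot = df["A_plus"].to_numpy() + df["A_minus"].to_numpy()
    c_tot = df["C_plus"].to_numpy() + df["C_minus"].to_numpy()
    g_tot = df["G_plus"].to_numpy() + df["G_minus"].to_numpy()
    t_tot = df["T_plus"].to_numpy() + df["T_minus"].to_numpy()

    tol = config.max_third_allele_fraction
    with np.errstate(invalid="ignore", divide="ignore"):
        third_ag = np.where(total > 0, (c_tot + t_tot) / np.maximum(total, 1), 0.0)
        third_tc = np.where(total > 0, (a_tot + g_tot) / np.maximum(total, 1), 0.0)

    is_ag = (ref == "A") & (third_ag <= tol)
    is_tc = config.include_tc_strand & (ref == "T") & (third_tc <= tol)
    keep = (is_ag | is_tc) & (total >= config.min_reads) & ~bad

    known_ref = np.isin(ref.astype(str), ["A", "C", "G", "T"])
    for idx in np.nonzero(bad | ~known_ref)[0]:
        logger.warning("skipping malformed pileup row %d (chrom=%s pos=%s)",
                       idx, df["chrom"].iloc[idx], df["pos"].iloc[idx])

    out: list[SampleSiteRecord] = []
    sub = df.loc[keep]
    flipped = is_tc[keep]
    for (row, flip) in zip(sub.itertuples(index=False), flipped):
        rowd = row._asdict()
        if flip:
            # antisense T>C: reads on + strand of the genome are - strand of
            # the transcript; represent as A>G with strands swapped
            rna = AlleleCounts(
                ref_plus=int(rowd["T_minus"]), ref_minus=int(rowd["T_plus"]),
                alt_plus=int(rowd["C_minus"]), alt_minus=int(rowd["C_plus"]),
            )
        else:
            rna = _row_counts(rowd, "A", "G")
        sb = stats.strand_bias_p(rna.ref_plus, rna.ref_minus, rna.alt_plus, rna.alt_minus)
        if sb < config.strand_bias_alpha:
            continue
        site = SiteKey(str(rowd["chrom"]), int(rowd["pos"]), str(rowd["ref"]))
        out.append(SampleSiteRecord(site=site, rna=rna, strand_bias_p=sb, flipped_strand=bool(flip)))
    return out


def attach_dna_counts(
    records: Iterable[SampleSiteRecord], dna_rows: pd.DataFrame
) -> list[SampleSiteRecord]:
    """Attach DNA ref/alt counts to RNA candidate records by site.

    Sites absent from the DNA pileup get zero counts (they will fail the
    zero-confidence filter: absence of DNA reads is absence of confidence).
    """
    lookup: dict[tuple[str, int], AlleleCounts] = {}
    for row in dna_rows.itertuples(index=False):
        rowd = row._asdict()
        ref = str(rowd["ref"])
        if ref == "A":
            ac = _row_counts(rowd, "A", "G")
        elif ref == "T":
            ac = AlleleCounts(
                ref_plus=int(rowd["T_minus"]), ref_minus=int(rowd["T_plus"]),
                alt_plus=int(rowd["C_minus"]), alt_minus=int(rowd["C_plus"]),
            )
        else:
            continue
        lookup[(str(rowd["chrom"]), int(rowd["pos"]))] = ac
    out = []
    for rec in records:
        dna = lookup.get((rec.site.chrom, rec.site.pos), AlleleCounts())
        out.append(replace_record(rec, dna=dna))
    return out


def replace_record(rec: SampleSiteRecord, **kw) -> SampleSiteRecord:
    new = SampleSiteRecord(
        site=rec.site, rna=rec.rna, dna=rec.dna,
        strand_bias_p=rec.strand_bias_p, dna_zero_conf=rec.dna_zero_conf,
        flipped_strand=rec.flipped_strand,
    )
    for k, v in kw.items():
        setattr(new, k, v)
    return new


# ---------------------------------------------------------------------------
# DNA variant handling
# ---------------------------------------------------------------------------

def accept_dna_variants(
    vcf_records: pd.DataFrame, config: FilterConfig = FilterConfig()
) -> list[DnaVariant]:
    """Keep homozygous A>G DNA variants with sufficient depth and quality.

    ``vcf_records`` columns: ``chrom, pos, ref, alt, genotype, depth, qual``
    (``genotype`` in {hom, het}; see :func:`rnaedit.io.read_vcf_variants`).
    Records missing genotype or depth are skipped with a warning.
    """
    out: list[DnaVariant] = []
    for idx, row in enumerate(vcf_records.itertuples(index=False)):
        r = row._asdict()
        gt, dp = r.get("genotype"), r.get("depth")
        if gt is None or (isinstance(gt, float) and math.isnan(gt)) or dp is None or (
            isinstance(dp, float) and math.isnan(dp)
        ):
            logger.warning("variant record %d lacks genotype/depth; skipped", idx)
            continue
        if str(r["ref"]) != "A" or str(r["alt"]) != "G":
            continue
        if str(gt) != "hom":
            continue
        depth = int(dp)
        qual = float(r["qual"])
        if depth < config.dna_min_reads or qual < config.dna_min_qual:
            continue
        out.append(
            DnaVariant(
                site=SiteKey(str(r["chrom"]), int(r["pos"]), "A"),
                alt_base="G", genotype="hom", depth=depth, qual=qual,
            )
        )
    return out


def subtract_dna_variants(
    records: Sequence[SampleSiteRecord], variants: Iterable[DnaVariant]
) -> list[SampleSiteRecord]:
    """Drop candidate records whose position coincides with a DNA variant.

    Matching is positional (chromosome + position); the output is always a
    subset of the input and the operation is idempotent.
    """
    positions = {(v.site.chrom, v.site.pos) for v in variants}
    return [r for r in records if (r.site.chrom, r.site.pos) not in positions]


# ---------------------------------------------------------------------------
# zero-confidence filter
# ---------------------------------------------------------------------------

def zero_confidence_filter(
    records: Sequence[SampleSiteRecord], config: FilterConfig = FilterConfig()
) -> list[SampleSiteRecord]:
    """Retain records whose DNA reads confidently lack the G allele.

    Scores ``x`` = DNA alternative (G) reads against ``n`` = total DNA reads;
    a record passes when the score reaches ``zero_conf_threshold``.  Records
    with no DNA coverage fail by definition (score treated as 0).
    """
    out = []
    n_uncovered = 0
    for rec in records:
        dna = rec.dna
        if dna is None or dna.total == 0:
            rec.dna_zero_conf = 0.0
            n_uncovered += 1
            continue
        score = stats.zero_confidence_score(dna.alt_total, dna.total, config.zero_conf_alpha)
        rec.dna_zero_conf = score
        if score >= config.zero_conf_threshold:
            out.append(rec)
    if n_uncovered:
        logger.info("zero-confidence filter: %d records had no DNA coverage", n_uncovered)
    return out


# ---------------------------------------------------------------------------
# discovery
# ---------------------------------------------------------------------------

def _classify(or_raw: float, p: float, config: FilterConfig) -> Direction:
    if math.isnan(or_raw) or p > config.fisher_alpha:
        return "insignificant"
    if or_raw >= config.or_high:
        return "tumor_enriched"
    if or_raw <= config.or_low:
        return "normal_enriched"
    return "insignificant"


def matched_discovery(
    normal: SampleSiteRecord,
    tumor: SampleSiteRecord,
    config: FilterConfig = FilterConfig(),
    individual: str = "",
) -> CandidateSite:
    """Compare RNA allele counts between matched normal and tumor samples.

    The 2x2 table has rows {normal, tumor} and columns {ref, alt}; the odds
    ratio is oriented so values above 1 mean a higher alternative-allele
    fraction in the tumor.  Sites with 0.5 < OR < 2.0 or Fisher p > 0.05 are
    classed insignificant (and pruned downstream).
    """
    if (normal.site.chrom, normal.site.pos) != (tumor.site.chrom, tumor.site.pos):
        raise ValueError(f"site mismatch: {normal.site} vs {tumor.site}")
    table = [
        [normal.rna.ref_total, normal.rna.alt_total],
        [tumor.rna.ref_total, tumor.rna.alt_total],
    ]
    if normal.rna.alt_total == 0 and tumor.rna.alt_total == 0:
        # no alternative reads anywhere: nothing to compare
        or_raw, p = math.nan, 1.0
    else:
        or_raw = stats.odds_ratio(table, "raw")
        p = stats.fisher_exact_2x2(table)
    or_hal = stats.odds_ratio(table, "haldane")
    return CandidateSite(
        site=normal.site, individual=individual, normal=normal, tumor=tumor,
        or_raw=or_raw, or_haldane=or_hal, fisher_p=p,
        direction=_classify(or_raw, p, config),
    )


@dataclass
class SingleSampleResult:
    site: SiteKey
    accepted: bool
    dna_zero_conf: float
    or_raw: float
    or_haldane: float
    fisher_p: float


def single_sample_discovery(
    record: SampleSiteRecord, config: FilterConfig = FilterConfig()
) -> SingleSampleResult:
    """RNA-vs-DNA comparison for a single sample (no matched tissue).

    The 2x2 table has rows {DNA, RNA} and columns {ref, alt}, oriented so an
    odds ratio above 1 means a higher alternative fraction in RNA.  The site
    is accepted when the DNA zero-confidence score reaches the threshold
    (default 10.0) and the OR reaches ``or_high`` (default 2.0).
    """
    if record.dna is None:
        raise ValueError("record lacks DNA counts")
    dna, rna = record.dna, record.rna
    if dna.total == 0:
        score = 0.0
    else:
        score = stats.zero_confidence_score(dna.alt_total, dna.total, config.zero_conf_alpha)
    record.dna_zero_conf = score
    table = [[dna.ref_total, dna.alt_total], [rna.ref_total, rna.alt_total]]
    if dna.alt_total == 0 and rna.alt_total == 0:
        or_raw, p = math.nan, 1.0
    else:
        or_raw = stats.odds_ratio(table, "raw")
        p = stats.fisher_exact_2x2(table)
    or_hal = stats.odds_ratio(table, "haldane")
    accepted = (score >= config.zero_conf_threshold) and (
        not math.isnan(or_raw) and or_raw >= config.or_high
    )
    return SingleSampleResult(record.site, accepted, score, or_raw, or_hal, p)


# ---------------------------------------------------------------------------
# per-individual cascade
# ---------------------------------------------------------------------------

def _sample_cascade(
    rna_rows: pd.DataFrame,
    dna_rows: pd.DataFrame,
    variants: pd.DataFrame | None,
    config: FilterConfig,
    counts: dict,
    label: str,
) -> dict[tuple[str, int], SampleSiteRecord]:
    recs = extract_ag_candidates(rna_rows, config)
    counts[f"{label}.rna_candidates"] = len(recs)
    recs = attach_dna_counts(recs, dna_rows)
    if variants is not None and len(variants):
        accepted = accept_dna_variants(variants, config)
        recs = subtract_dna_variants(recs, accepted)
    counts[f"{label}.after_dna_subtraction"] = len(recs)
    recs = zero_confidence_filter(recs, config)
    counts[f"{label}.after_zero_confidence"] = len(recs)
    return {(r.site.chrom, r.site.pos): r for r in recs}


def run_matched_individual(
    individual: str,
    rna_normal: pd.DataFrame,
    dna_normal: pd.DataFrame,
    rna_tumor: pd.DataFrame,
    dna_tumor: pd.DataFrame,
    variants_normal: pd.DataFrame | None = None,
    variants_tumor: pd.DataFrame | None = None,
    config: FilterConfig = FilterConfig(),
) -> tuple[list[CandidateSite], dict]:
    """Full matched-sample cascade for one individual.

    Each sample is processed independently (candidate extraction, DNA-variant
    subtraction, zero-confidence filter); a site enters the matched
    comparison only when it survives in *both* samples, and only significant
    (non-insignificant) candidates are returned.  The per-stage survivor
    counts are returned alongside for the filter-accounting log.
    """
    counts: dict = {"individual": individual}
    normal = _sample_cascade(rna_normal, dna_normal, variants_normal, config, counts, "normal")
    tumor = _sample_cascade(rna_tumor, dna_tumor, variants_tumor, config, counts, "tumor")
    common = sorted(set(normal) & set(tumor))
    counts["matched.common_sites"] = len(common)
    out = []
    for key in common:
        cand = matched_discovery(normal[key], tumor[key], config, individual)
        if cand.direction != "insignificant":
            out.append(cand)
    counts["matched.significant"] = len(out)
    logger.info("individual %s: %s", individual, counts)
    return out, counts


def run_single_sample(
    rna_rows: pd.DataFrame,
    dna_rows: pd.DataFrame,
    variants: pd.DataFrame | None = None,
    config: FilterConfig = FilterConfig(),
) -> tuple[list[SingleSampleResult], dict]:
    """Single-sample cascade: candidate filters then RNA-vs-DNA discovery."""
    counts: dict = {}
    recs = _sample_cascade(rna_rows, dna_rows, variants, config, counts, "sample")
    results = [single_sample_discovery(r, config) for r in recs.values()]
    accepted = [r for r in results if r.accepted]
    counts["sample.accepted"] = len(accepted)
    return accepted, counts
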