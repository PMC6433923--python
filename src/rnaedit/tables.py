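"""Flat-table serialization of pipeline objects.

The TSV dialects written here are the tool's interchange formats: candidate
tables carry one row per (individual, site) call with the full filter
statistics; cohort tables one row per aggregated site.  Writing then reading
a table reproduces it.
"""

from __future__ import annotations

import math

import pandas as pd

from .cohort import CohortSite
from .pipeline import AlleleCounts, CandidateSite, SampleSiteRecord, SiteKey

__all__ = ["candidates_to_frame", "frame_to_candidates", "cohort_to_frame"]

CANDIDATE_COLUMNS = [
    "chrom", "pos", "ref", "individual",
    "normal_ref", "normal_alt", "tumor_ref", "tumor_alt",
    "or_raw", "or_haldane", "fisher_p",
    "strand_bias_p_normal", "strand_bias_p_tumor",
    "zero_conf_normal", "zero_conf_tumor", "direction",
]


def candidates_to_frame(candidates) -> pd.DataFrame:
    rows = []
    for c in candidates:
        nr, tr = c.normal, c.tumor
        rows.append(
            {
                "chrom": c.site.chrom,
                "pos": c.site.pos,
                "ref": c.site.ref,
                "individual": c.individual,
                "normal_ref": nr.rna.ref_total if nr else -1,
                "normal_alt": nr.rna.alt_total if nr else -1,
                "tumor_ref": tr.rna.ref_total if tr else -1,
                "tumor_alt": tr.rna.alt_total if tr else -1,
                "or_raw": c.or_raw,
                "or_haldane": c.or_haldane,
                "fisher_p": c.fisher_p,
                "strand_bias_p_normal": nr.strand_bias_p if nr else math.nan,
                "strand_bias_p_tumor": tr.strand_bias_p if tr else math.nan,
                "zero_conf_normal": nr.dna_zero_conf if nr else math.nan,
                "zero_conf_tumor": tr.dna_zero_conf if tr else math.nan,
                "direction": c.direction,
            }
        )
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def frame_to_candidates(df: pd.DataFrame) -> list[CandidateSite]:
    out = []
    for row in df.itertuples(index=False):
        r = row._asdict()
        site = SiteKey(str(r["chrom"]), int(r["pos"]), str(r["ref"]))

        def _rec(prefix: str) -> SampleSiteRecord | None:
            if int(r[f"{prefix}_ref"]) < 0:
                return None
            return SampleSiteRecord(
                site=site,
                rna=AlleleCounts(ref_plus=int(r[f"{prefix}_ref"]), alt_plus=int(r[f"{prefix}_alt"])),
                strand_bias_p=float(r[f"strand_bias_p_{prefix}"]),
                dna_zero_conf=float(r[f"zero_conf_{prefix}"]),
            )

        out.append(
            CandidateSite(
                site=site,
                individual=str(r["individual"]),
                normal=_rec("normal"),
                tumor=_rec("tumor"),
                or_raw=float(r["or_raw"]),
                or_haldane=float(r["or_haldane"]),
                fisher_p=float(r["fisher_p"]),
                direction=str(r["direction"]),
            )
        )
    return out


def cohort_to_frame(sites: list[CohortSite]) -> pd.DataFrame:
    rows = [
        {
            "chrom": s.site.chrom,
            "pos": s.site.pos,
            "ref": s.site.ref,
            "sample_count": s.sample_count,
            "n_tumor_enriched": s.n_tumor_enriched,
            "n_normal_enriched": s.n_normal_enriched,
            "in_dbsnp": s.in_dbsnp,
            "gene": s.gene,
            "region": s.region,
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "sample_count", "n_tumor_enriched",
                 "n_normal_enriched", "in_dbsnp", "gene", "region"],
    )
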