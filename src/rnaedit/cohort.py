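"""Cohort-level aggregation of per-individual editing calls.

Sites discovered independently in several individuals are far more likely to
be genuine editing events than individual-specific calls, so the cohort step
counts, for every site, the number of distinct individuals in which it was
called with a significant direction, and keeps the recurrent subset
(default: more than 4 individuals).  Known-SNP (dbSNP-like) positions serve
as negative controls: a discovery set of true editing events should rarely
coincide with known germline SNPs, so the fraction of calls inside the SNP
set - overall and stratified by recurrence - estimates the false-positive
rate.  SNP membership annotates sites; it never removes them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pipeline import CandidateSite, SiteKey

logger = logging.getLogger(__name__)

__all__ = ["CohortSite", "SnpSet", "aggregate_recurrence", "dbsnp_overlap_rate", "annotate_sites"]


@dataclass
class CohortSite:
    """Cross-individual aggregate for one site."""

    site: SiteKey
    sample_count: int
    n_tumor_enriched: int
    n_normal_enriched: int
    directions: dict = field(default_factory=dict)  # individual -> direction
    in_dbsnp: bool | None = None
    gene: str = ""
    region: str = ""


class SnpSet:
    """Duplicate-free membership structure over genomic positions.

    Matching is positional (chromosome + position) by default, since missed
    DNA variants coincide with SNP positions regardless of the catalogued
    allele; allele-aware membership is available when alleles were loaded.
    """

    def __init__(self, positions: Iterable[tuple[str, int]], alleles: Mapping | None = None):
        self._positions = frozenset((str(c), int(p)) for c, p in positions)
        self._alleles = dict(alleles) if alleles else {}

    def __len__(self) -> int:
        return len(self._positions)

    def __contains__(self, site) -> bool:
        if isinstance(site, SiteKey):
            return (site.chrom, site.pos) in self._positions
        c, p = site
        return (str(c), int(p)) in self._positions

    def contains_allele(self, site: SiteKey, ref: str, alt: str) -> bool:
        key = (site.chrom, site.pos)
        if key not in self._alleles:
            return False
        return (ref, alt) in self._alleles[key]

    def __or__(self, other: "SnpSet") -> "SnpSet":
        return SnpSet(self._positions | other._positions, {**self._alleles, **other._alleles})


def aggregate_recurrence(
    candidates: Mapping[str, Sequence[CandidateSite]],
    min_individuals: int = 4,
) -> tuple[list[CohortSite], list[CohortSite]]:
    """Group significant candidates by site and count distinct individuals.

    ``candidates`` maps individual identifiers to their significant
    candidate lists.  Duplicate (individual, site) entries are deduplicated
    with a warning.  Returns ``(all_sites, recurrent)`` where the recurrent
    subset keeps sites called in more than ``min_individuals`` individuals
    (default 4, i.e. at least 5).  A site counts once per individual; the
    tumor-enriched and normal-enriched tallies are kept separately.
    """
    per_site: dict[tuple[str, int, str], dict[str, str]] = {}
    for indiv, cands in candidates.items():
        seen: set[tuple[str, int, str]] = set()
        for cand in cands:
            if cand.direction == "insignificant":
                continue
            key = (cand.site.chrom, cand.site.pos, cand.site.ref)
            if key in seen:
                logger.warning("duplicate candidate for individual %s at %s:%d; deduplicated",
                               indiv, key[0], key[1])
                continue
            seen.add(key)
            per_site.setdefault(key, {})[indiv] = cand.direction
    all_sites = []
    for key in sorted(per_site):
        dirs = per_site[key]
        all_sites.append(
            CohortSite(
                site=SiteKey(key[0], key[1], key[2]),
                sample_count=len(dirs),
                n_tumor_enriched=sum(1 for d in dirs.values() if d == "tumor_enriched"),
                n_normal_enriched=sum(1 for d in dirs.values() if d == "normal_enriched"),
                directions=dirs,
            )
        )
    recurrent = [s for s in all_sites if s.sample_count > min_individuals]
    return all_sites, recurrent


def dbsnp_overlap_rate(
    sites: Sequence[CohortSite] | Sequence[SiteKey],
    snps: SnpSet,
    stratify_by_recurrence: bool = False,
):
    """Fraction of sites whose position lies in the known-SNP set.

    Returns a float for the plain rate, or a DataFrame with columns
    ``stratum, n_sites_exact, pct_in_dbsnp_exact, n_sites_at_least,
    pct_in_dbsnp_at_least`` when stratified by recurrence (both the
    "exactly k individuals" and "at least k individuals" readings are
    reported).  An empty site list yields ``nan`` (undefined), not 0.
    """
    site_keys = [s.site if isinstance(s, CohortSite) else s for s in sites]
    if not site_keys:
        return math.nan if not stratify_by_recurrence else pd.DataFrame(
            columns=["stratum", "n_sites_exact", "pct_in_dbsnp_exact",
                     "n_sites_at_least", "pct_in_dbsnp_at_least"]
        )
    member = [sk in snps for sk in site_keys]
    for s, m in zip(sites, member):
        if isinstance(s, CohortSite):
            s.in_dbsnp = m
    if not stratify_by_recurrence:
        return sum(member) / len(member)
    if not all(isinstance(s, CohortSite) for s in sites):  # pragma: no cover
        raise TypeError("stratification requires CohortSite inputs")
    counts = [s.sample_count for s in sites]
    kmax = max(counts)
    rows = []
    for k in range(1, kmax + 1):
        exact = [m for c, m in zip(counts, member) if c == k]
        atleast = [m for c, m in zip(counts, member) if c >= k]
        rows.append(
            {
                "stratum": k,
                "n_sites_exact": len(exact),
                "pct_in_dbsnp_exact": (100.0 * sum(exact) / len(exact)) if exact else math.nan,
                "n_sites_at_least": len(atleast),
                "pct_in_dbsnp_at_least": (100.0 * sum(atleast) / len(atleast)) if atleast else math.nan,
            }
        )
    return pd.DataFrame(rows)


def annotate_sites(
    sites: Sequence[CohortSite], features: pd.DataFrame
) -> list[CohortSite]:
    """Attach gene name and region class by interval overlap.

    ``features`` is a BED-derived table with columns ``chrom, start, end,
    name, region`` (``start`` half-open 0-based as in BED, converted to the
    1-based site coordinate; ``strand`` optional).  Overlapping genes are
    joined with ``;`` sorted by name.  An unsorted table is sorted
    internally.
    """
    req = {"chrom", "start", "end", "name"}
    if not req <= set(features.columns):
        raise ValueError(f"feature table needs columns {sorted(req)}")
    feats = features.sort_values(["chrom", "start", "end"], kind="mergesort")
    if not features[["chrom", "start"]].equals(feats[["chrom", "start"]].set_axis(features.index)):
        logger.info("feature table was unsorted; sorted internally")
    by_chrom: dict[str, list] = {}
    has_region = "region" in feats.columns
    for row in feats.itertuples(index=False):
        r = row._asdict()
        by_chrom.setdefault(str(r["chrom"]), []).append(
            (int(r["start"]), int(r["end"]), str(r["name"]),
             str(r["region"]) if has_region else "")
        )
    for s in sites:
        hits = [
            (name, region)
            for (start, end, name, region) in by_chrom.get(s.site.chrom, [])
            # BED half-open [start, end) vs 1-based site: site p overlaps iff start < p <= end
            if start < s.site.pos <= end
        ]
        hits.sort()
        s.gene = ";".join(h[0] for h in hits)
        s.region = ";".join(h[1] for h in hits)
    return list(sites)
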