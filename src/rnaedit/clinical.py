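"""Clinical relevance of discovered editing sites.

For each recurrent site the cohort splits into an *edited* group (the
individuals in which the site was called with a significant direction) and a
*non-edited* group (everyone else).  Two downstream analyses follow:

* **ADAR differential expression** - A-to-I editing is catalysed by the ADAR
  enzyme family (ADAR, ADARB1, ADARB2), so genuine editing should be
  accompanied by an ADAR expression difference between the tumor and normal
  tissue of the edited individuals.  Welch's unequal-variance t test is run
  per ADAR gene within the edited group; a site is DE-flagged when any
  tested gene reaches significance.
* **Survival association** - for a site (or a combined multi-site marker,
  where an individual is edited when edited at any member site), a two-group
  Kaplan-Meier / log-rank comparison of edited vs non-edited individuals,
  with Bonferroni correction over the number of sites tested.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import stats
from .cohort import CohortSite
from .pipeline import SiteKey

logger = logging.getLogger(__name__)

__all__ = [
    "ADAR_GENES",
    "EditedGroupAssignment",
    "CombinedMarker",
    "assign_edited_groups",
    "combine_markers",
    "adar_de_flag",
    "survival_association",
]

ADAR_GENES = ("ADAR", "ADARB1", "ADARB2")


@dataclass
class EditedGroupAssignment:
    site: SiteKey
    edited: frozenset
    non_edited: frozenset

    @property
    def testable(self) -> bool:
        return len(self.edited) > 0 and len(self.non_edited) > 0


@dataclass
class CombinedMarker:
    """Union marker: edited at any member site counts as edited."""

    member_sites: tuple
    edited: frozenset
    non_edited: frozenset


def assign_edited_groups(
    cohort_sites: Sequence[CohortSite],
    cohort_individuals: Sequence[str],
    tumor_enriched_only: bool = False,
) -> list[EditedGroupAssignment]:
    """Split the cohort into edited / non-edited groups per site.

    ``cohort_sites`` carry the per-individual direction labels collected
    during aggregation.  By default any significant direction counts as
    edited; with ``tumor_enriched_only`` the edited group is restricted to
    individuals where the site was tumor-enriched.
    """
    everyone = frozenset(cohort_individuals)
    out = []
    for cs in cohort_sites:
        edited = {
            ind
            for ind, d in cs.directions.items()
            if d == "tumor_enriched" or (not tumor_enriched_only and d == "normal_enriched")
        }
        if not edited <= everyone:
            raise ValueError(f"site {cs.site} edited in individuals outside the cohort")
        out.append(
            EditedGroupAssignment(cs.site, frozenset(edited), everyone - edited)
        )
    return out


def combine_markers(
    assignments: Sequence[EditedGroupAssignment], cohort_individuals: Sequence[str]
) -> CombinedMarker:
    """Combine sites into a single marker by union of edited sets."""
    if not assignments:
        raise ValueError("no assignments to combine")
    edited = frozenset().union(*(a.edited for a in assignments))
    everyone = frozenset(cohort_individuals)
    return CombinedMarker(
        member_sites=tuple(a.site for a in assignments),
        edited=edited,
        non_edited=everyone - edited,
    )


def adar_de_flag(
    assignment: EditedGroupAssignment,
    expression: pd.DataFrame,
    genes: Sequence[str] = ADAR_GENES,
    alpha: float = 0.05,
) -> tuple[bool, dict[str, float]]:
    """Test ADAR-family differential expression within the edited group.

    ``expression`` is long-form with columns ``individual, tissue, gene,
    value`` (``tissue`` in {normal, tumor}).  For each gene, Welch's test
    compares tumor vs normal expression restricted to edited individuals;
    the site is flagged when any gene's p falls below ``alpha``.  With fewer
    than two edited individuals carrying both tissues the test is undefined
    and the site is not flagged.

    Returns ``(flagged, per_gene_p)``.
    """
    per_gene: dict[str, float] = {}
    edited = assignment.edited
    if len(edited) < 2:
        logger.info("site %s: <2 edited individuals, ADAR DE untestable", assignment.site)
        return False, {g: math.nan for g in genes}
    sub = expression[expression["individual"].isin(edited)]
    for gene in genes:
        g = sub[sub["gene"] == gene]
        tum = g.loc[g["tissue"] == "tumor", "value"].to_numpy()
        nor = g.loc[g["tissue"] == "normal", "value"].to_numpy()
        res = stats.welch_test(tum, nor)
        per_gene[gene] = res.p_value
    flagged = any((not math.isnan(p)) and p < alpha for p in per_gene.values())
    return flagged, per_gene


@dataclass
class SurvivalAssociation:
    nominal_p: float
    corrected_p: float
    statistic: float
    curves: dict = field(repr=False, default_factory=dict)
    n_edited: int = 0
    n_non_edited: int = 0

    @property
    def defined(self) -> bool:
        return not math.isnan(self.nominal_p)


def survival_association(
    marker: CombinedMarker | EditedGroupAssignment,
    survival: pd.DataFrame,
    n_tests: int = 1,
) -> SurvivalAssociation:
    """Log-rank comparison of edited vs non-edited survival.

    ``survival`` has columns ``individual, time_days, event``.  ``n_tests``
    is the number of sites over which multiplicity is corrected
    (Bonferroni, ``min(1, p * n_tests)``); it is an explicit input, never
    inferred.  One empty group makes the test undefined (``nan``).
    """
    edited, non_edited = marker.edited, marker.non_edited
    missing = (edited | non_edited) - set(survival["individual"])
    if missing:
        raise ValueError(f"individuals lack survival data: {sorted(missing)[:5]}")
    if not edited or not non_edited:
        return SurvivalAssociation(math.nan, math.nan, math.nan,
                                   n_edited=len(edited), n_non_edited=len(non_edited))
    sub = survival[survival["individual"].isin(edited | non_edited)]
    group = sub["individual"].isin(edited).map({True: "edited", False: "non_edited"})
    res = stats.km_logrank(sub["time_days"], sub["event"].astype(bool), group)
    corrected = stats.bonferroni(res.p_value, n_tests) if res.defined else math.nan
    return SurvivalAssociation(
        nominal_p=res.p_value, corrected_p=corrected, statistic=res.statistic,
        curves=res.curves, n_edited=len(edited), n_non_edited=len(non_edited),
    )
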