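"""Edited-group assignment, ADAR differential expression, survival tests."""

import math

import numpy as np
import pandas as pd
import pytest

from rnaedit import clinical as clin
from rnaedit import cohort as coh
from rnaedit import pipeline as pl


def _cohort_site(pos, directions):
    return coh.CohortSite(
        site=pl.SiteKey("chr1", pos),
        sample_count=len(directions),
        n_tumor_enriched=sum(1 for d in directions.values() if d == "tumor_enriched"),
        n_normal_enriched=sum(1 for d in directions.values() if d == "normal_enriched"),
        directions=directions,
    )


COHORT = [f"I{i}" for i in range(10)]


class TestAssignEditedGroups:
    def test_split_is_partition(self):
        cs = _cohort_site(100, {"I1": "tumor_enriched", "I2": "tumor_enriched", "I3": "normal_enriched"})
        (a,) = clin.assign_edited_groups([cs], COHORT)
        assert a.edited == {"I1", "I2", "I3"}
        assert a.non_edited == set(COHORT) - a.edited
        assert a.testable

    def test_tumor_enriched_only_restriction(self):
        cs = _cohort_site(100, {"I1": "tumor_enriched", "I3": "normal_enriched"})
        (a,) = clin.assign_edited_groups([cs], COHORT, tumor_enriched_only=True)
        assert a.edited == {"I1"}

    def test_empty_edited_group_untestable(self):
        (a,) = clin.assign_edited_groups([_cohort_site(100, {})], COHORT)
        assert a.edited == frozenset() and not a.testable

    def test_combined_marker_is_union(self):
        s1 = _cohort_site(100, {"I1": "tumor_enriched", "I2": "tumor_enriched"})
        s2 = _cohort_site(200, {"I2": "tumor_enriched", "I5": "tumor_enriched"})
        assignments = clin.assign_edited_groups([s1, s2], COHORT)
        marker = clin.combine_markers(assignments, COHORT)
        assert marker.edited == {"I1", "I2", "I5"}
        assert marker.non_edited == set(COHORT) - {"I1", "I2", "I5"}


def _expr(values):
    rows = []
    for (ind, tissue, gene), v in values.items():
        rows.append({"individual": ind, "tissue": tissue, "gene": gene, "value": v})
    return pd.DataFrame(rows)


class TestAdarDeFlag:
    def _assignment(self, edited):
        return clin.EditedGroupAssignment(
            pl.SiteKey("chr1", 100), frozenset(edited), frozenset(COHORT) - set(edited))

    def test_strong_separation_flagged(self):
        edited = COHORT[:6]
        vals = {}
        for i, ind in enumerate(edited):
            for gene in clin.ADAR_GENES:
                vals[(ind, "normal", gene)] = 10.0 + 0.1 * i
                vals[(ind, "tumor", gene)] = 20.0 + 0.1 * i
        flagged, per_gene = clin.adar_de_flag(self._assignment(edited), _expr(vals))
        assert flagged
        assert all(p < 0.05 for p in per_gene.values())

    def test_identical_expression_not_flagged(self):
        edited = COHORT[:4]
        vals = {}
        for ind in edited:
            for gene in clin.ADAR_GENES:
                vals[(ind, "normal", gene)] = 10.0
                vals[(ind, "tumor", gene)] = 10.0
        flagged, per_gene = clin.adar_de_flag(self._assignment(edited), _expr(vals))
        assert not flagged
        assert per_gene["ADAR"] == pytest.approx(1.0)

    def test_insufficient_edited_individuals_untestable(self):
        vals = {("I0", t, g): 1.0 for t in ("normal", "tumor") for g in clin.ADAR_GENES}
        flagged, per_gene = clin.adar_de_flag(self._assignment(["I0"]), _expr(vals))
        assert not flagged
        assert all(math.isnan(p) for p in per_gene.values())

    def test_null_flag_rate_matches_any_gene_multiplicity(self):
        # with g independent null genes, P(flag) ~ 1 - 0.95**g
        rng = np.random.default_rng(5)
        edited = COHORT[:8]
        n_flag = 0
        reps = 400
        for _ in range(reps):
            vals = {}
            for ind in edited:
                for gene in clin.ADAR_GENES:
                    vals[(ind, "normal", gene)] = rng.normal(10, 1)
                    vals[(ind, "tumor", gene)] = rng.normal(10, 1)
            flagged, _ = clin.adar_de_flag(self._assignment(edited), _expr(vals))
            n_flag += flagged
        expected = 1 - 0.95 ** len(clin.ADAR_GENES)
        assert n_flag / reps == pytest.approx(expected, abs=0.06)


class TestSurvivalAssociation:
    @staticmethod
    def _surv(times, events):
        return pd.DataFrame({
            "individual": COHORT, "time_days": times, "event": events})

    def _assignment(self, edited):
        return clin.EditedGroupAssignment(
            pl.SiteKey("chr1", 100), frozenset(edited), frozenset(COHORT) - set(edited))

    def test_identical_survival_p_one(self):
        surv = self._surv([100] * 10, [True] * 10)
        res = clin.survival_association(self._assignment(COHORT[:5]), surv, n_tests=7)
        assert res.nominal_p == pytest.approx(1.0)
        assert res.corrected_p == pytest.approx(1.0)

    def test_reference_bonferroni_arithmetic(self):
        from rnaedit.stats import bonferroni
        assert bonferroni(2.2e-7, 207) == pytest.approx(4.6e-5, abs=0.05e-5)

    def test_empty_group_undefined(self):
        surv = self._surv(list(range(100, 1100, 100)), [True] * 10)
        res = clin.survival_association(self._assignment([]), surv, 1)
        assert not res.defined

    def test_missing_survival_rejected(self):
        surv = self._surv(list(range(100, 1100, 100)), [True] * 10).iloc[:-1]
        with pytest.raises(ValueError):
            clin.survival_association(self._assignment(COHORT[:5]), surv, 1)

    def test_separated_groups_significant_with_curves(self):
        times = [100] * 5 + [2000] * 5
        surv = self._surv(times, [True] * 10)
        res = clin.survival_association(self._assignment(COHORT[:5]), surv, n_tests=3)
        assert res.nominal_p < 0.01
        assert res.corrected_p == pytest.approx(min(1.0, res.nominal_p * 3))
        assert set(res.curves) == {"edited", "non_edited"}
        # edited group dies early: survival drops to 0 at t=100
        edited_curve = res.curves["edited"]
        assert edited_curve["survival"].iloc[-1] == pytest.approx(0.0)

    def test_power_against_planted_hazard(self):
        # editing-linked hazard ratio 3, cohort of 60: nominal p < 0.05 in
        # most replicates
        rng = np.random.default_rng(17)
        hits = 0
        reps = 100
        for _ in range(reps):
            edited = [f"P{i}" for i in range(20)]
            others = [f"P{i}" for i in range(20, 60)]
            t_e = rng.exponential(1000 / 3, 20)
            t_o = rng.exponential(1000, 40)
            surv = pd.DataFrame({
                "individual": edited + others,
                "time_days": np.concatenate([t_e, t_o]),
                "event": True,
            })
            a = clin.EditedGroupAssignment(pl.SiteKey("chr1", 1),
                                           frozenset(edited), frozenset(others))
            res = clin.survival_association(a, surv, 1)
            hits += res.nominal_p < 0.05
        assert hits / reps >= 0.8
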