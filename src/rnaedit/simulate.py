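"""Synthetic matched-cohort generator with known ground truth.

Emulates the data structure the discovery pipeline consumes - per-site,
per-strand RNA and DNA allele counts for normal and tumor samples of every
individual, DNA variant calls, a known-SNP position set, ADAR expression
values and survival times - with planted site classes:

``true_editing_tumor_enriched`` / ``true_editing_normal_enriched``
    alternative G reads appear in RNA only, at the configured editing level
    in the enriched tissue, in a per-site random subset of carrier
    individuals (so recurrence varies across sites);
``germline_snp_het`` / ``germline_snp_hom``
    G reads at ~50% / ~100% in both DNA and RNA of both tissues for carrier
    individuals - the false-positive mode the zero-confidence filter and the
    DNA-variant subtraction target.  Planted SNP positions (plus decoys)
    populate the known-SNP set; the simulated DNA caller misses a
    configurable fraction of them;
``strand_artifact``
    alternative RNA reads confined to one strand (alignment-artifact
    signature caught by the strand-bias filter);
``clean_background``
    reference-only sites where alternative reads arise from sequencing
    error alone.

All randomness flows from a single integer seed; identical configs and
seeds give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .cohort import SnpSet

__all__ = ["SimConfig", "SimResult", "Truth", "simulate_cohort", "score_calls"]

TISSUES = ("normal", "tumor")
ASSAYS = ("rna", "dna")

SITE_CLASSES = (
    "true_editing_tumor_enriched",
    "true_editing_normal_enriched",
    "germline_snp_het",
    "germline_snp_hom",
    "strand_artifact",
    "clean_background",
)


@dataclass(frozen=True)
class SimConfig:
    """Data-generating parameters of the synthetic cohort.

    Defaults describe a modest matched cohort: 20 individuals, 5,000
    assayed sites of which 2% (100) are true tumor-enriched editing sites
    edited at a 0.4 alternative-allele fraction in tumor RNA, 5% are
    germline A/G SNPs, ~60x mean coverage in both assays with
    negative-binomial over-dispersion, and a per-base sequencing error rate
    of 0.001.
    """

    n_individuals: int = 20
    n_sites: int = 5000
    editing_site_fraction: float = 0.02
    normal_enriched_fraction: float = 0.0  # fraction of editing sites enriched in normal
    snp_site_fraction: float = 0.05
    het_snp_fraction: float = 0.667  # of SNP sites, the rest are hom-capable
    strand_artifact_fraction: float = 0.01
    tumor_edit_level: float = 0.4
    normal_edit_level: float = 0.0
    artifact_level: float = 0.3
    carrier_prob_range: tuple[float, float] = (0.1, 0.9)
    snp_carrier_prob: float = 0.5
    rna_mean_depth: float = 60.0
    dna_mean_depth: float = 60.0
    depth_dispersion: float = 10.0  # negative-binomial size parameter
    seq_error_rate: float = 0.001
    strand_imbalance: float = 1.0  # P(alt read on + strand) at artifact sites
    dna_caller_sensitivity: float = 0.9
    decoy_snp_fraction: float = 0.02  # background sites listed in the SNP set
    adar_tumor_fold: float = 2.0
    expression_sigma: float = 0.3
    n_clinical_sites: int = 4
    hazard_ratio_edited: float = 3.0
    baseline_hazard: float = 1.0 / 2000.0  # per day
    followup_days: float = 3000.0
    seed: int = 0

    def __post_init__(self):
        fracs = self.editing_site_fraction + self.snp_site_fraction + self.strand_artifact_fraction
        if fracs > 1.0:
            raise ValueError(f"site-class fractions sum to {fracs} > 1")
        for f in ("editing_site_fraction", "snp_site_fraction", "strand_artifact_fraction",
                  "seq_error_rate", "snp_carrier_prob", "dna_caller_sensitivity",
                  "decoy_snp_fraction", "normal_enriched_fraction"):
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{f} must lie in [0, 1], got {v}")
        if self.hazard_ratio_edited <= 0:
            raise ValueError("hazard_ratio_edited must be positive")


@dataclass
class Truth:
    """Ground-truth labels of a simulated cohort."""

    site_class: pd.Series  # index (chrom, pos), values in SITE_CLASSES
    sites: pd.DataFrame  # chrom, pos, ref, site_class
    edited: pd.DataFrame  # bool, index sites, columns individuals (editing carriers)
    genotype: pd.DataFrame  # {"ref","het","hom"}, index sites, columns individuals
    clinical_sites: list  # (chrom, pos) tuples linked to survival
    individuals: list


@dataclass
class SimResult:
    config: SimConfig
    counts: dict  # (individual, tissue, assay) -> pileup DataFrame
    variants: dict  # (individual, tissue) -> VCF-like DataFrame
    snp_set: SnpSet
    expression: pd.DataFrame  # individual, tissue, gene, value
    survival: pd.DataFrame  # individual, time_days, event
    truth: Truth


def _site_universe(n_sites: int) -> pd.DataFrame:
    half = n_sites - n_sites // 2
    chroms = np.array(["chr1"] * half + ["chr2"] * (n_sites - half))
    pos = np.concatenate([
        np.arange(half, dtype=np.int64) * 100 + 1001,
        np.arange(n_sites - half, dtype=np.int64) * 100 + 1001,
    ])
    return pd.DataFrame({"chrom": chroms, "pos": pos, "ref": "A"})


def _split_bases(rng, n_a, n_c, n_g, n_t, g_plus_prob):
    """Split per-base totals into strand counts; G gets its own strand prob."""
    out = {}
    for base, tot, p in (("A", n_a, 0.5), ("C", n_c, 0.5), ("G", n_g, None), ("T", n_t, 0.5)):
        if p is None:
            plus = rng.binomial(tot, g_plus_prob)
        else:
            plus = rng.binomial(tot, p)
        out[f"{base}_plus"] = plus
        out[f"{base}_minus"] = tot - plus
    return out


def simulate_cohort(config: SimConfig = SimConfig()) -> SimResult:
    """Generate a full synthetic matched cohort (deterministic given seed)."""
    rng = np.random.default_rng(config.seed)
    sites = _site_universe(config.n_sites)
    n = config.n_sites
    individuals = [f"IND{i:03d}" for i in range(config.n_individuals)]

    # --- site class assignment -------------------------------------------
    n_edit = round(n * config.editing_site_fraction)
    n_edit_normal = round(n_edit * config.normal_enriched_fraction)
    n_snp = round(n * config.snp_site_fraction)
    n_het = round(n_snp * config.het_snp_fraction)
    n_art = round(n * config.strand_artifact_fraction)
    labels = np.array(
        ["true_editing_tumor_enriched"] * (n_edit - n_edit_normal)
        + ["true_editing_normal_enriched"] * n_edit_normal
        + ["germline_snp_het"] * n_het
        + ["germline_snp_hom"] * (n_snp - n_het)
        + ["strand_artifact"] * n_art
        + ["clean_background"] * (n - n_edit - n_snp - n_art),
        dtype=object,
    )
    labels = labels[rng.permutation(n)]
    sites = sites.assign(site_class=labels)
    is_edit = np.isin(labels, ["true_editing_tumor_enriched", "true_editing_normal_enriched"])
    is_het = labels == "germline_snp_het"
    is_hom = labels == "germline_snp_hom"
    is_art = labels == "strand_artifact"
    is_clean = labels == "clean_background"

    # --- per-individual carrier / genotype structure ----------------------
    lo, hi = config.carrier_prob_range
    carrier_prob = np.where(is_edit, rng.uniform(lo, hi, size=n), 0.0)
    edited = rng.random((n, config.n_individuals)) < carrier_prob[:, None]
    geno = np.full((n, config.n_individuals), "ref", dtype=object)
    snp_carrier = rng.random((n, config.n_individuals)) < config.snp_carrier_prob
    geno[is_het] = np.where(snp_carrier[is_het], "het", "ref")
    geno[is_hom] = np.where(snp_carrier[is_hom], "hom", "ref")

    site_index = pd.MultiIndex.from_arrays([sites["chrom"], sites["pos"]], names=["chrom", "pos"])
    truth = Truth(
        site_class=pd.Series(labels, index=site_index, name="site_class"),
        sites=sites.copy(),
        edited=pd.DataFrame(edited, index=site_index, columns=individuals),
        genotype=pd.DataFrame(geno, index=site_index, columns=individuals),
        clinical_sites=[],
        individuals=individuals,
    )

    # --- SNP set (planted positions + decoys at clean sites) --------------
    decoy = is_clean & (rng.random(n) < config.decoy_snp_fraction)
    snp_mask = is_het | is_hom | decoy
    snp_set = SnpSet(zip(sites.loc[snp_mask, "chrom"], sites.loc[snp_mask, "pos"]))

    # --- per-sample count tables and DNA variant calls --------------------
    err = config.seq_error_rate
    counts: dict = {}
    variants: dict = {}
    geno_frac = np.where(geno == "het", 0.5, np.where(geno == "hom", 1.0, 0.0))
    for j, indiv in enumerate(individuals):
        for tissue in TISSUES:
            if tissue == "tumor":
                level_te, level_ne = config.tumor_edit_level, config.normal_edit_level
            else:
                level_te, level_ne = config.normal_edit_level, config.tumor_edit_level
            for assay in ASSAYS:
                mean = config.rna_mean_depth if assay == "rna" else config.dna_mean_depth
                r = config.depth_dispersion
                depth = rng.negative_binomial(r, r / (r + mean), size=n)
                f = geno_frac[:, j].copy()  # SNPs show in both assays
                if assay == "rna":
                    mask_te = labels == "true_editing_tumor_enriched"
                    mask_ne = labels == "true_editing_normal_enriched"
                    f[mask_te] = np.where(edited[mask_te, j], level_te, 0.0)
                    f[mask_ne] = np.where(edited[mask_ne, j], level_ne, 0.0)
                    f[is_art] = config.artifact_level
                p_g = f * (1.0 - err) + (1.0 - f) * err / 3.0
                n_g = rng.binomial(depth, p_g)
                rest = depth - n_g
                with np.errstate(invalid="ignore", divide="ignore"):
                    p_c = np.where(p_g < 1.0, (err / 3.0) / (1.0 - p_g), 0.0)
                n_c = rng.binomial(rest, np.clip(p_c, 0.0, 1.0))
                rest2 = rest - n_c
                with np.errstate(invalid="ignore", divide="ignore"):
                    p_t = np.where(p_g + err / 3.0 < 1.0,
                                   (err / 3.0) / (1.0 - p_g - err / 3.0), 0.0)
                n_t_ = rng.binomial(rest2, np.clip(p_t, 0.0, 1.0))
                n_a = rest2 - n_t_
                g_plus = np.full(n, 0.5)
                if assay == "rna":
                    g_plus[is_art] = config.strand_imbalance
                strand = _split_bases(rng, n_a, n_c, n_g, n_t_, g_plus)
                df = pd.DataFrame({"chrom": sites["chrom"], "pos": sites["pos"], "ref": "A", **strand})
                df = df[df[[c for c in df.columns if c.endswith(("plus", "minus"))]].sum(axis=1) > 0]
                counts[(indiv, tissue, assay)] = df.reset_index(drop=True)
                if assay == "dna":
                    called = (geno[:, j] != "ref") & (
                        rng.random(n) < config.dna_caller_sensitivity
                    ) & (depth > 0)
                    vdf = pd.DataFrame(
                        {
                            "chrom": sites.loc[called, "chrom"].to_numpy(),
                            "pos": sites.loc[called, "pos"].to_numpy(),
                            "ref": "A",
                            "alt": "G",
                            "genotype": np.where(geno[called, j] == "hom", "hom", "het"),
                            "depth": depth[called],
                            "qual": 99.0,
                        }
                    )
                    variants[(indiv, tissue)] = vdf

    # --- expression --------------------------------------------------------
    any_edited = edited.any(axis=0)  # per individual: carries >= 1 editing site
    rows = []
    for j, indiv in enumerate(individuals):
        for tissue in TISSUES:
            for gene in ("ADAR", "ADARB1", "ADARB2"):
                base = math.exp(3.0 + rng.normal(0.0, config.expression_sigma))
                if tissue == "tumor" and any_edited[j]:
                    base *= config.adar_tumor_fold
                rows.append({"individual": indiv, "tissue": tissue, "gene": gene, "value": base})
    expression = pd.DataFrame(rows)

    # --- survival ----------------------------------------------------------
    edit_idx = np.nonzero(is_edit)[0]
    n_clin = min(config.n_clinical_sites, edit_idx.size)
    clin_idx = rng.choice(edit_idx, size=n_clin, replace=False) if n_clin else np.array([], dtype=int)
    truth.clinical_sites = [
        (sites["chrom"].iloc[i], int(sites["pos"].iloc[i])) for i in sorted(clin_idx)
    ]
    clin_edited = edited[clin_idx].any(axis=0) if n_clin else np.zeros(config.n_individuals, bool)
    hazard = config.baseline_hazard * np.where(clin_edited, config.hazard_ratio_edited, 1.0)
    raw_t = rng.exponential(1.0 / hazard)
    event = raw_t <= config.followup_days
    time = np.minimum(raw_t, config.followup_days)
    survival = pd.DataFrame(
        {"individual": individuals, "time_days": np.round(time, 1), "event": event}
    )

    return SimResult(config, counts, variants, snp_set, expression, survival, truth)


def score_calls(called_sites, truth: Truth) -> dict:
    """Confusion summary of cohort-level calls against the planted truth.

    ``called_sites`` is an iterable of objects with ``chrom``/``pos`` (e.g.
    SiteKey or CohortSite.site) or (chrom, pos) tuples.  Sensitivity is the
    fraction of true editing sites called; FDR the fraction of calls that
    are not true editing sites (``nan`` when nothing was called); the
    per-class breakdown attributes each false call to its planted class.
    """
    keys = set()
    for s in called_sites:
        if hasattr(s, "site"):
            s = s.site
        if hasattr(s, "chrom"):
            keys.add((s.chrom, s.pos))
        else:
            keys.add((str(s[0]), int(s[1])))
    cls = truth.site_class
    edit_classes = {"true_editing_tumor_enriched", "true_editing_normal_enriched"}
    true_edit = {k for k, c in cls.items() if c in edit_classes}
    called_true = keys & true_edit
    false_calls = keys - true_edit
    per_class = {c: 0 for c in SITE_CLASSES}
    for k in keys:
        if k in cls.index:
            per_class[cls.loc[k]] += 1
    return {
        "n_called": len(keys),
        "n_true_editing": len(true_edit),
        "sensitivity": len(called_true) / len(true_edit) if true_edit else math.nan,
        "fdr": len(false_calls) / len(keys) if keys else math.nan,
        "per_class_calls": per_class,
    }
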