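# rnaedit

Confident discovery of A-to-I (A-to-G) RNA-editing sites from matched
tumor–normal RNA- and DNA-sequencing allele counts.

## The problem

A-to-I editing converts adenosine to inosine in RNA; sequencers read inosine
as guanosine, so edits show up as A>G mismatches in RNA-seq. The catch is
that A>G mismatches also arise from germline A/G variants, sequencing error
and alignment artifacts, and naive transcriptome-wide calling drowns in
false positives — above all from heterozygous DNA variants that the exome
data happened to cover too thinly to call. `rnaedit` is for analysts with
per-site allele counts (pileups) from RNA and DNA of matched normal/tumor
samples across a cohort who want editing calls confident enough to carry
downstream clinical analysis.

## The method

For a site with `x` alternative (G) reads out of `n` DNA reads, let `U` be
the exact one-sided 100·(1−α)% upper confidence bound on the binomial
success probability (Clopper–Pearson; at `x = 0`, `U = 1 − α^(1/n)`). The
**zero-confidence score** is

```
Z = −10 · log10(U)
```

High `Z` means the DNA data actively demonstrate the absence of a G allele,
rather than merely failing to show one. With α = 0.05 and `x = 0`, depths
n = 5, 10, 30 score 3.46, 5.87 and 10.22; the default cutoff `Z ≥ 10`
therefore demands ≥ 29 alternative-free DNA reads, in the DNA of *both*
matched samples.

Around this score sits a filter cascade per sample: A-reference sites whose
only alternative allele is G, more than 4 reads at base quality ≥ 25,
strand-bias Fisher p ≥ 0.01, subtraction of called homozygous A>G DNA
variants (> 4 reads, calling quality ≥ 50), then the zero-confidence
filter. Surviving sites are compared between matched samples on the 2×2
table of RNA reference/alternative counts: odds ratio `OR` and Fisher exact
p, keeping sites with `p ≤ 0.05` and `OR ≥ 2.0` (tumor-enriched) or
`OR ≤ 0.5` (normal-enriched). A single-sample mode compares RNA against DNA
counts instead (`Z ≥ 10` and `OR ≥ 2`). Cohort-level recurrence (a site
called in more than 4 individuals) and a known-SNP (dbSNP-like) negative
control set — annotation only, never removal — quantify reliability, and
edited/non-edited groups feed ADAR differential-expression flags (Welch's
test) and Kaplan–Meier/log-rank survival association with Bonferroni
correction.

A synthetic-cohort simulator (`rnaedit.simulate`) generates matched count
tables, variant calls, SNP sets, expression and survival data with known
ground truth, so the whole pipeline is testable end to end without any
external data.

## Worked example

```python
from rnaedit import simulate as sim, pipeline as pl, cohort as coh

cfg = sim.SimConfig(n_individuals=8, n_sites=1200, seed=11)
r = sim.simulate_cohort(cfg)

by = {}
for ind in r.truth.individuals:
    cands, stage_counts = pl.run_matched_individual(
        ind,
        r.counts[(ind, "normal", "rna")], r.counts[(ind, "normal", "dna")],
        r.counts[(ind, "tumor", "rna")], r.counts[(ind, "tumor", "dna")],
        r.variants[(ind, "normal")], r.variants[(ind, "tumor")])
    by[ind] = cands

all_sites, recurrent = coh.aggregate_recurrence(by, min_individuals=4)
print("aggregated sites:", len(all_sites), "recurrent:", len(recurrent))
print("SNP-set overlap:", coh.dbsnp_overlap_rate(all_sites, r.snp_set))
m = sim.score_calls(all_sites, r.truth)
print("sensitivity %.3f  FDR %.3f" % (m["sensitivity"], m["fdr"]))
```

prints

```
aggregated sites: 22 recurrent: 4
SNP-set overlap: 0.0
sensitivity 0.917  FDR 0.000
```

i.e. 22 distinct sites were called with a significant direction in at least
one individual, 4 of them in more than 4 of the 8 individuals; none of the
called sites coincides with the known-SNP set; 22 of the 24 planted editing
sites were recovered with no false calls.

The same flow is available from the shell:

```
rnaedit simulate --seed 11 --out run/
rnaedit matched --manifest run/cohort_manifest.tsv --out run/matched/
rnaedit cohort --calls run/matched/candidates.tsv --snps run/snps.bed --out run/cohort/
rnaedit clinical --calls run/matched/candidates.tsv \
    --expression run/expression.tsv --survival run/survival.tsv --out run/clinical/
rnaedit score --calls run/cohort/cohort_sites.tsv --truth-dir run/ --out run/score.json
```

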