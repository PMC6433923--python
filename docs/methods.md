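# Methods

## Statistical model

### Zero-confidence score

At a candidate locus the DNA reads are modelled as `n` Bernoulli trials
with `x` alternative-allele (G) successes. The score is
`Z = −10·log10(U)` where `U` is the exact one-sided `100(1−α)%` upper
confidence bound on the success probability — the Clopper–Pearson
construction, i.e. the `1−α` quantile of `Beta(x+1, n−x)`, with the closed
form `U = 1 − α^(1/n)` at `x = 0` and `U = 1` at `x = n`. The exact bound
(rather than a likelihood-interval or normal-approximation bound) is used
because it reproduces the reference scores 3.46 / 5.87 / 10.22 at depths
5 / 10 / 30 exactly; the construction is noted here because the bound's
usual citation does not pin down one formula. `Z` is monotone: it falls as
alternative reads appear and rises with alternative-free depth. The default
cutoff `Z ≥ 10` at `α = 0.05` corresponds to a minimum alternative-free
depth of 29 (`min_depth_for_score`). Allowing `x > 0` rather than requiring
exact zeros tolerates sequencing error in deep data.

Rationale: the score converts "no G seen" into a quantified statement.
Ten reads without a G are compatible with a heterozygote at probability
`0.5^10 ≈ 1e−3` per locus — across millions of loci that is thousands of
missed heterozygotes, which is precisely the dominant false-positive mode
of RNA-editing discovery. The filter is applied to the DNA counts of both
matched samples; a site must pass in both.

### Exact tests and odds ratios

All 2×2 comparisons use Fisher's exact test (hypergeometric; two-sided p
sums the probabilities of tables, at fixed margins, no more probable than
the observed one). Sidedness of the matched test is configurable; the
default is two-sided as the conservative standard choice. The test is
delegated to `scipy.stats.fisher_exact`; the test suite verifies it against
an independent integer-arithmetic full-enumeration oracle for every table
with total ≤ 40.

The odds ratio is the raw cross product `(a·d)/(b·c)` oriented so that
values above 1 mean a higher alternative fraction in tumor (matched mode)
or in RNA (single-sample mode). Zero-cell policy: raw ORs report `+inf`
when only the denominator vanishes — an infinite OR *passes* an `OR ≥ 2`
threshold, which matters because the cleanest editing sites (zero
alternative reads in normal RNA) produce exactly this pattern — and `nan`
(undefined, never significant) when both cross products vanish. Haldane-
corrected ORs (+0.5 per cell) are emitted alongside for finite reporting.
Thresholds are inclusive: the pruned region is the open set
`0.5 < OR < 2.0` or `p > 0.05`.

### Strand bias

Fisher's exact test on the strand × allele table of the RNA counts;
a site passes with `p ≥ 0.01`. Sites with zero alternative reads are
trivially unbiased (`p = 1`). The filter is applied to RNA only — the
protocol states it for the RNA side, and DNA strand artifacts are already
absorbed by the zero-confidence requirement.

### Survival and expression

Kaplan–Meier product-limit curves per group and the standard two-group
log-rank test (hypergeometric variance at tied event times) via
`lifelines`. Multiplicity over sites is handled by Bonferroni
(`min(1, p·n_tests)`) with `n_tests` an explicit argument — the number of
tested sites is a reporting decision the caller owns. Multi-site markers
are unions: an individual is edited on the marker if edited at any member
site. ADAR differential expression uses Welch's unequal-variance t test
(tumor vs normal within the edited group) per gene over the configurable
gene set {ADAR, ADARB1, ADARB2}, flagging a site when *any* gene is
significant; per-gene p-values are always reported so stricter aggregation
rules can be applied downstream. Degenerate inputs (groups smaller than 2,
zero variance in both groups with unequal means, no events at all) return
an undefined marker (`nan`) and are treated as not significant, never as
significant.

## Pipeline semantics

* Coordinates are 1-based, fully closed, throughout (VCF/pileup
  convention); BED inputs are converted on read.
* A candidate site must have A reference with reads only on A and G
  (a `max_third_allele_fraction` tolerance, default 0, relaxes this),
  total RNA reads > 4 at base quality ≥ 25. Sites with zero G reads remain
  candidates if covered — a tumor-only editing site has no G in normal RNA,
  and the matched table needs both samples' counts; such sites are
  significant only when the other sample supplies the signal.
* A site enters the matched comparison only when it survives the per-sample
  cascade (extraction, variant subtraction, zero-confidence) in **both**
  samples.
* DNA-variant subtraction removes sites positionally matching an accepted
  homozygous A>G call (depth > 4, quality ≥ 50) of the same sample.
  Heterozygous variants are deliberately not subtracted: the
  zero-confidence filter removes them wherever DNA coverage exists, and
  positions with neither coverage nor a call fail the filter anyway
  (no DNA reads ⇒ score 0).
* Antisense representation (T reference, sole alternative C) is off by
  default — the protocol keeps genome-strand A>G only — and available for
  stranded libraries via `include_tc_strand`, which normalizes counts with
  strands swapped and flags the record.
* Known-SNP membership is positional (chromosome + position) by default,
  since a missed DNA variant coincides with the SNP position whatever the
  catalogued allele; allele-aware membership is available when the SNP set
  came from VCF. SNP overlap is an annotation and a quality metric, never a
  filter.
* Recurrence keeps sites called with a significant direction in more than
  `min_individuals` (default 4) distinct individuals; tumor- and
  normal-enriched tallies are kept separately, and the stratified SNP
  overlap table reports both "exactly k" and "at least k" strata.
* Every run logs per-stage survivor counts (candidates, after subtraction,
  after zero-confidence, common sites, significant) per individual.

### Dual-aligner read combination

`combine_aligner_reads` merges two aligners' outputs one read at a time:
reads mapped by only one aligner are kept; the same read at the same
location keeps the higher-scoring record; the same read at different
locations keeps the single best-scoring record. "Same read" means same
read identifier; scores are compared across aligners without normalization
(a documented caveat — alignment scores of different aligners are not on a
calibrated common scale), and exact ties break deterministically toward
the first aligner, then the lexicographically smaller location.

## The simulator

`rnaedit.simulate` draws, per site, per sample and per assay, a
negative-binomial depth (size 10, mean 60 by default — over-dispersion
mimicking exome capture and expression variation) and allocates reads
multinomially: the site's true alternative fraction perturbed by a
symmetric per-base error rate (default 0.001), strands split
binomial(0.5) except at artifact sites. Site classes: true editing
(RNA-only G at level 0.4 in tumor / 0.0 in normal by default, carried by a
per-site random subset of individuals with carrier probability uniform on
[0.1, 0.9], so recurrence varies), heterozygous and homozygous germline
SNPs (~50% / ~100% G in both assays and tissues of carriers), strand
artifacts (RNA alternative reads on one strand), and clean background.
The simulated DNA caller reports planted SNPs with sensitivity 0.9 —
the missed calls are exactly the false-positive mode the zero-confidence
filter exists for. The SNP position set contains all planted SNPs plus a
2% decoy fraction of background sites (catalogued SNPs not polymorphic in
the cohort). Edited individuals' tumor ADAR expression is shifted by a
configurable fold (default 2×) so DE flags have planted positives, and
survival is exponential with the hazard multiplied (default 3×) for
individuals edited at a small set of designated clinically-linked sites,
censored administratively at 3,000 days.

What the simulator does **not** model: alignment and mapping error,
splice-junction artifacts, PCR duplicates, GC- or position-dependent error,
linkage between nearby sites, subclonal tumor structure. Passing tests on
synthetic cohorts therefore demonstrate the statistical machinery — the
filters remove what they claim to remove under the stated generative
model — not performance on real tissue data, whose artifact spectrum is
broader.

Determinism: all draws flow from one `numpy` generator seeded by
`SimConfig.seed`; equal config and seed give byte-identical output files.

## Problem sizes and defaults

The reference synthetic cohort used by the end-to-end tests is 20
individuals × 5,000 sites with 100 true tumor-enriched editing sites at
editing level 0.4 and ~60× mean coverage in both assays — large enough for
the recurrence and overlap statistics to be stable, small enough to run
end-to-end in seconds. Null calibrations use 10,000 replicates. The
exact-test cross-check enumerates all 2×2 tables with total ≤ 40, reduced
to one representative per symmetry orbit (the p-value is invariant under
row/column swaps and transposition, itself property-tested).

## Known limitations

* Editing levels below ~0.1 at 60× coverage are usually insignificant in
  the per-individual Fisher test; sensitivity claims hold at the simulated
  effect sizes, not for rare or low-level editing.
* The matched test conditions on both samples being covered and candidate;
  sites expressed in only one tissue are not discoverable in matched mode.
* Cross-aligner score comparability in read combination is assumed, not
  calibrated.
* Bonferroni is conservative under correlated sites; no FDR alternative is
  provided because the downstream analyses report few, strongly recurrent
  sites.
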