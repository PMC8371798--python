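# Methods

This note documents the models, conventions and numerical choices behind
`strpanel`, and what the synthetic data do and do not establish about real
non-invasive genotyping data.

## Data model and conventions

Alleles are integer fragment sizes (bp) as binned by the genotyping
software; no raw-signal processing or re-binning is attempted.  A diploid
call is an unordered pair stored sorted ascending; missing data is an
explicit sentinel (never the on-disk `0` of the GenAlEx codominant layout).
Replicate-level calls may carry more than two alleles: that multiset is
preserved because ">2 alleles in one amplification" is the operational
mixture signature in species with 2–3 alleles per locus.

Pairwise genotype comparison uses pairwise deletion: loci where either call
is missing are excluded from the compared count and reported separately.  A
strict mode counting missing-vs-called as a mismatch is available.  Pair
totals are reported under the unordered n(n−1)/2 convention by default;
`ordered` and `squared` (n², self-pairs not tallied in the histogram)
conventions are provided for compatibility with reports quoting n² totals —
whether such totals include self-pairs is rarely stated, so both are exact
options rather than a guess.

A sex marker (Amelogenin-style, X/Y fragment classes) is excluded from all
diversity and identity statistics but participates in individual matching
and in calibration, where it carries one offset per fragment class.

## Diversity and Hardy–Weinberg

He is the uncorrected 1 − Σp² (the unbiased 2n/(2n−1) version is also
reported): the reference panel's printed diallelic He values back-solve to
allele frequencies cleanly only under the uncorrected form.  The HWE test
is the exact conditional test: given observed allele counts, all genotype
arrays are enumerated (A ≤ 4) and the two-sided p-value sums the
probabilities of arrays no more probable than the observed one
(probability-ordered tail, ties included within 1e-9).  When complete
enumeration would exceed ~2×10⁶ arrays the conditional null is sampled
instead by random pairing of the gene copies (20,000 draws, seeded) — the
same distribution the enumeration computes.  Above four alleles a pooled
chi-square (expected class < 5 pooled) stands in.  The one-sided tail
toward heterozygote deficiency drives the null-allele screen, alongside
the Chakraborty (He−Ho)/(He+Ho) and Brookfield (He−Ho)/(1+He) moment
estimators.

F-statistics are the Weir–Cockerham (1984) variance components (a, b, c)
summed over alleles and loci; multilocus estimates are ratios of summed
components, and the leave-one-locus-out jackknife supplies the SE.
Negative estimates are reported as computed — truncation at zero would
bias small-population comparisons where heterozygote excess is real.

## Identity probabilities

P_ID and P_IDsib use the standard HWE formulas on sample allele
frequencies, without sampling-bias correction (the "observed P_ID"
empirical variant is deliberately out of scope).  Loci are ranked by
ascending per-locus P_ID; ties break by descending He when He is supplied,
then by name, so rankings are total and reproducible.  Threshold
comparisons are strict (<).  The expected number of mismatching loci
between two profiles is Poisson-binomial with per-locus mismatch
probability 1 − match; the pmf is computed by an O(L²) DP convolution and
checked in the tests against exhaustive 2^L enumeration.

## Replicate error model and QC

One observation model is shared by the generator, the likelihoods and the
estimators.  Per replicate and locus: amplification fails with the missing
rate; otherwise a heterozygote drops one allele (uniformly chosen) with
probability ADO, yielding a false homozygote; independently with
probability FA one of the two allele copies is replaced by an artifact
allele drawn uniformly from the locus universe *excluding the alleles
already in the call*.  A false allele is by definition an allele the call
does not carry; under this convention FA events are observable as
non-consensus alleles and the counting estimators below recover the
configured rates.  Replacement (not addition) keeps single-source
replicates at ≤ 2 alleles, so the 3+-allele mixture signature stays
unambiguous.  Corollary: on a diallelic locus a true heterozygote offers no
spare allele and the FA event is unrealizable there — FA on such loci is
expressed only in homozygous(-appearing) replicates, which mirrors what a
replicate-counting estimator could ever see.

Error rates are exact counts (GIMLET-style): ADO = false homozygotes for a
consensus allele among positive replicates of heterozygous-consensus
samples; FA = replicates showing ≥ 1 allele absent from the consensus,
over all positive replicates.  An ADO denominator of zero yields an
*absent* rate, never 0.

Consensus calling follows the multiple-tubes literature: a heterozygote
needs each allele seen in ≥ 2 replicates; a homozygote needs ≥ 3 concordant
homozygous replicates with no second allele ever observed; anything else is
unresolved.  These thresholds are configurable — the source studies rarely
print them, and 2/3 are the common defaults.

Reliability is a Bayesian re-specification of the published
reliability-scoring approach, not a binary-exact clone: per locus, the
posterior probability of the consensus genotype under an HWE prior (from
population allele frequencies) and the replicate likelihood from the
observation model; multilocus reliability is the product over called loci.
Replicates with 3+ alleles have zero likelihood under every single-source
genotype and drive reliability to zero.  The QC loop accepts at ≥ 0.95
multilocus reliability with all loci resolved, otherwise requests
additional replicates at unresolved loci and loci below the per-locus share
of the confidence target (confidence^(1/L)), up to a configurable number of
rounds (default 2), then discards; a mixture signature stops the loop
immediately.

## Calibration

Per-locus conversion keys are inferred from shared reference samples by
rank-pairing the sorted allele lists in the two frames (offsets are
monotone shifts, so rank pairing is order-preserving) and requiring a
single integer difference across all pairs; anything else — including
ploidy disagreements — is recorded as an inconsistency with the offending
pairs, never silently rounded.  Sex markers are fitted with one offset per
fragment class; classes must be separable by size, and the class boundary
is stored with the key so conversion is self-contained.

One reference-data note: the published conversion table's G10P row prints
key +7 while its own size ranges (Lab2 159–171, Lab3 152–164) imply −7
under the table's stated direction; every other row is internally
consistent.  The packaged data treat the ranges as primary and store −7.

## The synthetic generator

The generator emulates the study conditions the analyses assume: 113
individuals at 13 loci with 2–3 alleles, per-locus He equal to the
published profile (one major allele, remaining mass split equally — solved
in closed form for 2 alleles, numerically otherwise), per-locus ADO/FA as
published, 4 replicates per sample, a per-replicate failure rate of 0.05
(not printed in the source material; a typical order for non-invasive
extracts), a full-sib fraction of 0.2 (the true relatedness structure of
the study sample is unpublished; this free parameter makes the sibling
bound consequential without dominating), and two lab frames related by the
published per-locus offsets.  Individuals are drawn locus-independently
under HWE; sib pairs come from Mendelian segregation of two unsampled
parents.  All randomness flows from one seed, with per-sample substreams
derived deterministically so subsetting is reproducible.

What the generator does *not* model: DNA degradation kinetics, amplification
bias beyond ADO/FA/failure, stutter, linkage, inbreeding, population
substructure, or allele-size homoplasy between labs.  Tests passing on this
synthetic population therefore establish the correctness of the statistics
and the QC logic under the stated model — not that real hair-snag data meet
the model's assumptions.

## Panel evaluation and selection

Panels are scored on mean Ne/Ho/He (unweighted across loci, SE across
loci), multilocus P_ID/P_IDsib, observed 0–3-mismatch pair counts, mean
ADO/FA (unweighted; undefined ADO counts as 0), and maximum fragment
length.  The selection rule operationalizes the three published criteria —
low molecular weight, high discriminatory power, low genotyping error — as:
start from all candidates, drop loci violating per-locus error caps, and
re-admit the *fewest* dropped loci needed to bring multilocus P_IDsib under
the ceiling, taking the first admissible combination in informativeness
order (ascending P_ID, then shorter maximum fragment, then name).  The
minimal-re-admission search is exhaustive over the dropped set, so the rule
coincides with a brute-force subset search and is invariant to input
order.  Defaults: P_IDsib ceiling 0.006 (≈ 0.3 expected collisions in a
population of 50); FA cap 0.037, sitting between the worst FA retained on
the reference panel (0.035) and the rate that disqualified a locus there
(0.039).  Both are declared policy defaults to be set per study, not
universal constants.

## Problem sizes and numerical tolerances

Frequency maps must sum to 1 within 1e-9 (asserted), He targets are hit
within 1e-9, Poisson-binomial pmfs sum to 1 within 1e-12, and reliability
oracles agree with enumeration within 1e-9.  The simulation-based checks
use sizes chosen for tight Monte-Carlo error at desk scale: 5,000 positive
replicates for error-rate recovery (≤ 3 MC SEs), 1,000 populations of 113
for the exact-test type-I rate (±0.02), 50 replicates of a 20-locus
two-deme Balding–Nichols model at F = 0.10 for the Fst recovery (±0.02),
10,000 disjoint pairs for the mismatch-distribution goodness of fit
(disjoint because all-pairs histograms share individuals and are
over-dispersed relative to the multinomial null), and 100 random tables or
offset maps for the I/O and calibration round-trip properties.

## Known limitations

* Reliability scores are model-based posteriors; if true error rates differ
  from those supplied, the 0.95 acceptance level is nominal, not actual.
* The exact HWE test is conservative at small n (discrete support), as all
  conditional exact tests are.
* P_ID/P_IDsib assume locus independence and HWE; family structure beyond
  full sibs and substructure are out of scope.
* Calibration assumes constant integer offsets (plus per-class offsets for
  sex markers); platform effects that are non-constant across the allele
  range would surface as inconsistencies rather than being fitted.
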