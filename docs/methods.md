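# Methods

## Model and conventions

A somatic single-base substitution is represented by its substitution
class and immediate 5'/3' flanking bases. Substitutions with a purine
reference are reverse-complemented (alleles and flanks, flanks swapped)
so every channel carries a C or T reference, yielding 96 channels
ordered COSMIC-style: classes C>A, C>G, C>T, T>A, T>C, T>G, and within
each class the 16 flank contexts ordered 5' then 3' over A, C, G, T.
Stranded (192-channel) catalogs split each channel into a coding (`+`,
untranscribed strand of the gene) and noncoding (`-`, transcribed
strand) sub-channel; "a C>A mutation on the coding strand" means its
pyrimidine-centered representation lies on the coding strand. This
convention is fixed in one place (`channels.py`) and everything else
derives from it.

Catalog construction skips indels and records with ambiguous context
bases, and excludes records whose stated reference allele contradicts
the reference sequence; all exclusions are counted in a QC report, and
column sums always equal the number of retained SNVs. Mutation tables
are 1-based inclusive; BED intervals are 0-based half-open; the readers
do all conversions.

Territory context-frequency tables cover the 32 pyrimidine-centered
trinucleotides (a purine-centered window is recorded under its reverse
complement). Windows centered on interval positions take their flanks
from the reference even when the flank falls outside the interval,
matching exome capture where flanking context is sequenced; windows
with ambiguous bases or overhanging a contig edge are skipped.

## NMF discovery and the choice of update rule

Discovery factorizes the count matrix V ≈ W·H by multiplicative
updates from i.i.d. uniform(0,1) factors scaled to the catalog's mean
mass. Because the optimization is non-convex, `n_runs` independently
seeded runs (run r uses seed base+r) are performed and the run with the
minimum Frobenius residual ‖V − W·H‖ is kept; W columns are then
renormalized to distributions with compensating row scaling of H, which
leaves the product unchanged.

Two update rules are implemented. The default is the Euclidean
(Frobenius) multiplicative update, for which monotone non-increase of
‖V − W·H‖ is a theorem — and that is the quantity run selection, the
refit stopping rule and the reported residuals are all defined on. The
KL-divergence rule (`update="kl"`) is also available; it is monotone in
generalized KL but not in the Frobenius norm, so with it the error
trace used for selection and stopping is not guaranteed monotone. Using
the Frobenius rule as the default keeps the optimizer and its tracked
objective consistent; on the count catalogs exercised here the two
rules recover planted signatures equally well.

Within a run, iteration stops at `max_iter` (default 2,000) or when the
relative error change drops below 1e-6. A pseudocount of 1e-12 in the
update denominators guards division by zero; zero-count channels are
retained.

Rank diagnostics report, per candidate rank: the best-run residual and
its square (RSS), the best seed, and a cophenetic coefficient computed
from the consensus of sample co-clusterings (samples clustered by their
dominant signature per run; average-linkage tree on 1 − consensus;
Pearson correlation between cophenetic and consensus distances). A
degenerate consensus with no dispersion — for example every run
agreeing completely — is reported as 1.0. Rank selection is
deliberately not automated; the diagnostics are for a human.

Cosine matching of discovered to reference signatures flags a match at
threshold 0.85 (interoperable with published signature tables); ties go
to the lower reference index and are flagged. Similarity to the mean of
caller-specified reference pairs is also reported, since some processes
are best described by an average of two canonical signatures.

## Fixed-signature refitting

With W fixed, H starts at i.i.d. uniform(0,1) × (sample total / K) —
a scale-appropriate start that shortens burn-in — and is updated
multiplicatively. The stopping rule is the flat-trace criterion:
terminate when (err₍ᵢ₋w₎ − errᵢ)/w < tol with window w = 20 iterations
and tol = 1e-4 on the Frobenius error, with a hard `max_iter` cap
(default 10,000, with a warning) guarding non-terminating tolerance
settings. All-zero sample columns receive zero activities. Activity
fractions divide a signature's activity mass by the total activity
mass, per sample and cohort-wide.

## Cross-territory comparison and permutation nulls

Renormalization multiplies each channel by target/source frequency of
its context (the three channels sharing a context share the ratio) and
re-closes to a distribution; it is exactly invertible for strictly
positive frequency tables, and a zero source frequency under signature
mass is an error rather than a silent drop.

The substitution test replaces the candidate signature column with the
external signature, re-infers activities with everything else fixed,
and Pearson-correlates candidate and replacement activities across
samples; a near-constant activity vector makes the correlation
undefined and is flagged. Null distributions are built by (1) full
random permutations of the external signature's 96 entries — the
permutation is deliberately unrestricted rather than within-class — or
(2) w·ref_a + (1−w)·ref_b with distinct reference signatures drawn
uniformly and w ~ Uniform(0,1). The empirical p is the plain proportion
of null correlations ≥ the observed one; the (r+1)/(n+1) small-sample
correction is intentionally not applied, so p = 0 is possible at finite
n. The original-set refit is computed once and reused across null
draws (it does not depend on the draw).

## Strand bias

Each substitution class's coding/noncoding split is tested against
Binomial(n, ½) two-sided by doubling the smaller exact tail (capped at
1) — direction was not pre-specified, and for a symmetric null this
equals the minimum-likelihood two-sided test. Both raw class totals and
signature-attributed counts (credits summed per strand, rounded to
integers for the exact test) are reported, since either could be the
quantity of interest; no multiple-testing correction is applied across
the six classes, but a Benjamini–Hochberg column is emitted for
transparency.

## Attribution and subclonal enrichment

A mutation's credit to signature k is hₖ·W[c,k] / Σⱼ hⱼ·W[c,j] for its
channel c and its tumor's activity vector h — invariant to rescaling
h, summing to 1, with sub-1e-12 credits clamped to zero and the vector
re-closed. Mutations on channels where no signature has mass are
unattributable and counted. Clonality comes from subclone CCF: clonal
iff CCF = 1 within 1e-3 (the tolerance is this package's choice).
Credits are identical for mutations sharing (sample, channel,
clonality), so aggregation groups mutations into such cells and scales
the credit vector by the cell count — exactly equal to per-mutation
iteration, at cohort speed.

The enrichment test applies Pearson's χ² (no continuity correction) to
the K × 2 clonal/subclonal credit table, df = K − 1, pooling credits
across samples (the cohort-level question). Credits are real-valued but
treated as counts — a documented approximation. Zero-credit signatures
are dropped with a warning and df reduced; an all-clonal or
all-subclonal table short-circuits to statistic 0, p 1.

## Detection power and shared/private timing

The power model is Binomial: a site is detectable when ≥ 3 alternate
reads (the conventional minimum-supporting-reads filter, configurable)
would be seen at the mate tumor's depth and expected VAF; the per-base
error rate (default 0) folds into the effective alternate-read
probability as p = vaf·(1−e) + (1−vaf)·e/3. Expected VAF is supplied
by the caller — purity × CCF / 2 for a diploid heterozygous site. A
site detected in both tumors is shared; detected in one with mate
power ≥ 0.8 it is pre_only/post_only; otherwise unpowered and excluded
from pre/post comparisons. The post_only set feeds validation-style
discovery of treatment-era signatures.

## Heterogeneity metrics

Per patient: the proportion of labeled mutations that are subclonal
(pre and post separately, unknowns excluded and counted; undefined with
zero labels), and the count of subclones with CCF > 0 in either tumor.
"High" heterogeneity flags use strict inequality at the conventional
cutoffs (0.2 proportion; 6 subclones); because boundary inclusion is a
convention, the ≥ variants are recorded alongside. Load comparisons use
the two-sided paired t-test on post − pre (a zero-variance difference
vector is flagged degenerate) and Mann–Whitney U for
pre-private/shared/post-private group contrasts. Survival modeling is
out of scope: the package emits the covariate table (metrics plus
pass-through clinical columns) for external tools.

## The synthetic cohort generator

The generator is the package's study-conditions module, not a test
helper. Per patient it builds a truncal clone (CCF 1 in both tumors),
shared subclonal subclones, and pre-/post-private subclones (CCF 0 in
the other tumor, own-tumor CCF ~ Uniform(0.1, 0.8)); each tumor
receives exactly `mutations_per_tumor` mutations split into shared
(65%, of which 75% truncal) and private sites. Channels are drawn
i.i.d. from the generating signature's distribution; each background
mutation first draws its signature from the patient's Dirichlet(1)
exposure mixture. Planted signatures are Dirichlet(0.5) draws on the
96-simplex kept mutually distinct (pairwise cosine < 0.8 by rejection)
for identifiability.

The treatment signature is drawn only for post-private (hence
subclonal) mutations. Its per-patient exposure is Beta-distributed with
mean `treatment_fraction` (default 0.15) and concentration 12 (SD ≈
0.10), capped by the private-mutation budget: patients genuinely differ
in mutagenic response, and a component with literally constant relative
exposure across samples is unidentifiable for NMF — the variability is
both realistic and what makes recovery a meaningful test. Strand labels
are drawn per mutation with a configurable noncoding:coding ratio per
signature and class (default 1:1). Depths are negative-binomial (mean
150, dispersion 5); a 5% fraction of mate-tumor sites draws from a
low-coverage distribution (mean 10) to exercise the power filter;
purity ~ Uniform(0.5, 0.9); half the records are written on the purine
strand to exercise pyrimidine collapsing. CCFs are emitted exactly,
with an optional beta-noise switch (off by default) for robustness
tests.

What the generator does **not** emulate: real genome coordinates and
hotspot structure, copy-number variation and multiplicity, signature
channel correlations beyond the multinomial model, shared subclonal
CCF drift between tumors, and caller-specific artifacts. Passing tests
therefore demonstrate correctness of the analysis chain under the
multinomial signature model, not robustness to every artifact of real
exome data.

## Problem sizes and numerical choices

The reference cohort used by the test suite and the acceptance script
is 30 patients × 2,000 mutations per tumor with 3 background
signatures — enough mass that planted structure is recoverable while
the full chain (two discoveries at 50 runs each, refits, a 1,000-draw
permutation null) completes in well under a minute. Calibration checks
use deliberately small cohorts (8 samples × 400 mutations for the
200-replicate permutation-uniformity check) and simulated credit/count
tables for the 1,000-replicate type-I-error checks of the strand-bias
and enrichment tests, where the quantity under test is the statistical
test itself rather than cohort generation.

Seeds: every stochastic routine takes an explicit seed; multi-run NMF
uses base+r for run r; pipeline stages derive per-stage seeds by fixed
offsets from the base seed. Identical seeds reproduce results exactly.

## Known limitations

- The χ² enrichment test treats fractional credits as counts; with few
  attributed mutations its p-values are approximate.
- Signature-attributed strand-bias counts are rounded to integers for
  the exact binomial test.
- The binomial power model is a documented stand-in for a full
  purity/ploidy-aware power calculation; callers control the expected
  VAF.
- Discovery assumes the catalog rank is chosen by the analyst; no
  automatic rank selection is attempted.
- The generator plants all treatment-signature mutations in post-private
  subclones; partial clonal leakage of a treatment signature is not
  modeled.
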