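# Methods

`mamut` implements the downstream statistics of a mutation-accumulation
(MA) experiment for germline base substitutions, together with a generative
model of such an experiment so every stage can be exercised without
sequencing data. This note records the model, the estimators, the numerical
choices, and what the synthetic data does and does not emulate.

## The experimental model

An MA experiment propagates replicate lineages of a single ancestor through
repeated single-individual bottlenecks. The bottlenecks suppress selection,
so nearly all spontaneous mutations drift to fixation or loss independently
of their effect, and the count of mutations accumulated by a line measures
the mutation rate directly. In ciliates such as *Paramecium*, periodic
autogamy converts the silent germline (micronuclear) genome into a
whole-genome homozygote expressed by the new macronucleus, so germline
mutations surface as homozygous variant calls.

A line's *exposure* is the number of opportunities it had to mutate:
callable nucleotide sites × total cell divisions, where total divisions =
transfers × divisions per culturing cycle. Reported division totals are
conventionally rounded to the nearest ten (e.g. 148 transfers × 6.6
divisions/cycle → 976.8 → 980; `cell_divisions(…, nearest=10)`).

## Rate estimation

The total mutation count n over pooled exposure E is treated as Poisson:

    mu_hat = n / E        (per site per cell division)

Confidence intervals use the exact (Garwood) construction,

    low  = chi2(alpha/2, 2n) / 2,      (0 when n = 0)
    high = chi2(1 - alpha/2, 2(n+1)) / 2,

divided by E. At the counts these experiments yield (tens of events),
normal and score approximations differ visibly from the exact interval, so
the exact form is the only one offered. The exact interval is conservative:
its realised coverage is ≥ the nominal level. Pooling across lines is
always counts-over-pooled-exposure; the estimate is invariant to how
exposure is partitioned among lines, and never a mean of per-line rates.

Two rates are compared with the exact conditional (binomial) test: given
N = n1 + n2, under equal rates n1 ~ Binomial(N, E1/(E1+E2)); the two-sided
p-value doubles the smaller tail and is capped at 1. Tail-doubling was
chosen over minimum-likelihood summation for reproducibility; the choice is
visible in the test suite's enumeration oracle. No multiple-testing
correction is applied across the six per-class comparisons by default; a
Bonferroni column is available behind the pipeline's `bonferroni` flag.

## Spectra and directional rates

Because assembly strands are arbitrary, the twelve ordered base changes
fold two-to-one onto six classes named by the source base pair: A:T→G:C,
A:T→C:G, A:T→T:A, G:C→A:T, G:C→T:A, G:C→C:G. A change is a transition iff
it is purine↔purine or pyrimidine↔pyrimidine on either strand (the two
transition classes are A:T→G:C and G:C→A:T).

Per-class rates are conditional: each class's count is normalised by the
exposure of its *source* pair (A/T-site exposure for A:T→· classes, G/C
for G:C→·). The directional rates are

    u = (n[A:T→G:C] + n[A:T→C:G]) / E_AT      (toward G/C)
    v = (n[G:C→A:T] + n[G:C→T:A]) / E_GC      (toward A/T)

with bias m = u/v. The pair-conserving classes A:T→T:A and G:C→C:G enter
neither u nor v. When per-line A/T vs G/C callable splits are unavailable,
a caller may approximate them by line callable totals × genome-wide base
composition; the simulator always records the exact split, so the pipeline
never needs the approximation on synthetic data.

## Equilibrium composition, selection, and Ne

Under mutation pressure alone the expected equilibrium G/C content is

    p_n = u / (u + v)  =  m / (1 + m).

p_n is always computed from unrounded u and v; printed two-decimal values
of m and p_n therefore need not be mutually consistent after rounding, and
the report never back-derives one from the other. In the summary object
p_n is a derived property of (u, v), so it cannot drift out of sync.

The observed G/C fraction p4 at fourfold-degenerate third-codon positions
is displaced from p_n by selection and/or GC-biased gene conversion. The
population-scaled strength of that force is obtained by inverting the
selection-mutation equilibrium p4 = p_n·e^S / (p_n·e^S + 1 − p_n):

    S = ln[ (p4/(1−p4)) / (p_n/(1−p_n)) ].

This log-odds inversion is verified for self-consistency on a grid over
(0.01, 0.99)² rather than against any external tabulation.

Fourfold-degenerate codons are detected by scanning all 16 codon prefixes
under a configurable NCBI translation table: a prefix XY is fourfold when
XYA/XYC/XYG/XYT all encode the same amino acid and none is a stop. The
default is table 6 (ciliate nuclear code; TAA/TAG encode glutamine), with
table 1 available for non-ciliate reuse; both are checked against a
brute-force 64-codon translation oracle. Internal stop codons in a CDS are
skipped with a warning (they indicate a frame or table problem); codons
containing ambiguity codes are skipped silently.

Genome G/C is reported with its binomial standard error sqrt(p(1−p)/L);
ambiguity codes are excluded from L and counted separately. Effective
population size uses the neutral relation pi_s = 4·Ne·mu, i.e.
Ne = pi_s/(4·mu), with pi_s (fourfold-site pairwise diversity) supplied as
input. Cross-species agreement between p_n and observed G/C is quantified
by the product-moment correlation with its t-test p-value (n−2 df); when
reproducing published correlations the inputs are the printed two-decimal
table columns, the only form in which they exist.

## The synthetic experiment generator

`simulate_ma_experiment` draws, per line i with its own deterministic
substream (root seed + spawn key, so adding lines never perturbs earlier
lines):

1. a callable mask: an exact-size uniform subset of round(f·L) positions
   (an all-true mask shared across lines when f = 1);
2. per-class counts N_c ~ Poisson(rate_c × callable source-pair sites × D),
   with D = transfers × divisions/cycle applied as a single exposure
   multiplier;
3. positions uniform over eligible callable sites, sampled without
   replacement within the line (no double hits — at ~1e-11 per site per
   division over ~800 divisions a collision has probability ~1e-8 per
   line), with alt alleles determined by the class on the strand of the
   reference base.

All calls are emitted homozygous (autogamy is modelled as complete). The
reference genome is i.i.d. with P(G)=P(C)=gc/2. The truth manifest records
the generating config and realized per-class counts, and the writer emits
reference FASTA, one VCF v4.2 per line (GT 1/1), BED callable masks
(0-based half-open), a line-metadata TSV, and a JSON manifest.

Defaults are the conditions of a *P. biaurelia*-like arm: 32 lines, 156
transfers × 5.1 divisions/cycle, callable fraction 0.62, genome G/C 0.25,
total rate 2.44e-11 per site per division. The genome length defaults to
5 Mb — a deliberate scale-down from the tens-of-megabase genomes of real
*Paramecium* (chosen so simulation studies run in seconds); callable-site
counts, not genome length, carry the exposure, so the estimators are
unaffected by the reduction. Because per-class counts for these species
have never been resolved, the default split of the total rate over the six
classes (weights 2:1:2:17:5:2) is this package's choice; it reproduces the
published magnitudes (ts/tv ≈ 1.9, m ≈ 0.045) without claiming the
unpublished per-class values.

What the generator does **not** emulate: read-level error, alignment and
caller artefacts, coverage heterogeneity (the callable mask is uniformly
random, not depth-driven), cross-line contamination, ancestral shared
polymorphism, indels/SVs, and heterozygous intermediate states. Tests that
pass on synthetic data therefore validate the statistics downstream of
variant calling, not the calling itself — which is the intended scope.

## Pipeline filtering

Mirroring the filtering such studies apply between calling and analysis:
reference-mismatching records are a hard error (listing offenders);
non-homozygous genotypes are excluded with a logged reason code (post-
autogamy calls must be homozygous); lines below a configurable callable-
fraction threshold are excluded; and calls sharing scaffold, position and
alleles across lines are dropped by default (independent lines should not
recur a mutation; recurrence indicates ancestry or contamination), with an
`exclude_shared=False` escape hatch for synthetic data whose lines are
independent by construction. Every exclusion carries a machine-readable
reason code. Report tables round exactly as conventional for this
literature: two decimals, rates scaled ×1e11; JSON output keeps full
precision.

## Problem sizes and replication

Simulation-based checks use a 5 Mb genome. At the realistic rate 2.44e-11
with 32 fully callable lines × 800 divisions, a replicate expects only
~3.1 mutations — the rare-event regime is intrinsic to MA data. The
mean-recovery study therefore averages 400 replicate seeds, putting the
Monte-Carlo standard error of the mean estimate below 1% so that its 10%
bias check tests the estimator, not sampling noise. Simulator calibration
compares per-class means over 200 small-genome replicates to their Poisson
expectations within 3 standard errors. Interval coverage is checked with
2000 Poisson draws at each of λ ∈ {1, 5, 29}.

## Known limitations

- Exposure is deterministic given metadata; per-cycle division-count
  variance across transfers is not modelled (only total exposure enters
  the estimators).
- The conditional test is exact but unconditional-power considerations
  (mid-p variants) are not offered.
- GFF3 handling assumes in-frame CDS features (phase 0 at each feature's
  translation start within the spliced transcript); overlapping CDS
  annotations are resolved to the lexicographically first transcript, with
  a log message.
- The scalar S conflates selection and biased gene conversion by
  construction; the package does not attempt to separate them.
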