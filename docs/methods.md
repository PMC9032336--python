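# Methods

## Problem setting

Small RNA-seq of tumors captures, alongside miRNAs, 16–36 nt fragments
excised from snoRNA precursors (sdRNAs). The analysis implemented here
answers three questions: where on each precursor is a fragment specifically
excised (as opposed to diffuse degradation); which fragments are
tumor-enriched across a cohort; and which of those behave like miRNAs —
loaded into Argonaute and complementary to 3'UTR sites.

## Alignment model

Reads count toward a precursor only as whole-read, ungapped, 100%-identity
matches of at least 20 nt. Under these constraints an alignment exists iff
the trimmed read is a substring of the precursor, so the implementation
indexes every 6-mer word of the reference and verifies full-read identity
at each occurrence of the read's first word. This is provably equivalent
to exhaustive substring search (the test-suite checks the equivalence on
random instances) while staying O(occurrences) per read. An E-value
cutoff, familiar from general-purpose local aligners, is vestigial in this
regime — a whole-read exact match of ≥ 20 nt is always reported — and is
deliberately not modelled. Alignment is sense-strand only by default:
small RNA libraries are stranded and an sdRNA is a subsequence of its
precursor transcript; reverse-complement search is a flag. Multi-mapping
reads contribute one alignment per placement.

Adapter trimming removes the longest read suffix that exactly matches a
prefix of the configured 3' adapter (≥ 6 nt overlap). The minimum retained
insert is 15 nt; these reads define the per-library RPM denominator
(`total_reads_post_trim`), while the stricter 20-nt rule applies at
alignment. Keeping the denominator at "all usable reads" makes RPM
independent of the reference set; the alternative (aligned reads only)
would couple a fragment's RPM to whatever else is in the reference.

## Fragment calling

Coverage d(i) over a precursor counts alignments containing position i.
A specifically excised fragment appears as a rectangular plateau with
sharp edges. The caller scores every inter-position boundary i ∈ [0, n]
with an unnormalized single-scale Haar step response,

    score(i) = mean(d[i : i+w]) − mean(d[i−w : i]),   w = 4 nt,

zero-padded at the precursor ends. The response to an ideal step of
height h is a triangular peak with apex exactly h at the step, so plateau
boundaries are local extrema of the score. The track has n+1 entries
because boundaries are fenceposts: a fragment flush against the 3' end has
its fall boundary at i = n.

Candidate boundaries must exceed `edge_threshold_k` (default 4) times the
median |score| over the whole track, zeros included. The median over all
positions — rather than over nonzero scores only — is deliberate: away
from edges the response of both empty and uniformly covered regions is
exactly zero, so on a clean profile the threshold floor is 0 and ideal
plateaus are always callable, while on ragged profiles the median tracks
typical jitter response. (A median over nonzero scores only would, for a
single clean plateau, equal half the peak height and the threshold could
never be met.)

Rise/fall extrema are paired into fragments constrained to 16–36 nt.
Each candidate must satisfy two support rules, both using
`min_support = 10` reads: at least that many alignments contained within
the interval ± 3 nt slop, and — plateau consistency — interior coverage
(interval shrunk by the slop) never below `min_support`. The second rule
rejects rise/fall pairs that bridge a low-coverage gap, e.g. a background
rise at the precursor end paired with a genuine fragment fall. Candidates
overlapping reciprocally ≥ 50% are merged keeping the higher-support, then
leftmost, call. All tie-breaks are leftmost, making catalogues
byte-deterministic and independent of library input order.

Discovery is two-pass: fragments are called once on coverage pooled over
all cohort libraries, then every library is quantified against that shared
catalogue (support by containment within interval ± slop, RPM against the
library's own denominator). A shared catalogue is what makes per-sample
RPM columns comparable; per-library calling would fragment identity across
samples.

## Cohort screen

"Expressed" means RPM ≥ 30 throughout; prevalence is the expressing
fraction of a sample class. Class means include non-expressing samples by
default (a config flag restricts means to expressing samples, which is the
convention used when reporting per-expressing-sample averages). Fold
change is (mean_T + ε)/(mean_N + ε) with ε = 1 RPM, so all-zero normal
arms yield finite, monotone fold changes. The screen is threshold- and
rank-based, not test-statistic-based, so no multiple-testing correction
applies. Ranking is lexicographic: tumor prevalence, then fold change,
then fragment ID. The first filter keeps fold ≥ 2 and tumor prevalence
≥ 0.5; the final selection keeps tumor prevalence strictly > 0.9, normal
prevalence strictly < 0.5, and Ago-IP support ≥ 1 contained read. Ago
libraries are aligned with the identical perfect-match parameters and
never contribute to discovery coverage or to the cohort matrix.

## Target scanning

The duplex model is ungapped and antiparallel: a UTR window of guide
length pairs guide position p (1-based from the guide 5' end) with window
position L − p. Pairs are Watson–Crick {A:U, U:A, G:C, C:G}, wobble
{G:U, U:G}, or unpaired; any N is unpaired. Sequences are held in DNA
alphabet, so wobbles appear as G:T/T:G. A window is reported when the
seed (guide positions 2–8, the standard miRNA convention) is all
Watson–Crick or when some contiguous paired run reaches 7 nt; ranking is
by longest contiguous Watson–Crick run, then paired fraction, then
position. No thermodynamics, bulges or conservation scoring: the contract
is the per-position pair-class track, which is also what the rendered
three-line duplex text (`|` WC, `:` wobble) encodes, losslessly.

## Synthetic data

The generators emulate the structure of the real inputs while keeping
exact, machine-readable truth:

* **Reference**: uniform-random precursors (90–160 nt) with 0–2 planted
  non-overlapping fragment intervals, ≥ 5 nt apart so coverage edges stay
  separable.
* **Libraries**: fragment reads copy the planted interval with up to 2 nt
  shaved per end — never below the 20-nt alignment floor, otherwise
  jittered reads of short fragments would silently vanish from counts and
  bias every truth comparison — and carry the full 3' adapter. Background
  reads are random 20–30 nt inserts rejection-sampled against the set of
  all precursor substrings in that length range, so background alignment
  is impossible by construction and aligner false-positive tests are
  exact, not probabilistic.
* **Cohorts**: per sample and fragment, expression is Bernoulli with a
  class probability; expressing samples draw RPM from a Gamma (shape 2,
  mean-parameterized) truncated at the 30-RPM expression threshold, chosen
  as the simplest right-skewed positive law with closed-form mean control.
  Truncation pulls realized expressing-sample means slightly above the
  nominal mean (≈ +2% at mean 384 RPM, ≈ +6% at mean 150 RPM); reported
  numbers reflect this, deliberately. Read-mode cohorts realize each drawn
  RPM as round(RPM × depth / 10⁶) fragment reads at the stated depth; the
  default emulation parameters mirror a prostate-cancer screen scale
  (489 tumor / 52 normal; prevalences 0.916/0.423 and 0.975/0.308;
  expressing means 384/162 and 711/150 RPM) and are configuration, not
  constants. Read mode is capped at 64 libraries.
* **Ago libraries** draw reads only from a chosen enriched subset, so
  non-enriched fragments have exactly zero Ago support downstream.
* **Planted UTR sites** insert the antiparallel complement of a guide
  span, optionally converting chosen positions to the G:U-compatible base.
  The bases flanking the span are clamped to the guide's own base there
  (a base never pairs with itself), making the planted span exactly the
  longest paired run rather than a lower bound.

What passing tests do and do not show: the generators produce exact-match
reads with uniform backgrounds and no sequencing error, quality variation,
ligation bias, or cross-mapping between precursor families. Recovery on
this data validates the bookkeeping and the detector's contract — not
robustness to the messiness of real libraries, where adapter variants,
mismatches and paralogous snoRNAs would all matter.

## Problem sizes

The test-suite exercises the aligner oracle on 200 random instances, the
perfect-match rules on 1,000 reads, the fragment caller on 500 random
pulses (plus uniform background 1–2), and read-level cohort recovery at
30 tumor / 10 normal libraries of 10⁵ reads over 20 seeds, pooling
realized prevalence against exact binomial 95% intervals. The
reproduction script runs cohort statistics at the full 489/52 scale in
matrix mode, averaged over 20 replicate cohort draws so Monte Carlo error
stays well below single-cohort sampling noise, and the end-to-end
selection at 20/10 libraries × 3·10⁴ reads.

## Known limitations

Single-scale edge detection assumes near-rectangular plateaus; nested or
heavily overlapping isoforms (reciprocal overlap ≥ 50%) collapse to the
better-supported call. Fragments shorter than 20 nt are below the
alignment floor and invisible by design. The RPM denominator convention
and the ≥ 30 RPM "expressed" definition are both configurable because
cohort prevalence figures depend materially on them. The target scanner
ranks by complementarity only; a high-scoring site is a hypothesis for
reporter validation, not evidence of repression.
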