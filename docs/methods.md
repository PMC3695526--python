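# Methods

This note documents the models, assumptions, defaults and numerical choices
behind `sortmut`, in the order data flows through the package.

## Coordinates, labels and the mutation space

Internally all coordinates are 0-based, half-open intervals on the DNA
amplicon; sequences are stored as DNA (the sequencer reads DNA).  Biological
labels use the RNA alphabet and are anchored on the start codon: the A of
the AUG is +1, the base immediately 5′ of it is −1, and position 0 does not
exist.  `U-75A` therefore reads "reference U, 75 nt upstream of the AUG,
mutated to A".  The mapping between amplicon indices and AUG-relative
coordinates is a bijection, and label formatting/parsing are exact inverses
(property-tested over the full enumeration).

The single-substitution space of an *L*-nt amplicon has size 3*L*
(474 for the default 158-nt window).  Rows of every count matrix follow one
canonical order: position ascending, then alternative base in the fixed
order A<C<G<T with the reference base skipped.  The alternative-base order
is a package-wide convention chosen for reproducible row order; nothing
downstream depends on it.

The placement of the mutagenized core inside the analyzed window is
configuration; the default centres a 109-nt core in the 158-nt window, with
the start codon near the core's 3′ end so that upstream regulatory elements
fall at negative coordinates, as in a 5′-UTR screen.

## Design calculators

Two closed forms, plus seeded Monte-Carlo counterparts:

- **Read accuracy.** The probability that an *L*-nt read contains no
  base-call error at phred *q* is `(1 − 10^{−q/10})^L`.  At Q30 this is
  99.9% per base, ≈85.4% for a 158-nt read, and ≈60.6% for a 500-nt read —
  the reason amplicon length is the binding constraint for this method, not
  transformant numbers.
- **Library coverage.** Under i.i.d. uniform draws of *n* transformants
  from a mutation space of size *M* (3L singles; 9·C(L,2) doubles — a
  position holds one base, so a double mutant occupies two distinct
  positions), each mutant is hit Binomial(n, 1/M) times; the expected
  fraction covered ≥ *k* times is `1 − BinomCDF(k−1; n, 1/M)`.  The
  simulator draws actual pools and agrees with this marginal within
  Monte-Carlo error; full-coverage probability is additionally checked
  against the inclusion–exclusion coupon-collector formula at small *M*.

Uniformity of the mutational spectrum is an idealisation of "random
mutagenesis"; an optional per-mutation weight vector admits biased spectra
and is off by default.  For the canonical design point (L=109, n=3000,
k=5) the uniform model gives a mean coverage of ≈95%, and a full-coverage
(k=1) probability of ≈0.967.  Numbers near 99.5% for full coverage require
a different (unstated) draw model; we keep the uniform model and flag the
discrepancy rather than tune toward it.

## The synthetic experiment

The simulator emulates the whole screen so every downstream stage can be
tested against a truth table.  What it models, and what it deliberately
does not:

- **Library.** Clones carry 0–4 substitutions with a configurable
  mutation-count distribution (default `{0: .45, 1: .35, 2: .12, 3: .05,
  4: .03}`, matching the observed shape of error-prone-PCR libraries:
  mostly wild type, singles dominating the mutants, few clones with >3).
  Mutated positions are distinct within a clone and drawn with per-region
  mass 90% core / 10% primer flanks by default — flank mutations exist at
  low rate, which is what the region-detection statistics quantify.
- **Phenotype.** Log10 fluorescence
  `basal + Σ shift − rep·[srna]·Π(1−loss) + N(0, σ)` with defaults
  basal = 3.0, repression = 1.0 (10-fold), σ = 0.3.  Two effect axes per
  mutation: a constitutive `expression_shift` and a `regulation_loss`
  (fraction of sRNA repression abolished).  The default scenario plants
  regulation-loss mutations in a binding-site window (−79…−61),
  expression-raising mutations in a destabilizing window (−20…−13),
  expression-lowering ones at −8…−4, and strongly deleterious ones in the
  start codon.  Magnitudes are package defaults chosen to give a clearly
  bimodal sort, not measurements.
- **FACS.** Gaussian noise on the log scale approximates the log-normal
  shape of FACS distributions.  Default gates are the 5th-percentile bounds
  of the wild-type control laws (high: above the unrepressed wild-type p05;
  low: below the repressed wild-type p95), computed analytically from the
  model — equal in distribution to drawing gates on simulated wild-type
  histograms but byte-deterministic.  Sorting subsamples each gate without
  replacement to the target pool size.
- **Sequencing.** One read pair per pooled cell; read 1 is the amplicon 5′
  prefix, read 2 the reverse complement of the 3′ suffix (primer-anchored
  amplicon sequencing).  Substitution errors flip a base to a uniform other
  base at the per-cycle rate `10^{−q/10}`; an optional per-fragment indel
  rate (one-base insertion or deletion) exercises the exact-length filter.
  Not modelled: PCR amplification bias and jackpots, plasmid copy number,
  quality-score degradation along the read (the default profile is flat
  Q30), adapter read-through.

Consequently, passing end-to-end tests demonstrates the pipeline's
correctness and statistical calibration under idealised error and sampling
models; it does not certify performance under PCR jackpots, biased spectra
or degraded quality tails.

All randomness descends from one integer seed through
`numpy.random.SeedSequence.spawn`; identical seeds give byte-identical
FASTQ/TSV outputs (gzip members are written with a fixed timestamp).

## Read processing

- **Trimming.** 3′ quality trimming by the running-sum rule: remove the
  suffix maximising `Σ (q_threshold − q_i)` over removed bases, ties going
  to the shortest removal.  Default threshold Q30 on phred+33 scores.  Note
  the rule may reach past an isolated good base inside a bad tail.
- **Merging.** Exhaustive ungapped overlap scan (the amplicon design
  guarantees collinearity, so no gapped alignment).  Among overlaps
  ≥ `min_overlap` (default 30) the one with the smallest mismatch fraction
  wins, ties to the longer overlap.  A best candidate worse than a 25%
  mismatch fraction is indistinguishable from random sequence and is
  reported as `no_overlap`; a detected overlap above
  `max_mismatch_fraction` (default 0.02) is `too_many_mismatches`.  At the
  default geometry (100+100 reads, 158-nt amplicon, 42-nt overlap) the 2%
  cap rejects any pair with even one overlap mismatch — a deliberate strict
  default that trades ~0.1 of depth for cleaner overlap resolution.
  Within the overlap, disagreements resolve toward the higher-quality base
  (ties to read 1) and the merged quality is the per-position maximum.
- **Length filter.** Only merged reads exactly matching the reference
  length survive; this removes every indel-bearing fragment by
  construction, along with mis-merges.  Reads containing N after merging
  are dropped and tallied.

Sequencing-error-induced false single mutations are *not* corrected; depth
keeps the per-mutation signal above this uniform error floor, whose expected
size follows from the read-accuracy closed form and is surfaced in QC.

## Counting and region statistics

Mutation calling is a position-wise comparison of exact-length reads to the
reference.  Reads with exactly one substitution populate the count matrix;
multi-mutation reads can be tallied into an auxiliary genotype table
(for future double-mutant analyses) but never enter any statistic.

Region-detection definitions (the terms are used loosely in the field, so
ours are explicit): per sample, **sensitivity** is the fraction of the
3·|core| target substitutions observed at least once, and **specificity**
is the fraction of single-mutation reads whose mutation lies inside the
core.  Cumulative distributions of per-mutation fractions are emitted for
the core and flank subgroups separately.

## Enrichment statistics

Size factors, dispersions and the conditioned exact test are described in
the README; numerical details:

- Dispersion method of moments uses the within-condition pooled variance
  (ddof 1 per condition) so genuine between-condition signal does not
  inflate dispersion.  The mean–variance trend is a lowess fit (frac 0.4)
  of log pooled variance against log mean, corrected for the chi-square
  log bias `ψ(ν/2) − log(ν/2)` before back-transforming (without this the
  trend underestimates variances by ~25% at ν = 4 and the test becomes
  anticonservative in the far tail).  The working dispersion is
  `max(raw, trend, 10⁻⁸)` — the conservative sharing choice, appropriate
  for 3 replicates.  Equal-replicate rows clamp to the floor; all-zero rows
  are excluded from testing.
- The exact test compares partition log-likelihoods with a relative slack
  of 1e−7 so floating-point rounding cannot split ties; when the assembled
  variance does not exceed the mean the NB law degenerates to Poisson.
  With dispersion → 0 and equal size factors the test reproduces the
  two-sided exact binomial test on the condition split (verified
  exhaustively for totals ≤ 200).
- Calibration, measured by the suite: on null NB triplicate-vs-triplicate
  matrices with row means log-uniform on [100, 3000] (the per-mutation
  depth regime of a deeply sequenced screen) and dispersion 0.05, the
  type-I error at nominal 0.05 is ≈0.035; in balanced spiked matrices BH
  keeps the realised FDR at ≈0.04.  At much lower depth (row means down to
  ~20) the max-sharing rule makes the test conservative (type-I ≈0.027) —
  the intended failure direction.
- The baseline pool is an explicit argument (all-sorted or unsorted both
  make sense and both are exercised in tests); there is no hard-wired
  default contrast.

## Clustering diagnostics

Mutation fractions (columns summing to 1) are row-standardized to zero mean
and unit *population* SD (constant rows → zeros), matching the per-row
colour scaling of a heatmap.  Samples are clustered agglomeratively on
Euclidean distances with complete linkage by default (both exposed); the
routine is written out so tie-breaking is contractual — closest pair first,
exact ties resolved toward the lowest column indices — and it matches
scipy's linkage on generic inputs (tested).  The dendrogram exports to
Newick with branch lengths derived from merge heights.

**Replicate concordance** is the fraction of (plasmid, gate) groups whose
replicates form their own clade (singleton groups count as concordant).
Note conditions with genuinely identical composition — an all-sorted gate
vs unsorted cells — differ only by sampling noise, so their replicates can
legitimately interleave; the default scenario's score of 0.8 across five
conditions reflects exactly this, not a pipeline defect.

## Degenerate inputs and edge cases

Zero-total sample columns are excluded from fraction tables with a warning;
empty FACS gates yield empty pools with a warning; a count matrix with no
all-positive row falls back to column-total normalization (warned).  Reads
shorter than the minimum overlap cannot merge (`no_overlap`).  Labels with
a wrong reference base raise errors naming the offending position.

## Problem sizes used by the test suite

The default-scenario fixture simulates a 10 000-clone library, 250 000
cells per replicate culture, and 15 samples of 20–40k read pairs
(five conditions × three replicates); statistical-calibration tests use
five (type I) and six (FDR) independent 474-row matrices.  These sizes give
the suite per-mutation depths and replicate structure comparable to a real
screen while keeping a full run around a minute.
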