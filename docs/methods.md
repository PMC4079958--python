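# Methods

## Evidence extraction and the VARW statistic

Every insertion/deletion CIGAR element of every mapped read becomes one
*observation*: a signed width (+k insertion, −k deletion) anchored at the
0-based reference position immediately left of the event after left
alignment. Left alignment slides a gap or insert to its leftmost equivalent
placement within a repeat, so all reads reporting the same biological event
share one anchor regardless of where the aligner placed the gap. Soft-clipped
bases contribute neither observations nor aligned span; depth at a locus is
the count of reads whose aligned span covers the anchor base
(deletion-spanning reads count, matching pileup-style DP).

**VARW** is the *population* variance of the signed widths of the
observations sharing the call's anchor. Three properties motivate the
definition:

* `VARW = 0` exactly when every supporting read reports the same single
  event — the profile of a real indel — so a threshold of 0 is satisfiable;
* signing the widths makes mixed insertion/deletion evidence at one locus
  (the classic two-sided homopolymer slippage pattern) register as large
  variance even when each side is internally consistent;
* an empty observation set leaves VARW *undefined*, which is distinct from
  0: a called indel with zero read-level gap evidence fails the VARW filter
  rather than trivially passing it.

Only observations at the exact anchor are pooled by default; a ±W bp window
is available (`window` argument / `--window`) for callers that anchor
inconsistently, in which case VARW is computed over the pooled widths.

**BAF** is the fraction of spanning reads contributing at least one
observation at the anchor; **HRun** is the length of the maximal reference
run starting at the base right of the anchor (≥ 1 by construction; for a
left-aligned insertion extending a run this is the run it extends).
**MAPQ profile** (median/quartiles over spanning reads) is exposed for
diagnosing loci where mis-mapping rather than miscalling drives evidence.

## Filtering

`PASS ⇔ QD ≥ QD_th ∧ VARW ≤ VARW_th`, boundaries inclusive. Inclusivity is
required for `VARW_th = 0` to be meaningful, and symmetric treatment of the
QD boundary keeps the rule simple. When both statistics fail, the recorded
status is `fail_qd` (one status per record; the VCF FILTER column carries
the same value). Depth for QD is taken from the VCF record when present,
otherwise recomputed from alignments; the source is recorded in `DPSRC`.
Multi-allelic records are split before annotation, and all calls are
normalized (left-aligned, minimal, single anchor base) on input.

Thresholds are profile-scoped, never global: QUAL scales differ between
callers, so a QD cut tuned for one caller is meaningless for another.
The `gatk` (2.5 / 0) and `samtools` (1 / 0) profiles carry values
established for those callers on PGM amplicon data. The `naive` profile
(3 / 0.5) was derived from the distributions the bundled stack produces,
the same procedure one would apply to any new caller:

* the naive caller's QUAL is a binomial tail against a 1% artifact rate, so
  a heterozygous indel (~50% support) scores QD ≳ 5 while homopolymer
  artifacts (support bounded by the miscall ceiling, ≲ 20–30%) stay below
  ~2.2; 3 splits the gap;
* at a true locus, a handful of discordant-width reads (boundary effects,
  stray miscalls at the same anchor) induce VARW ≈ 4/n for n supporting
  observations (≤ ~0.4 at realistic depth), while mixed-direction artifacts
  produce VARW ≈ 4·b·(1−b) ≈ 0.84 at deletion bias b = 0.7; 0.5 splits that
  gap.

**Cross-sample recurrence.** A PASS call in sample *s* is demoted to
`fail_recurrent` iff its exact identity key `(chrom, pos, ref, alt)` appears
in the threshold-failed set of at least one *other* sample. Exact-allele
matching was chosen over position-only matching: it is the conservative
reading (position-only would demote more aggressively), and normalization
makes allele identity well-defined. The sample's own failed set never
demotes its calls.

## Per-base evaluation

Each indel event — true or called — occupies exactly one base at its
left-aligned anchor, regardless of event span; with N samples over B
callable bases, `TN = N·B − TP − FP − FN`. The one-base convention is the
only one under which published per-workflow confusion rows (6 × 16,023 =
96,138 and 17 × 16,023 = 272,391 bases) sum correctly with multi-base truth
events, and it keeps specificity comparable across event-length mixes.
Matching is exact on the normalized identity key; a call at a truth anchor
with a different allele counts as one FP plus one FN (no partial credit).

Confidence intervals are Clopper–Pearson (exact beta quantiles) by default,
with Wilson available via `method=`. Published tables in this field print
95% CIs whose generating method is often unstated and not reproducible from
the counts; the package therefore treats CI values as method-dependent
output, not as comparable constants.

Percentages display with half-up rounding at two decimals, trailing zeros
trimmed. One deliberate display rule: a proportion strictly below 1 never
shows as 100% — where rounding would reach 100 it is floored (96,134/96,135
→ 99.99%) — reserving "100%" for literally error-free counts, as clinical
validation tables do.

False positives are stratified by HRun at a default threshold of 4: runs of
4+ are where flow-signal ambiguity becomes substantial, and the boundary
sits inside the gap between the planted-variant contexts (HRun 1) and the
artifact-prone runs (6+) so the qualitative conclusion is insensitive to
the exact cut.

## Simulator

The generator emulates amplicon resequencing of a diploid sample on a
flow-based instrument. What it models:

* **Reference** — built run by run: run lengths i.i.d. from a configurable
  distribution, each run's base different from its predecessor. The default
  composition (68% 1-mers down to 0.5% 8-mers, mean run 1.64 b) is
  homopolymer-rich enough that length-miscall artifacts arise at callable
  rates in a 20 kb target, while keeping two-thirds of the sequence
  non-repetitive.
* **Variants** — heterozygous 1-bp deletions by default (the dominant class
  of short coding indels), planted at uniformly chosen sites whose local
  context is non-repetitive (anchor, deleted base and right flank mutually
  distinct), ≥ 300 bp apart and ≥ 200 bp from the ends. Insertions, longer
  events and homozygous planting are available by flag. Truth records are
  emitted normalized.
* **Reads** — uniform fragments of both haplotypes at the target mean
  depth, emitted *pre-aligned*: placement is known by construction and both
  planted indels and injected errors are expressed in the CIGAR, so no
  external mapper is needed (a FASTQ export exists for users who want one).
  Each maximal run of length L inside a read is miscalled to L±1 with
  probability `p(L) = min(p0·L^γ, pmax)`, shortened with probability
  `indel_bias`. Defaults: p0 = 0.002, γ = 2, pmax = 0.3, bias = 0.7
  (undercalls dominate on real flow instruments). The power law captures
  the qualitative rise of error rate with run length; it is not calibrated
  to any particular chemistry, and the parameters are exposed for users who
  have instrument-specific estimates. Miscalls are limited to ±1 per run
  per read, the dominant mode of one-unit flow-signal ambiguity.
* **Naive caller** — emits a call wherever the modal gap width is supported
  by ≥ 2 reads and ≥ 15% of spanning reads, with QUAL the Phred-scaled
  binomial tail probability of that support under a 1% per-read artifact
  rate, capped at 3000. It exists so the filter stack is testable
  standalone; it is not a production caller.

All randomness flows from one integer seed per call (child seeds derived
via `numpy.random.SeedSequence`); identical seeds give byte-identical
FASTA/SAM/VCF outputs. The default seed is 20140624.

What the simulator does **not** model — and hence what passing tests do not
demonstrate about real data: flow-space signal values (FZ tags), PCR and
amplicon coverage bias, base-quality profiles, mapping ambiguity (all reads
are emitted at their true location with MAPQ 60, so the MAPQ diagnostics are
exercised only by hand-built fixtures), strand structure, multi-contig
references, and miscalls of more than one unit. Real QUAL scales are
caller-specific where the naive caller's is binomial by construction, so
the bundled `naive` thresholds do not transfer to real callers — the
published `gatk`/`samtools` profiles or a fresh calibration do.

## Study problem sizes

The default recovery experiment (tests and `scripts/acceptance.py`) uses
five replicate samples, each a fresh 20 kb reference at 100× coverage with
5 planted indels — 25 truth events and ~98,000 callable bases pooled, about
a hundred thousand simulated reads in total. These sizes give clean
separation statistics (every replicate recovers 5/5 planted indels; pooled
pre-filter FDR is typically 10–30% and post-filter 0%) while a full run
completes in well under a minute.

## Numerical and degenerate-input conventions

* VARW uses population (not sample) variance; a single observation gives 0.
* Median/quartiles use numpy's linear interpolation; even counts take the
  mean of the two central values.
* Metrics with empty denominators are reported NA, never 0, and serialize
  as JSON null.
* Modal-width ties in the naive caller break toward the narrower event,
  deletions first, for determinism.
* Indels that left-align across the contig start (no anchor base) raise
  bounds errors rather than being silently re-anchored.
* The binomial QUAL computation uses `binom.logsf` to avoid underflow; an
  infinite tail maps to the QUAL cap.
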