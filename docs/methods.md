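# Methods

This note documents the models, conventions, numerical choices and
limitations behind `clonediv`, in the order the pipeline runs.

## Clone and subclone model

Reads (or collapse units with `duplicate_count`) are grouped by IGHV gene,
IGHJ gene and CDR3 nucleotide junction.  The group with the largest summed
read count is the pathological clone; if no annotated group exists the
sample is reported as "no prevalent clone".  Junction matching is exact by
default; a similarity mode (same length, ≥ 85% identity by default) exists
because heavily diversified clones can carry CDR3 point mutations.  Ties
between equally abundant groups are broken lexicographically on
(v_call, CDR3) and logged — ties are a measure-zero event on real data but
must be deterministic on synthetic data.

Within the clone, identical sequences are collapsed; a subclone is any
retained sequence, and diversification evidence is any retained non-major
sequence (which by construction differs from the major by ≥ 1 nt).  Two
gates protect the diversity statistic:

* `min_subclone_freq` = 0.001 — sequences below 0.1% of the clone's reads
  are removed.  Frequencies are then **renormalized over the retained
  reads** so they form a proper probability vector; the alternative
  (keeping the pre-filter denominator) makes the Hill number of the
  retained spectrum improper.  With renormalization the canonical
  9000/900/90 example gives iSI = 1.2198 rather than the 1.2222 obtained
  with the 10,000-read denominator; the difference is below the
  classification granularity.
* `min_clone_reads` = 5000 — below this depth a 0.1% subclone has fewer
  than 5 supporting reads and the iSI is dominated by shot noise, so the
  sample is marked non-evaluable rather than scored.

Reads containing N are assigned to a retained subclone only when their
non-N positions match exactly one candidate; otherwise they are dropped and
recorded in the audit trail.  Every filter decision is appended to
`CloneProfile.filters` as (name, reads removed), and read conservation
(`clone_reads = retained + removed`) is asserted in tests.

Internal coordinates are 0-based half-open everywhere; AIRR columns that
are 1-based on disk are converted at the IO boundary.

## IGHV mutational status

Identity is computed column-wise over the germline window (N positions
skipped).  A case is unmutated (U) when the mutational load,
100 − identity%, is ≤ 2.0; mutated (M) above that.  The boundary case
(exactly 98% identity) is U.

## Systematic-error model

Amplicon protocols on short-read sequencers produce recurrent artifacts
conditioned on the local template sequence: the same flanking context is
miscalled to the same alternative base across unrelated samples, at low
frequency and reduced Phred quality.  The correction implemented here is
intent-level, with every threshold exposed:

* context width k = 5 (the miscalled base ± 2), taken from the
  major-subclone sequence;
* a (context, alt) pair is blacklisted when observed in ≥ `min_recurrence`
  = 5 distinct clones as a variant of frequency < `systematic_max_freq` =
  2% with mean Phred < `quality_floor` = 20;
* correction reverts blacklisted variants — or variants supported only by
  sub-floor quality — to the major base and re-merges the corrected
  sequence into whichever subclone it now matches, conserving reads.

Only subclones below `systematic_max_freq` are ever edited, so a genuine
subclone at ≥ 2% can never be merged away regardless of blacklist
contents.  Correction runs **before** the 0.1% gate so rescued reads
re-join real subclones instead of being silently filtered.  Both the
context-recurrence and the quality signal are combined because the exact
position-vs-context definition used by the original protocol is not
public.

## UMI cross-validation path

The UMI layout is three fixed-length random blocks interleaved with 3-nt
constant spacers (both configurable); extraction validates the spacers,
concatenates the random blocks, and audits non-matching reads.  UMIs
within Hamming distance 1 of a larger group are absorbed (UMI bases err
too); groups with < 3 reads are dropped; each surviving group is collapsed
by per-position majority vote with ties resolved to the reference base
when given, else alphabetically.  Consensus molecules then flow through
the same clone/correction/diversity machinery with `min_clone_reads`
relaxed (molecule counts are two orders of magnitude below read counts).

## Diversity

`hill_number(p, q)` implements (Σ pᵢ^q)^{1/(1−q)} with the analytic limits
at q = 0 (richness) and q = 1 (exp Shannon); inputs must be positive and
sum to 1 within 1e-9.  The inverse Simpson index is the q = 2 value and is
checked against brute-force 1/Σp² to 1e-12.  The default profile grid is
q ∈ [0, 4] step 0.1.  Classification uses iSI ≥ 1.2 → ID_high; the
boundary is counted high because the headline definition is "iSI ≥ 1.2",
and a `boundary="gt"` flag covers the alternative reading.  1.2 is the
rounded form of a maximally-selected-log-rank optimum (1.23) and is kept
as the configurable default.

## AID signatures

Motif classes are determined from germline context only: a C is a
WRC hotspot when preceded by W,R (W = A/T, R = A/G) and an SYC coldspot
when preceded by S,Y (S = G/C, Y = C/T); a G is the reverse-strand
GYW hotspot when followed by Y,W and a GRS coldspot when followed by R,S.
Hotspot takes precedence over coldspot; for these alphabets the overlap is
provably empty (W∩S = ∅, R∩Y = ∅) and a unit test documents that.
Context running off the window edge classifies as "other".

Mutability per class = (distinct mutated germline positions of that class)
/ (germline positions of that class); a class with zero opportunities
reports an undefined rate rather than 0.  Replacement/silent calls
translate the germline and mutated codon under the standard genetic code
(stop = replacement); codons truncated by the analysis window leave the
call unclassifiable and excluded from R/S densities.  Sharing classes:
present in all retained subclones = shared (trivially true for a
single-subclone profile), in ≥ 2 but not all = partially shared, in one =
unique; the non-shared scope restricts summaries to the
post-transformation signal.  R/S densities per FR/CDR region are mutations
per nucleotide, weighted by subclone frequency by default (a flat mode
exists) so rare subclones do not dominate.

## Lineage trees

The tree is the minimum-spanning arborescence of subclone sequences plus
the germline under Hamming distance, grown by Prim's construction from the
root (germline by default, major subclone optionally) with deterministic
tie-breaks: distance, then parent attachment order, then child abundance
descending, then sequence.  This is a descriptive reconstruction — the
package does not rank trees by likelihood or search maximum parsimony; the
MST is reproducible and sufficient for the node taxonomy (root / leaf /
split / pass-through) and the complexity metrics (node counts, depth,
total nucleotide branch length) used to corroborate iSI.  Edges longer
than 1 nt can optionally be subdivided by inferred single-mutation
intermediates with zero abundance.

## Survival

Kaplan–Meier estimation and the two-group log-rank test delegate to
lifelines.  The maximally selected log-rank scan computes the standardized
statistic (O − E)/√V (hypergeometric variance, ties pooled) at every
distinct marker value whose low/high split stays inside the quantile
window (default 10%–90%), reports the maximizing split as the midpoint to
the next distinct value, and adjusts the p-value with the Miller–Siegmund
approximation P(max|Z| > b) ≈ 4φ(b)/b + φ(b)(b − 1/b)·log[ε₂(1−ε₁)/(ε₁(1−ε₂))],
clipped to [min-unadjusted-p, 1] so the adjustment is never
anti-conservative.  In simulation this is slightly conservative (null
rejection ≈ 5% at α = 0.05 with n = 60) and recovers a planted lattice
threshold essentially always at hazard ratio 5, n = 200.

## Synthetic data

The simulator emulates the structure of a diagnostic IGHV amplicon
experiment, not clonal evolution dynamics:

* **Template**: a packaged synthetic 300-nt IGHV-like sequence generated
  once from a fixed seed (no third-party reference data is redistributed),
  with FR1/CDR1/FR2/CDR2/FR3 delimitation and a realistic density of
  hotspot/coldspot motifs; any user FASTA can substitute.
* **Clone**: the major sequence carries a clonal mutation load (default 5%
  of positions, i.e. an M case) placed with AID-hotspot bias (default 5×
  relative rate in WRC/GYW contexts); each further subclone adds 1–3 extra
  hotspot-biased mutations.  Subclone frequencies come from a Dirichlet
  (default), stick-breaking, or explicit model.
* **Reads**: multinomial over subclones at depth 15,000 (the scale of
  routine diagnostic repertoires; evaluable cohorts run ~5,000–70,000),
  random per-base errors at 10⁻³ at baseline quality Q35, and systematic
  context errors (default: three template-derived 5-mer contexts at 1.2%
  per read) written at Q12 — matching the detection assumptions above.
  Errors are confined to the V window; the appended junction is error-free
  so clone grouping is unambiguous, which means junction-error robustness
  is *not* exercised by these tests.
* **Survival cohorts**: four IGHV-status × ID-class strata with
  exponential TTFT (monthly hazards 0.0057 / 0.002 / 0.022 / 0.0136 for
  M-ID_low / M-ID_high / U-ID_low / U-ID_high, i.e. medians of roughly
  120 / 350 / 31 / 51 months), uniform censoring on [0, 180] months, and
  iSI values drawn below or above 1.2 per class.

Everything is deterministic given the seed.  What passing tests show is
that the measurement pipeline recovers planted compositions, signatures
and thresholds under this generative model; real data add features the
generator omits — indels, chimeras, primer bias, truncated FR1 coverage,
biclonal samples — which the pipeline either audits out (indel-bearing
reads never match the germline-aligned window) or does not address.

## Problem sizes in tests and the acceptance script

The acceptance checks run at sizes chosen to make their statistical
assertions stable: 100-sample cohorts at full depth for correction
efficacy and ID recovery, 50 samples for UMI concordance (500 molecules,
~4 reads each), 1000/500/200 replicates for log-rank calibration, maxstat
null and cutpoint recovery, and 100 samples for signature recovery.
`scripts/acceptance.py` reports the same quantities from 25–60-sample
cohorts and a 500-patient survival cohort, each regenerated from the
given seed.

## Known limitations

* Substitution-only: indels inside the clone are not modeled or corrected.
* Only the top clone is profiled; biclonal samples need two passes.
* The minimal annotator is identity-based and single-reference in the
  default pipeline; production inputs are expected pre-annotated.
* Mutability rates are per-motif-opportunity counts, not a phylogeny-aware
  substitution model; per-mutation fractions can be derived from the same
  summary.
* The maxstat approximation is asymptotic; for very small cohorts a
  permutation p-value would be preferable.
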