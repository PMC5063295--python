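# Methods

## SSR model

A locus is a *maximal perfect tandem repeat*: a primitive unit of 2–6 bp
repeated without interruption, not extendable by one more phase base on
either side, with only whole units counted (a partial trailing unit extends
neither the span nor the repeat count). Coordinates are 1-based inclusive.
Runs are broken at `N`. Because a flanking base can happen to extend an
embedded tract, the maximal run may be phase-shifted relative to the
inserted motif; it then covers the tract except for up to `unit−1` bases at
one end, which is why truth-recovery checks compare canonical motif classes
and coverage rather than exact spans.

Detection thresholds (`SSRCriteria`): ≥6 reiterations for dinucleotides and
≥5 for tri–hexa (the standard genic-SSR survey criteria); mononucleotides
are never scanned by default, though the criteria object accepts unit size
1 for generality. When maximal runs of distinct motifs overlap, the longer
wins; ties go to the leftmost start, then the smaller (primitive) unit.
Filtering drops mononucleotide, compound (another locus within
`compound_max_gap_bp`, default 100 bp — configurable because only the
exclusion, not the gap, is a fixed convention) and <10 bp loci; compound
flags are transitive along chains. Type I = tract ≥ 20 bp.

Canonical motif = lexicographic minimum over all cyclic rotations of the
motif and of its reverse complement. Exhaustively this yields 4 classes for
dinucleotides and 10 for trinucleotides.

## Primer design

All hard constraints are enforced during enumeration: primer length 20–25,
product 100–250 bp with the forward 3′ end strictly upstream and the
reverse 3′ end strictly downstream of the tract, GC 40–60 %, and a 3′
clamp: the run of identical G's or C's ending at the terminal base must be
≤ 1. The clamp reading ("no homopolymeric G/C run longer than one at the
terminus") is the weaker of two plausible interpretations of the
single-consecutive-G/C rule; the stricter alternative (≤1 G or C among the
terminal bases in total) would also reject e.g. `…GC`, and was not adopted.

Tm uses the long-oligo approximation `81.5 + 0.41·GC% − 675/N`, valid for
the 20–25-mer range and undefined below 14 nt (the function refuses shorter
input). The selection score,

    |Tm_f − 65| + |Tm_r − 65| + |Tm_f − Tm_r| + (|GC_f − 50| + |GC_r − 50|)/10,

prioritises the annealing target and inter-primer balance, with GC
deviation a tie-breaker at one-tenth weight; remaining ties resolve by
smaller forward start, then smaller product, then shorter primers, making
the design deterministic. No thermodynamic nearest-neighbour model,
hairpin or dimer screening is attempted.

## Pileup and SNP calling

Alignments are consumed from SAM (only flag 0x4 and CIGAR ops `M,=,X,I,D,S`
are interpreted; `N/H/P` records are skipped and counted). Each variety's
base counts and quality sums are accumulated into per-transcript
`(length × 4)` matrices via vectorised scatter-adds, which keeps
30×-coverage three-variety runs with millions of reads tractable on one
core. `N` read bases are ignored and counted.

Filters (defaults): pooled depth ≥ 10 — pooled, not per-variety, because
the tagged reads of all three varieties are aligned as one pool; mean base
quality ≥ 25 computed over **all** piled bases at the position (not
alt-only); an allele is *supported* iff ≥ 2 reads carry it within at least
one variety. A site is emitted iff exactly two alleles are supported and at
least one differs from the reference base. Sub-threshold alleles are noise;
three supported alleles drop the site as multi-allelic. When the reference
base itself is unsupported the two supported alleles are reported in
lexicographic order with the original reference base kept in a separate
column. Indels never nominate alleles. Every drop reason is counted so the
raw-candidate → filtered-site funnel is inspectable.

Raising any of the three thresholds can only shrink the emitted set
(monotonicity, property-tested).

## Trio classification

Zygosity per variety depends only on the two allele depths and the support
threshold: HT if both ≥ 2, HM if exactly one, else NOCALL. Sites with any
NOCALL are excluded from the eight-class table (they are not informative in
all three genotypes); exclusions are counted, never imputed. Apparent
heterozygosity loss driven by shallow hybrid coverage (class 5) is reported
as observed, not corrected. Summary identities: HT_hybrid = c1+c2+c3+c4 =
novel + maintained; lost + c6 = total − HT_hybrid. Reported percentages are
printed at 2 dp; comparisons against published values round to the
precision those values carry (1 or 2 dp).

## Simulator

The simulator emulates the data-generating situation the analysis assumes —
a non-redundant transcript reference, two parents and their F1, uniform
coverage — not a full RNA-seq platform model (no expression-level
variation, indels, splice forms or position-dependent error profiles; both
sequencing chemistries a real study mixes are abstracted to uniform
substitution errors at constant quality).

* **Reference**: i.i.d. A/C/G/T transcripts, lengths uniform in
  `length_range` (default 400–1500 bp). With probability
  `ssr_per_transcript_prob` one perfect SSR is embedded: unit size uniform
  in 2–6, primitive motif uniform, reiterations uniform from the detection
  threshold to threshold+6 so tract lengths straddle the 20 bp Type-I
  boundary, position uniform with ≥60 bp flanks (enough for primer
  windows). Config validation rejects transcripts too short to host this.
* **Sites**: placed on a grid of slots spaced exactly `read_len` apart and
  ≥ `read_len` from the ends, sampled without replacement — a deterministic
  way to guarantee each read overlaps at most one site, keeping the
  caller/pileup interaction analyzable; capacity errors are exact.
* **Genotypes (direct mode)**: class drawn from `class_proportions`
  (default: the published trio's observed distribution over 22,306 sites);
  HT genotypes are ref/alt, HM genotypes drawn ref-ref or alt-alt
  uniformly. Class 1 forces contrasting homozygous parents (that is what
  novel heterozygosity means); class 6 is restricted to all-homozygous
  patterns in which *both* alleles occur within the trio, since a site
  monomorphic across the trio cannot be observed by a biallelic
  two-supported-allele caller and would silently break truth recovery.
* **Genotypes (mendelian mode)**: parental alleles i.i.d. at frequency 1/2,
  hybrid takes one allele from each parent; sites with no alternate allele
  anywhere are redrawn; the implied class is recorded. The hybrid never
  carries an allele absent from both parents (invariant-tested).
* **Reads**: per variety and transcript, `round(coverage·L/read_len)`
  reads at uniform starts; read *i* copies haplotype *i* mod 2 (HT phasing
  randomised per site); substitution errors i.i.d. at `error_rate` to a
  uniform different base; constant quality `base_quality`. Defaults pair
  Q30 with a coherent 10⁻³ error rate; the average-quality filter is
  exercised by configs setting quality below/above 25. Truth alignments
  are all-match CIGAR at the true origin.

All randomness derives from one seed via per-stage child generators;
identical configs give byte-identical outputs.

## What passing tests show — and what they do not

Error-free 30× runs recover every truth site with its true class and emit
zero false positives; this validates the bookkeeping (CIGAR walk, tallies,
thresholds, classification), not the filters' real-world operating
characteristics. At a 1 % error rate and 30× depth, the min-2-reads support
rule alone admits error-driven sites at a per-position rate of roughly
C(30,2)·(e/3)² per variety and non-ref base — visible in any run as extra
called sites — so class-recovery checks are computed over truth-matched
positions, and real studies additionally rely on allele-frequency filters
this package deliberately does not add. Published whole-dataset counts
(tens of thousands of SSRs/SNPs from ~10⁸ reads) depend on the real reads
and assembly and are outside what simulation can or should reproduce; the
arithmetic that derives summaries from such counts is reproduced exactly.

## Problem sizes

Recovery checks use 10,000 sites (tests) / 5,000 sites (acceptance script)
on 400 bp transcripts with 50 bp reads — seven grid slots per transcript,
~1,400 transcripts, ~10⁶ reads per run at 30× across three varieties —
sizes chosen so a full run completes in tens of seconds on one core while
leaving per-class binomial standard errors small enough for 3–4 SE bounds
to be meaningful.
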