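# Methods

## The analysis model

A stably transformed plant carries one or more T-DNA insertions: at each
locus the host sequence may lose bases (a deletion spanning the insertion
point), gain short novel "filler" bases on either side of the cassette, and
receive a cassette segment that is complete (right border to left border),
partial, or rearranged (discordant junction orientations). Separately, the
expressed nuclease cuts its target sites — and, through paralogous
near-matches, sometimes additional sites — leaving small indels whose read
proportions reflect the plant's somatic chimerism and zygosity. The package
treats both event classes as string-rewriting operations on a reference
genome and recovers their parameters from short-read alignments.

Three read signatures carry all the information used:

1. a pair with exactly one cassette-mapped mate marks a fragment straddling
   a junction; the host placement of the other (orphan) mate localizes the
   insertion to within roughly a fragment length;
2. a read crossing a junction aligns to the host with a soft-clipped tail
   whose bases are insert-side sequence; the clip boundary is the host
   breakpoint;
3. a read spanning a target-site window carries its allele in its CIGAR.

## Stage conventions and parameters

**Trimming** (defaults: min length 40 bp, quality cutoff Q20, exact-prefix
adapter match with ≥ 8 bp overlap) uses the standard running-sum 3′ quality
rule; a read falling below the length floor is dropped and its mate kept as
an orphan single.

**Alignment.** The internal aligner indexes exact 15-mers, chains seed hits
on diagonals (band 100), and extends with affine-gap Smith–Waterman
(match +1, mismatch −6, gap open −5, extend −2; the mismatch penalty
mirrors the value commonly used when mapping such data). A placement is
reported with ≥ 2 chained seeds or an extension score ≥ 40. Ties break
deterministically (reference name, coordinate, then forward strand); equal
scoring placements are emitted as secondary records. The DP kernel is
numba-compiled; a full-length exact-match shortcut handles the bulk of
error-free reads. The aligner is a contract-level stand-in adequate for
low-divergence synthetic data, not a replica of a production mapper;
its score and alignment interval are property-tested against an
independent quadratic dynamic-programming oracle. Coordinates are 0-based
half-open internally and 1-based in SAM and human-facing reports.

**Locus detection.** Orphan placements are single-linkage clustered with
window = fragment mean + 3 SD (580 bp at the defaults); a locus needs
min_support = 2 orphan mates. Two suffices because contamination-derived
orphans rarely co-locate, while a real junction at 20× yields ten or more.

**Presence calling.** Coverage is computed over unmasked cassette positions
only: backbone flanks (border-to-border transfer means backbone coverage is
not expected) and host-homologous components such as a native-promoter
segment (whose reads cannot distinguish transgene from genome) are
excluded. Verdicts: *integrated* if breadth ≥ 0.5 and mean ≥ 0.2× the
genome depth; *trace* if any unmasked reads mapped but thresholds are not
met — the handful-of-reads signature of cross-contamination between
barcoded libraries; *absent* otherwise. The two thresholds are this
package's own declared defaults; the distinction they encode ("consistent
coverage" versus a few stray reads) is qualitative in the source material.

**Junction resolution.** Clipped reads (clip ≥ 10 bp, boundary within the
locus interval ± 50 bp) are deduplicated, the modal clip boundary fixes the
host breakpoint per side, and a per-column majority vote (≥ 0.7 within
30 bp of the breakpoint, ≥ 2 reads) builds the insert-side consensus. The
longest consensus suffix (left side; prefix on the right) occurring in the
cassette on either strand — found by binary search, since occurrence is
monotone in length — anchors the cassette breakpoint and orientation with a
minimum anchor of 12 bp; the unmatched remainder is filler. The deletion is
the gap between the two host breakpoints, clamped at zero: breakpoint bases
shared by host and cassette (microhomology) are assigned to the host side
with leftmost placement, a stated convention required because single
coordinates are reported despite the inherent ambiguity. Completeness
requires both cassette breakpoints within ± 5 bp of the border component
boundaries. One resolvable junction yields a *partial* record with the
other side unresolved; none yields *unresolved*; discordant orientations
yield *rearranged*, which is labeled, not reconstructed — multi-kilobase
concatemer assembly is out of scope.

**Microhomology.** For each resolved junction the caller takes 30 bp of
host flank per side of the breakpoint and 30 bp of junction-adjacent
cassette terminus, and exhaustively enumerates exact common substrings of
length ≥ 2 whose offsets from the respective breakpoints are ≤ 10 bp, on
both cassette strands (N never matches). The longest tract wins; ties break
to the smallest host/cassette offset difference, then leftmost host offset,
then forward strand. The search bounds are this package's defaults — short
windows are what junction diagrams of this kind show — and the whole
routine is property-tested against an all-substring-pairs oracle.

**Edit profiling.** The scanner reports protospacer+NGG matches with ≤ 2
mismatches on both strands; the cut is modeled blunt between bases 3 and 4
upstream of the PAM (SpCas9), and mismatches are reported as distances from
the PAM with the proximal base = 1. Allele counting uses reads whose
aligned span covers the cut ± 20 bp in full — partial overlaps are excluded
to prevent length misclassification — and assigns the net in-window indel;
substitution-only reads count as wild type, since only indel alleles are
tracked. Reads clipped ≥ 10 bp with the boundary inside the window, and
whose clipped bases seed onto the cassette, form a distinct TGI allele
(transgene integration at the target site) rather than coverage dropout.
Alleles under 2 reads merge into "other". Frameshift/in-frame classes come
from net length mod 3.

**Genotyping and families.** Per locus, with f the fraction of
reference-spanning reads among (reference-spanning + junction-supporting)
reads — junction support is the per-side maximum, since summing both sides
double-counts the integrated haplotype — the state is hemizygous for
f ∈ [0.25, 0.75], homozygous for f ≤ 0.1, absent for f ≥ 0.9 when no read
still supports the junction (or when sample-level presence is trace/absent),
and unresolved otherwise. The zygosity band is a declared default;
requiring a trace/absent presence verdict for *every* absent call would
make per-locus absence impossible in multi-locus plants that retained one
insertion, so residual junction support is the deciding signal instead.
Family outcomes apply four ordered rules (cosegregating; not transmitted;
TGI locus segregating; mutation without integration; else other), and are
invariant to progeny order. The segregation test is exact and two-sided
under minimum-likelihood ordering (the convention is stated because
two-sided binomial conventions differ): the binomial case sums pmf terms,
the multinomial case enumerates outcomes for n ≤ 30 and switches to seeded
Monte Carlo beyond. Selfing is the only mating model, matching how these
families are produced; outcross/backcross schemes are future work.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes: a
uniform-composition host (default GC 0.35, soybean-like), a ~2.2 kb
cassette of labeled components (100 bp backbone flanks, 25 bp borders,
promoter, nuclease, guide cassette, marker; the promoter optionally copied
from the host to model a native-promoter construct), integration and edit
events applied as string rewrites, and FR paired-end reads (125 bp, default
20×, truncated-normal fragments with mean 400 SD 60 bounded to
[2 × read length, 3 × mean] — the real libraries' insert distribution being
unstated, these are conventional values). Errors are uniform substitutions
(default 10⁻³) with Q15 at substituted bases and Q30 elsewhere, giving the
trimmer something to act on while keeping allele truth unambiguous; indel
errors, PCR/optical duplicates and realistic Illumina error profiles are
deliberately out of scope. Contamination draws whole pairs from a foreign
transgenic haplotype at a set fraction, emulating cross-contamination by
template switching within barcoded libraries. All randomness flows from
integer seeds; outputs are byte-reproducible.

Two generator contracts matter for interpretation. First, planted
microhomology is written into the *reference* flank (m bases adjacent to
the junction equal the m terminal bases of the inserted segment), because
microhomology is by definition sequence shared by host reference and
cassette — planting it only in the edited haplotype would fake SNPs and
break host anchoring. Second, preset fixtures are sanitized so the planted
junction parameters are the unique string-level interpretation: a drawn
filler or flank base that coincidentally extends a host or cassette match
across the breakpoint (a ¼ chance per junction end) is adjusted, or the
placement shifted, until an independent string-inspection check passes.
Without this, a "4 bp filler" fixture would sometimes be a 3 bp-filler
fixture by construction, and exact recovery would be untestable.

What passing on this generator does **not** show: robustness to repeats and
paralogy in real genomes (uniform random hosts are maximally mappable), to
coverage biases, indel sequencing errors, duplicates, or multi-copy
concatemer arrays. Results on real data depend on those factors; the tests
here establish correctness of the inference logic, not field performance.

## Problem sizes and test design

Fixture recovery runs on 100 kb single-chromosome hosts (single-locus
scenario) and four chromosomes (multi-locus scenario) at 20×; family
robustness uses 10–12 kb chromosomes at 20× over 20 seeds per scenario,
sizes chosen so the full suite exercises every stage end to end in about a
minute while read counts per junction and per target window match what 20×
gives on any genome size. The chimeric-allele acceptance estimate pools
window-spanning reads over 150 replicate 20× simulations because a single
site at 20× yields only ~15–25 spanning reads, an estimator with ~8-point
standard error; pooling reflects the estimator's sampling distribution, not
a change in per-sample conditions. Oracle suites compare the aligner kernel
with a pure-Python quadratic DP (500 instances), the microhomology caller
with an exhaustive substring-pair search (1000 instances), the exact test
with direct enumeration (all n ≤ 12 binomial cases; multinomial via 3⁸
assignment enumeration), and the scanner with a brute-force sliding-window
scan.

## Known limitations

- Rearranged loci are labeled from junction orientations only; internal
  structure (copy number, concatemer order) is not reconstructed.
- Zygosity calls need ~20 informative reads; at the margins of the
  hemizygous band a locus can come back unresolved at 20×.
- The allele quantifier ignores substitution alleles and cannot phase
  alleles across paralogous sites.
- Presence thresholds and the zygosity band are heuristics validated on the
  synthetic conditions above, not calibrated cutoffs for real libraries.
- The target-site scanner assumes a fixed 20 nt protospacer with an NGG PAM
  and a blunt cut 3 bp from the PAM.
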