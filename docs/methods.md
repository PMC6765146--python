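# Methods

This note documents the models, defaults and numerical choices behind
`circulome`, and what the synthetic-data generator does and does not emulate.
Coordinates are 0-based half-open everywhere internally; BED on export.

## Synthetic germline genome

`simulate.build_genome` lays out each contig as alternating feature blocks
(MAC loci, TBE transposons) separated by 400–800 bp spacers, with a 400–700 bp
leading margin so that no planted feature violates the 150 nt contig-end
filter used downstream. A MAC locus is generated MAC-first: the somatic
sequence is drawn at random and MDSs are defined as windows of it that
overlap by their pointer, so the pointer (3–7 bp for non-scrambled loci,
9–13 bp for scrambled ones, matching germline averages of ~5 and ~11 bp) is
duplicated at the end of MDS *n* and the start of MDS *n* + 1 by
construction. Scrambled loci place their MDSs on the MIC in a random
non-identity permutation, each inverted with probability 0.3. IESs
(80–300 bp by default; the generator refuses IESs under 57 bp, the smallest
circularly excisable length) fill the inter-MDS gaps. Chromosome breakage
sites are recorded at the midpoint of each locus-to-locus gap.

TBEs are planted as `[B₊₄][ANT][TIR_L … TIR_R][ANT][B₋₄]`: the A-N-T
target-site duplication flanks the element on both sides, the left TIR starts
with the telomeric phase `AAAACCCCAAAACCCC`, the right TIR ends with
`GGGGTTTTGGGGTTTT`, and both ±4 bases (immediately outside the TSDs) are
drawn from the composition 19 % C / 52 % G / 22 % A / 7 % T, the empirical
consensus at that position in germline TBEs.

## Circular excision

TBE circles are excised precisely: every event produces the same junction, a
5 bp insert `G + TSD + X` joining the two TIR ends, where X is the base
immediately outside the right TSD (the −4 position). One resolved strand is
emitted; the heteroduplex that a 5 bp staggered cut would create is not
modeled, because sequencing reads single junction strands. A modelling point
worth recording: the junction context is quasi-palindromic (the two TIR
motifs are reverse complements), so the 33-mer junction pattern matches
junction reads on *both* strands with different central 5-mers. The
classifier therefore reads the class from the orientation whose 5-mer starts
with G — the resolved-strand orientation — which is the only strand-symmetric
reading consistent with the three G-initial classes. Recorded TBE cut
coordinates are (element_start − 1, element_end + 4) so the genomic span
equals the circle length; only the motif counter, not coordinates, is used
for TBE detection downstream.

IES circles are excised imprecisely: each cut is an independent
truncated-normal draw (sd = `cut_offset_sd`, default 6 bp; degenerate draws
giving a circle under 1 bp are re-sampled) around the start of the left and
right pointer copies, so a zero-noise circle is exactly IES + one pointer
copy. The true cut distribution in vivo is unknown — only summaries of
inferred cut distances are available — so the normal is a stand-in, and the
6 bp default was chosen to put most cuts within the 50 bp annotation window
while spreading them across pointer, IES and MDS compartments. Scrambled
IESs and intergenic regions (between MAC loci, near breakage sites) are cut
around their boundary positions.

## Sequencing model

Tagmentation makes 9 bp staggered cuts: every fragment end internal to a
molecule carries the 9 bp downstream of its cut duplicated, so a circle cut
exactly once linearizes into a fragment whose two ends share one 9-mer —
the read pair then shows identical 5′ 9-mers mapping outward with exactly
9 bp overlap. The number of cuts per molecule is Poisson with mean
length / mean-insert (≥ 1 for circles); fragments outside
[30 bp, mean + 4 sd] are size-selected away, which is why large (4 kb) TBE
circles never yield single-cut 9 bp-duplication pairs while small IES
circles often do, as in the real libraries. Reads are error-free 75-mers
(mate 2 reverse-complemented); base-quality error models are out of scope.
Exonuclease enrichment keeps every circle and each linear molecule with
probability `exo_linear_survival` (default 0.05 after three successive
digestions). The library grid is fixed to asexual ×2, early ×2, mid ×2
(+exo), mid ×1 (−exo), late ×1, with circle abundance 0 / 0.1 / 1.0 / 0.4 of
the mid level — circles are rearrangement products and absent from asexual
cells.

RNA-seq: transcribed circles initiate transcripts at N(0, 10 bp) offsets from
the junction, on either strand, 200–1200 nt long on the circular template
(read-through across the junction allowed). Backgrounds at every time point:
genic reads from MDS intervals and a low genome-wide noise floor. Circle
transcription is emitted only at mid-rearrangement.

## Mapper

The internal mapper is exact k-mer seeded (k = 15) with ungapped extension,
adequate because simulated reads are error-free; real-data users supply
external SAM, which all downstream modules accept. A full-length exact match
is primary; otherwise the longest exact prefix and suffix matches form a
chimeric split (primary = longer part, the other supplementary). MAPQ is
binary — 60 unique, 0 ambiguous — since the only downstream use is the
MAPQ < 5 cut; ties break to the smallest (contig, position). When maximal
prefix and suffix matches overlap on the read (which happens precisely when
the junction sits in a flanking direct repeat), the overlap is assigned to
the suffix, pinning the split to the *leftmost* equivalent register. This
makes junction calls deterministic and canonical: any register inside a
flanking repeat describes the same circular molecule, and
`junctions.canonical_junction` applies the same normalization to arbitrary
coordinates so that truth and calls are compared in one register.

## Filters and statistics

- Junction calls: same contig, same strand, permuted order (read prefix
  downstream of read suffix); MAPQ ≥ 5 on both segments; no duplicates or
  secondary records; both coordinates ≥ 150 nt from contig ends.
- 9 bp duplication calls additionally require both mates primary and mapped
  from their first base, opposite strands, 5′ overlap of exactly 9 bp, and
  identical 9-mers in genome space.
- Isoform merging is exact-coordinate: junction heterogeneity is the
  phenomenon; a window-grouped summary exists separately and is never used
  for unique-isoform counts. High-confidence thresholds are inclusive
  (≥ 25 %, ≤ 15 %). The filter is applied to the union of the two mid
  replicates' isoform sets.
- PCR duplicates: pairs sharing both mates' (contig, 5′ start, strand); the
  survivor is the lexicographically smallest read id, so the result is
  independent of input order.
- Interval shuffles preserve lengths and allow overlaps. The default mode
  places intervals entirely within a domain segment (uniform over all valid
  positions); for the IES-restricted transcription null, where circles are
  slightly longer than their source IES, the include-region mode anchors the
  interval start inside the domain and requires containment only within the
  contig, matching the cited shuffling tool's include semantics.
- KS is the standard two-sample test with the asymptotic p-value; the 2×2
  chi-squared uses the Yates-corrected contingency test. Both are checked
  against brute-force oracles in the tests. Percentiles count replicates
  *strictly below* the observed mean. Percentages are rounded only at report
  time (2 decimals; RPM to 1 decimal).
- Distance-to-MDS uses the minimum over both circle ends (both per-end values
  are retained in output); the direct repeat at a junction is the maximal
  exact extension in both directions from the junction point in the register
  fixed by the call, capped at 25 bp. Default distance bins are
  [0,49], [50,249], [250,999], [1000,2000], >2000-or-no-MDS; the edges are a
  reporting choice of this package.
- Cut-site tallies count both ends of every circle; read-weighted tallies can
  be derived from per-isoform support since both are emitted.

## Problem sizes and what the tests show

The test and reproduction configurations use 2 contigs of ~19–20 kb, 10 MAC
loci × 6 MDSs (≈ 50 IESs, ~58 planted circles), 2 TBEs, depth 15–20, and
300–1000 shuffle replicates; the statistical calibrations use 100–200
repeated runs at these sizes. Passing tests demonstrate that the detectors
are exact and calibrated under the generator's assumptions — error-free
reads, a unique non-repetitive genome outside TBEs, independent
truncated-normal cuts, Poisson tagmentation. They do not establish
performance under sequencing error, genuine repeat families, MDS paralogy
(treated as an input-annotation problem), polyploid copy-number variation, or
translocation circles joining different contigs (out of scope by design).
The published genome-wide numbers that depend on the real assembly and
libraries (2432 high-confidence circles, median 616 bp, the 29/39/32 %
cut-site split, KS p = 4.108 × 10⁻¹⁵) are descriptive context, not assertions
of this package, although the default cut-noise reproduces a very similar
compartment split on synthetic data.
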