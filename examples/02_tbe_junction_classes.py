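"""Classify transposon (TBE) circular junction reads and anchor TIR consensus.

TBE circles carry a junction whose central 5-mer is G + the ANT target-site
duplication + one genomic flank base, producing the GANTC / GANTG / GANTA
classes.  The 33-mer telomeric pattern finds these junctions in raw reads
without any mapping.
"""

import circulome as C

config = C.simulate.SimConfig(
    n_contigs=1, contig_length=60_000, n_mac_loci=2, mds_per_locus=3,
    n_tbe=60, tbe_length=120, depth=8, seed=5)
genome = C.simulate.build_genome(config)
circles = C.simulate.excise_circles(genome, config, seed=6)
lib = C.simulate.LIBRARY_GRID[4]  # mid-rearrangement replicate 1
pairs = C.simulate.simulate_library(genome, circles, config, lib, seed=7)

reads = [(f"{p.pair_id}/{m}", s) for p in pairs
         for m, s in ((1, p.mate1_seq), (2, p.mate2_seq))]
counts = C.junctions.count_tbe_junction_reads(reads, library=lib.label)
print(f"junction reads matching the telomeric pattern: {counts.total}")
print("per-class counts:", counts.counts)
print("(class = the base copied from outside the TSD; its genomic composition")
print(" defaults to 19% C / 52% G / 22% A / 7% T, so GANTG dominates)")
print()

windows = [genome.contigs[t.contig][t.start - 12:t.end + 12]
           for t in genome.tbes]
tir_counts, n_used, n_skipped = C.junctions.tir_consensus(windows)
freqs = C.junctions.tir_frequencies(tir_counts)
print(f"TIR consensus anchored for {n_used} elements ({n_skipped} skipped)")
print("position -4 (immediately outside the TSD) base frequencies:")
print({b: round(f, 2) for b, f in freqs[-4].items()})
print("positions +-5..+-7 read the A-N-T duplication:",
      {p: max(freqs[p], key=freqs[p].get) for p in (5, 6, 7, -5, -6, -7)})
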