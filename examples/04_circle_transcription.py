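"""Quantify rearrangement-specific transcription of circles from RNA-seq.

A subset of circles is transcribed from TSSs near their junctions at
mid-rearrangement; the mean length-normalized read count over the circle set
is compared to 1000 permutations of the coordinates among all IESs and
genome-wide.
"""

import circulome as C
from circulome.align import GenomeIndex, Read, map_reads

config = C.simulate.SimConfig(
    n_contigs=2, contig_length=20_000, n_mac_loci=10, mds_per_locus=6,
    fraction_scrambled=0.0, n_tbe=0, cut_offset_sd=0, depth=10, seed=19)
genome = C.simulate.build_genome(config)
circles = [c for c in C.simulate.excise_circles(genome, config, seed=20)
           if c.category == "non_scrambled_ies"]
subset = circles[::3][:16]
model = C.simulate.TssModel(
    rate=2.0, tss_offset_sd=8,
    transcribed_ids=tuple(c.molecule_id for c in subset[:5]))
reads = C.simulate.simulate_rnaseq(subset, model, depth=10, seed=21,
                                   genome=genome, background_per_bp=0.005,
                                   noise_per_bp=0.03)

index = GenomeIndex(genome.contigs)
intervals = [(c.origin_contig, c.left_cut, c.right_cut) for c in subset]
for tp in ("pre", "mid"):
    segs = map_reads([Read(r.read_id, 1, r.sequence) for r in reads[tp]], index)
    rep = C.transcribe.transcription_report(
        intervals, segs, genome.ies_intervals(), genome.contig_lengths(),
        tp, n_shuffles=1000, seed=31, unit="read")
    _, _, summary = C.transcribe.horizontal_rna_coverage(intervals, segs)
    print(f"{tp:4s}: mean count/bp {rep.observed_mean:.4f} | "
          f"IES-null percentile {100 * rep.null_ies.percentile:.1f}% | "
          f"genome-null percentile {100 * rep.null_genome.percentile:.1f}% | "
          f"circles with zero RNA coverage {100 * summary['zero']:.0f}%")
print()
print("At mid-rearrangement the circle set out-transcribes ~all random IES")
print("placements (percentile >= 95%); before rearrangement it is typical of")
print("the null, and against the genome-wide null (which lands on genes) the")
print("signal is judged against genic transcription instead.")
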