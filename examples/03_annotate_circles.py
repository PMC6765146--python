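"""Characterize circle junctions against the rearrangement annotations.

For planted circles with imprecise cuts: distance to the nearest MDS boundary
(vs a shuffle null over the assembly), cut-site compartments (pointer / IES /
MDS), flanking direct repeats (cryptic pointers), and the IES-vs-MDS cut
spread comparison.
"""

import circulome as C

config = C.simulate.SimConfig(
    n_contigs=2, contig_length=19_000, n_mac_loci=10, mds_per_locus=6,
    fraction_scrambled=0.2, n_tbe=0, cut_offset_sd=6, seed=23)
genome = C.simulate.build_genome(config)
circles = [(c.origin_contig, c.left_cut, c.right_cut)
           for c in C.simulate.excise_circles(genome, config, seed=24,
                                              events_per_site=5)
           if c.category != "tbe"]

print(f"{len(circles)} excision events with cut noise sd = 6 bp")
print()
table = C.annotate.mds_distance_null(circles, genome, n_shuffles=200, seed=25)
print("distance of circles to the nearest MDS boundary, observed vs shuffle")
print("null (mean +- 3 sd) -- circles cluster at boundaries, shuffles do not:")
print(table.round(3).to_string(index=False))
print()

ann, counts, ks_samples = C.annotate.classify_cut_sites(
    circles, genome.pointers, genome.mds_annotations)
total = sum(v for k, v in counts.items() if k != "unclassifiable")
print("cut-site compartments within 50 bp of an MDS boundary:")
for k in ("pointer", "IES", "MDS"):
    print(f"  {k:8s} {counts.get(k, 0):4d} ({100 * counts.get(k, 0) / total:.0f}%)")
d, p = C.annotate.ks_two_sample(ks_samples["IES"], ks_samples["MDS"])
print(f"IES vs MDS cut distance distributions: KS D={d:.3f}, p={p:.2e}")
print()

repeats = [C.annotate.flanking_direct_repeat(genome, c)[0] for c in circles]
zero = sum(1 for r in repeats if r == 0)
print(f"flanking direct repeats: {100 * zero / len(repeats):.0f}% of junctions"
      f" have none; max observed {max(repeats)} bp")
print("(repeats appear when a cut pair straddles the pointer in register)")
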