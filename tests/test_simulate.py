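"""Simulator: genome structure, excision geometry, tagmentation signatures."""

import numpy as np
import pytest
from scipy import stats as sps

import circulome as C
from circulome.dna import revcomp
from circulome.simulate import (CircularMolecule, LinearMolecule, SimConfig,
                                build_genome, excise_circles,
                                exonuclease_filter, pair_from_fragment,
                                simulate_library, simulate_rnaseq,
                                stitch_mac, tagment_and_read, tagment_circle,
                                tagment_linear, TssModel)


# ---------------------------------------------------------------------------
# configuration and genome structure


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        SimConfig(ies_length_range=(40, 300)).validate()  # below 57 bp floor
    with pytest.raises(ValueError):
        SimConfig(fraction_scrambled=1.5).validate()
    with pytest.raises(ValueError):
        SimConfig(contig_length=0).validate()


def test_overfull_contig_raises_sizing_error_naming_contig():
    cfg = SimConfig(n_contigs=1, contig_length=2_000, n_mac_loci=4,
                    mds_per_locus=4, n_tbe=0, seed=0)
    with pytest.raises(ValueError, match="contig1"):
        build_genome(cfg)


def test_genome_determinism(small_config):
    g1 = build_genome(small_config)
    g2 = build_genome(small_config)
    assert g1.contigs == g2.contigs
    assert g1.mds_annotations == g2.mds_annotations
    assert g1.pointers == g2.pointers
    assert g1.tbes == g2.tbes


def test_tbe_tsd_duplicated_on_both_flanks(small_genome):
    for tbe in small_genome.tbes:
        seq = small_genome.contigs[tbe.contig]
        left = seq[tbe.start - 3:tbe.start]
        right = seq[tbe.end:tbe.end + 3]
        assert left == right == tbe.tsd
        assert tbe.tsd[0] == "A" and tbe.tsd[2] == "T"


def test_tbe_tirs_contain_telomeric_motifs(small_genome):
    for tbe in small_genome.tbes:
        seq = small_genome.contigs[tbe.contig]
        assert "AACCCCAAAACCCC" in seq[tbe.tir_left[0]:tbe.tir_left[1]]
        assert "GGGGTTTTGGGGTT" in seq[tbe.tir_right[0]:tbe.tir_right[1]]


def test_pointer_copies_identical(small_genome):
    by_pair = {}
    for p in small_genome.pointers:
        by_pair.setdefault((p.locus, p.pair_index), []).append(p)
    for copies in by_pair.values():
        assert len(copies) == 2
        assert copies[0].sequence == copies[1].sequence
        for p in copies:
            mic = small_genome.contigs[p.contig][p.start:p.end]
            expected = p.sequence if p.strand == "+" else revcomp(p.sequence)
            assert mic == expected


def test_annotations_within_contig_bounds(small_genome):
    lengths = small_genome.contig_lengths()
    for m in small_genome.mds_annotations:
        assert 0 <= m.start < m.end <= lengths[m.contig]
    for p in small_genome.pointers:
        assert 0 <= p.start < p.end <= lengths[p.contig]


def test_unscrambled_genome_has_mac_order_on_mic():
    cfg = SimConfig(n_contigs=1, contig_length=20_000, n_mac_loci=3,
                    mds_per_locus=4, fraction_scrambled=0.0, n_tbe=0, seed=7)
    genome = build_genome(cfg)
    by_locus = {}
    for m in genome.mds_annotations:
        by_locus.setdefault(m.locus, []).append(m)
    for mds_list in by_locus.values():
        mds_list.sort(key=lambda m: m.start)
        assert [m.index for m in mds_list] == list(range(1, len(mds_list) + 1))
        assert all(m.orientation == "+" for m in mds_list)


def test_scrambled_locus_has_permuted_mic_order():
    cfg = SimConfig(n_contigs=1, contig_length=20_000, n_mac_loci=2,
                    mds_per_locus=5, fraction_scrambled=1.0, n_tbe=0, seed=9)
    genome = build_genome(cfg)
    by_locus = {}
    for m in genome.mds_annotations:
        by_locus.setdefault(m.locus, []).append(m)
    for mds_list in by_locus.values():
        mds_list.sort(key=lambda m: m.start)
        order = [m.index for m in mds_list]
        assert order != sorted(order) or any(m.orientation == "-" for m in mds_list)


def test_mds_stitching_reconstructs_mac(small_genome):
    for locus, mac in small_genome.mac_sequences.items():
        assert stitch_mac(small_genome, locus) == mac


def test_scrambled_mds_stitching_reconstructs_mac():
    cfg = SimConfig(n_contigs=1, contig_length=20_000, n_mac_loci=2,
                    mds_per_locus=5, fraction_scrambled=1.0, n_tbe=0, seed=13)
    genome = build_genome(cfg)
    for locus, mac in genome.mac_sequences.items():
        assert stitch_mac(genome, locus) == mac


# ---------------------------------------------------------------------------
# circular excision


def test_zero_noise_ies_circle_is_pointer_plus_ies(small_config, small_genome,
                                                   small_circles):
    ptr = {(p.locus, p.pair_index, p.copy): p for p in small_genome.pointers}
    checked = 0
    for circ in small_circles:
        if circ.category != "non_scrambled_ies":
            continue
        seq = small_genome.contigs[circ.origin_contig]
        assert circ.sequence == seq[circ.left_cut:circ.right_cut]
        # cut exactly at the start of each pointer copy
        matches = [
            (lp, rp) for (locus, pair, copy), lp in ptr.items()
            if copy == "left" and lp.start == circ.left_cut
            for rp in [ptr[(locus, pair, "right")]]
            if rp.start == circ.right_cut
        ]
        assert matches, "cuts not at pointer starts"
        lp, rp = matches[0]
        assert len(circ.sequence) == (lp.end - lp.start) + (rp.start - lp.end)
        checked += 1
    assert checked >= 3


def test_tbe_circle_junction_motif(small_genome, small_circles):
    tbe_by_contig_start = {(t.contig, t.start): t for t in small_genome.tbes}
    for circ in small_circles:
        if circ.category != "tbe":
            continue
        tbe = tbe_by_contig_start[(circ.origin_contig, circ.left_cut + 1)]
        seq = small_genome.contigs[circ.origin_contig]
        x = seq[tbe.end + 3]  # base immediately outside the right TSD copy
        assert circ.junction_motif == "G" + tbe.tsd + x
        assert circ.sequence.endswith(circ.junction_motif)
        assert len(circ.sequence) == circ.right_cut - circ.left_cut


def test_non_tbe_circle_length_invariant(small_circles):
    for circ in small_circles:
        if circ.category != "tbe":
            assert len(circ.sequence) == circ.right_cut - circ.left_cut
            assert len(circ.sequence) >= 1


def test_cut_offset_sd_empirical():
    """Sample-moment oracle: cut offsets around pointer centers have sd 5+-0.2."""
    cfg = SimConfig(n_contigs=1, contig_length=20_000, n_mac_loci=4,
                    mds_per_locus=4, fraction_scrambled=0.0, n_tbe=0,
                    cut_offset_sd=5.0, seed=21)
    genome = build_genome(cfg)
    ptr = {(p.locus, p.pair_index, p.copy): p for p in genome.pointers}
    circles = excise_circles(genome, cfg, seed=22, events_per_site=500)
    offsets = []
    ies_by_id = {(i.contig, i.locus, i.pointer_pair): i for i in genome.ies
                 if not i.scrambled}
    centers = {}
    for key, ies in ies_by_id.items():
        lp = ptr[(ies.locus, ies.pointer_pair, "left")]
        rp = ptr[(ies.locus, ies.pointer_pair, "right")]
        centers[(lp.start, rp.start)] = True
    center_pairs = sorted(centers)
    for circ in circles:
        if circ.category != "non_scrambled_ies":
            continue
        best = min(center_pairs,
                   key=lambda cp: abs(cp[0] - circ.left_cut) + abs(cp[1] - circ.right_cut))
        offsets.append(circ.left_cut - best[0])
        offsets.append(circ.right_cut - best[1])
    offsets = np.array(offsets, dtype=float)
    assert len(offsets) >= 10_000
    assert abs(offsets.std() - 5.0) <= 0.2
    assert abs(offsets.mean()) <= 0.2


def test_excision_determinism(small_genome, small_config):
    c1 = excise_circles(small_genome, small_config, seed=42)
    c2 = excise_circles(small_genome, small_config, seed=42)
    assert c1 == c2


# ---------------------------------------------------------------------------
# exonuclease filter


def test_exonuclease_filter_limits():
    circles = [CircularMolecule(f"c{i}", "ACGT" * 30, "contig1", 0, 120,
                                "non_scrambled_ies") for i in range(5)]
    linears = [LinearMolecule(f"l{i}", "ACGT" * 30, "contig1", 0, 120)
               for i in range(5)]
    assert exonuclease_filter(circles + linears, 0.0, seed=1) == circles
    assert exonuclease_filter(circles + linears, 1.0, seed=1) == circles + linears
    with pytest.raises(ValueError):
        exonuclease_filter(circles, 1.5, seed=1)


def test_exonuclease_filter_binomial_oracle():
    linears = [LinearMolecule(f"l{i}", "ACGTACGTACGTACGTACGTACGTACGTACGT",
                              "contig1", 0, 32) for i in range(10_000)]
    kept = exonuclease_filter(linears, 0.1, seed=123)
    # binomial(10000, 0.1): mean 1000, sd 30
    assert abs(len(kept) - 1000) <= 3 * 30


# ---------------------------------------------------------------------------
# tagmentation


def test_single_cut_circle_pair_has_matching_9mers():
    rng = np.random.default_rng(0)
    seq = C.dna.random_dna(rng, 200)
    frags = tagment_circle(seq, [60])
    assert len(frags) == 1
    frag, start = frags[0]
    assert len(frag) == 209 and start == 60
    m1, m2, trunc = pair_from_fragment(frag, 75)
    assert not trunc
    assert m1[:9] == revcomp(m2[:9])
    assert m1[:9] == (seq + seq)[60:69]


def test_multi_cut_circle_fragments_tile_the_circle():
    rng = np.random.default_rng(1)
    seq = C.dna.random_dna(rng, 500)
    frags = tagment_circle(seq, [50, 200, 420])
    assert len(frags) == 3
    assert sum(len(f) - 9 for f, _ in frags) == 500
    doubled = seq + seq
    for frag, start in frags:
        assert doubled[start:start + len(frag)] == frag


def test_linear_fragments_have_no_duplicated_outer_ends():
    rng = np.random.default_rng(2)
    seq = C.dna.random_dna(rng, 400)
    frags = tagment_linear(seq, [100, 250])
    assert [s for _, s in frags] == [0, 100, 250]
    assert frags[0][0] == seq[:109]
    assert frags[-1][0] == seq[250:]


def test_9bp_flag_iff_single_cut_circle(small_genome, small_config, small_circles):
    linear = C.simulate.sample_linear_background(small_genome, small_config, seed=31)
    pairs = tagment_and_read(small_circles * 5, linear, small_config, "lib", seed=32)
    assert any(p.has_9bp_dup for p in pairs)
    for p in pairs:
        if p.has_9bp_dup:
            assert p.origin_kind == "circle" and p.n_cuts == 1
            assert p.mate1_seq[:9] == revcomp(p.mate2_seq[:9])
        if p.origin_kind == "linear":
            assert not p.has_9bp_dup


def test_read_conservation(small_genome, small_config, small_circles):
    """Every emitted read is an exact substring (or revcomp) of its origin."""
    by_id = {c.molecule_id: c for c in small_circles}
    linear = C.simulate.sample_linear_background(small_genome, small_config, seed=41)
    by_id.update({m.molecule_id: m for m in linear})
    pairs = tagment_and_read(small_circles, linear, small_config, "lib", seed=42)
    assert pairs
    for p in pairs:
        origin = by_id[p.origin_id].sequence
        template = origin + origin if p.origin_kind == "circle" else origin
        assert p.mate1_seq in template
        assert revcomp(p.mate2_seq) in template


def test_library_grid_and_determinism(small_config, small_genome, small_circles):
    lib = [l for l in C.simulate.LIBRARY_GRID if l.label == "mid_r1"][0]
    p1 = simulate_library(small_genome, small_circles, small_config, lib, seed=5)
    p2 = simulate_library(small_genome, small_circles, small_config, lib, seed=5)
    assert p1 == p2
    asex = [l for l in C.simulate.LIBRARY_GRID if l.timepoint == "asexual"][0]
    pa = simulate_library(small_genome, small_circles, small_config, asex, seed=5)
    assert all(p.origin_kind == "linear" for p in pa)  # no circles pre-mating


# ---------------------------------------------------------------------------
# TBE junction class composition


def test_tbe_junction_class_matches_flank_composition():
    """Chi-squared goodness of fit of junction classes against the configured
    -4 flank-base composition, over many independent elements."""
    comp = {"A": 0.25, "C": 0.25, "G": 0.5, "T": 0.0}
    cfg = SimConfig(n_contigs=1, contig_length=430_000, n_mac_loci=1,
                    mds_per_locus=2, n_tbe=600, tbe_length=60,
                    flank_base_composition=comp, seed=51)
    genome = build_genome(cfg)
    circles = excise_circles(genome, cfg, seed=52)
    classes = [c.junction_motif[4] for c in circles if c.category == "tbe"]
    assert len(classes) == 600
    assert "T" not in classes
    observed = np.array([classes.count(b) for b in "ACG"], dtype=float)
    expected = np.array([comp[b] * len(classes) for b in "ACG"])
    chi2, p = sps.chisquare(observed, expected)
    assert p > 0.01


# ---------------------------------------------------------------------------
# RNA simulation


def test_rnaseq_zero_rate_gives_background_only(small_circles, small_genome):
    model = TssModel(rate=0.0, transcribed_fraction=1.0)
    reads = simulate_rnaseq(small_circles, model, depth=3, seed=61,
                            genome=small_genome)
    assert all(r.origin == "background" for tp in reads for r in reads[tp])


def test_rnaseq_readthrough_crosses_junction(small_circles):
    circ = [c for c in small_circles if c.category == "non_scrambled_ies"][0]
    model = TssModel(rate=20.0, transcribed_fraction=1.0, tss_offset_sd=5,
                     transcript_length_range=(300, 500))
    reads = simulate_rnaseq([circ], model, depth=3, seed=62)
    mid = [r for r in reads["mid"] if r.origin == circ.molecule_id]
    assert mid
    assert any(r.crosses_junction for r in mid)
    doubled = circ.sequence * 2
    for r in mid:
        assert r.sequence in doubled or revcomp(r.sequence) in doubled
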