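"""Shared fixtures: a compact genome for unit tests and a richer simulated
experiment (50+ planted circles, full library grid) shared by the detection,
assembly and acceptance tests."""

import pytest

import circulome as C


@pytest.fixture(scope="session")
def small_config():
    return C.simulate.SimConfig(
        n_contigs=2, contig_length=15_000, n_mac_loci=4, mds_per_locus=3,
        fraction_scrambled=0.25, n_tbe=2, tbe_length=400, depth=10,
        cut_offset_sd=0, seed=3)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return C.simulate.build_genome(small_config)


@pytest.fixture(scope="session")
def small_circles(small_config, small_genome):
    return C.simulate.excise_circles(small_genome, small_config, seed=5)


@pytest.fixture(scope="session")
def rich_config():
    # ~50 planted IES circles with precise cuts, plus TBEs and intergenic
    # regions, across the full asexual/early/mid/late +-exo library grid.
    return C.simulate.SimConfig(
        n_contigs=2, contig_length=19_000, n_mac_loci=10, mds_per_locus=6,
        fraction_scrambled=0.2, n_tbe=2, tbe_length=400, depth=15,
        cut_offset_sd=0, seed=11)


@pytest.fixture(scope="session")
def rich_pipeline(rich_config):
    return C.workflow.run_pipeline(rich_config)


def canonical_truth_junctions(result):
    """Canonical (contig, start, end) of every planted non-TBE circle."""
    out = {}
    for circ in result.true_circles:
        if circ.category == "tbe":
            continue
        seq = result.genome.contigs[circ.origin_contig]
        s, e = C.junctions.canonical_junction(seq, circ.left_cut, circ.right_cut)
        out[circ.molecule_id] = (circ.origin_contig, s, e)
    return out
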