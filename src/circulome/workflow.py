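"""End-to-end orchestration: simulate -> map -> detect -> assemble -> filter.

Thin plumbing over the analysis modules, used by the examples and the
reproduction script; each step is equally callable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from . import align, circles as circles_mod, junctions, simulate


@dataclass
class LibraryResult:
    library: str
    pairs: list
    segments: list
    total_mapped: int
    split_calls: list
    ninebp_calls: list
    tbe_counts: junctions.TbeJunctionCount


@dataclass
class PipelineResult:
    genome: simulate.GenomeModel
    true_circles: list
    libraries: dict[str, LibraryResult]
    circle_calls: list = field(default_factory=list)

    def library_stats(self):
        stats = []
        for lib, res in self.libraries.items():
            stats.append(circles_mod.LibraryStats(
                library=lib, total_mapped=res.total_mapped,
                metrics={
                    "tbe_junction_reads": res.tbe_counts.total,
                    "circle_junction_reads": len(res.split_calls),
                    "ninebp_duplication_reads": len(res.ninebp_calls),
                }))
        return circles_mod.library_summary(stats)


def process_library(pairs, index: align.GenomeIndex, label: str) -> LibraryResult:
    """Map one library and run the three junction detectors."""
    reads = align.pairs_to_reads(pairs)
    segments = align.map_reads(reads, index)
    segments = align.mark_duplicates(segments)
    lengths = index.lengths()
    mapped_pairs = {s.read_id for s in segments if not s.unmapped}
    split_calls = junctions.detect_split_junctions(segments, lengths, label)
    split_calls = junctions.canonicalize_calls(split_calls, index.contigs)
    try:
        ninebp = junctions.detect_9bp_duplications(reads, segments, lengths, label)
    except ValueError:
        ninebp = []
    tbe = junctions.count_tbe_junction_reads(
        ((f"{p.pair_id}/{m}", s) for p in pairs
         for m, s in ((1, p.mate1_seq), (2, p.mate2_seq))),
        library=label)
    return LibraryResult(library=label, pairs=pairs, segments=segments,
                         total_mapped=len(mapped_pairs), split_calls=split_calls,
                         ninebp_calls=ninebp, tbe_counts=tbe)


def run_pipeline(config: simulate.SimConfig,
                 events_per_site: int = 1) -> PipelineResult:
    """Simulate the full library grid and call high-confidence circles."""
    genome, true_circles, libraries = simulate.simulate_experiment(
        config, events_per_site=events_per_site)
    index = align.GenomeIndex(genome.contigs)
    results = {}
    for label, pairs in libraries.items():
        results[label] = process_library(pairs, index, label)

    # putative circles = union of split-read junction calls over mid +exo
    split_calls = []
    for lib in circles_mod.MID_EXO_LIBRARIES:
        split_calls.extend(results[lib].split_calls)
    calls = circles_mod.assemble_circles(split_calls)
    circles_mod.coverage_by_library(
        calls, {lib: results[lib].segments
                for lib in (*circles_mod.MID_EXO_LIBRARIES,
                            *circles_mod.ASEXUAL_LIBRARIES)})
    circles_mod.call_high_confidence(calls)
    return PipelineResult(genome=genome, true_circles=true_circles,
                          libraries=results, circle_calls=calls)
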