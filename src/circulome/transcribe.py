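"""Rearrangement-specific transcription of circles from RNA-seq.

Quantifies length-normalized read counts over circle intervals, compares the
observed mean to permutation nulls (circle coordinates shuffled either among
IES intervals or genome-wide), and computes horizontal RNA coverage per
circle.  Counts are unstranded; "fraction of replicates strictly below the
observed mean" is the reported percentile.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .align import AlignmentSegment
from .annotate import NullDistribution, shuffle_intervals
from .circles import horizontal_coverage


def _as_interval(circle) -> tuple[str, int, int]:
    return (circle if isinstance(circle, tuple)
            else (circle.contig, circle.start, circle.end))


def _primary_by_unit(rna_segments: Sequence[AlignmentSegment], unit: str):
    """Collapse alignments to counting units: one entry per fragment (pair)
    or per read (mate)."""
    per_contig: dict[str, list[tuple[int, int, tuple]]] = defaultdict(list)
    for seg in rna_segments:
        if seg.unmapped or seg.secondary or seg.duplicate or seg.supplementary:
            continue
        key = (seg.read_id,) if unit == "pair" else (seg.read_id, seg.mate)
        per_contig[seg.contig].append((seg.ref_start, seg.ref_end, key))
    return per_contig


def count_reads_in_intervals(rna_segments: Sequence[AlignmentSegment],
                             intervals: Sequence, unit: str = "pair") -> np.ndarray:
    """Length-normalized counts (overlapping units per bp) per interval.

    A unit counts if any of its alignment extents intersects the interval by
    >= 1 bp; with unit='pair' the two mates of a fragment count once.
    """
    per_contig = _primary_by_unit(rna_segments, unit)
    out = np.zeros(len(intervals), dtype=float)
    for i, circ in enumerate(intervals):
        contig, start, end = _as_interval(circ)
        if end <= start:
            raise ValueError("zero-length interval")
        units = {key for (a, b, key) in per_contig.get(contig, ())
                 if a < end and b > start}
        out[i] = len(units) / (end - start)
    return out


def permutation_percentile(observed_mean: float, intervals: Sequence,
                           rna_segments: Sequence[AlignmentSegment],
                           domain: Sequence[tuple[str, int, int]],
                           n: int = 1000, seed: int = 0,
                           unit: str = "pair",
                           contig_lengths: Optional[dict[str, int]] = None,
                           ) -> NullDistribution:
    """Permutation null for mean length-normalized counts over intervals.

    Each replicate re-places every interval (length preserved) uniformly on
    `domain` -- the IES intervals for the IES-restricted null, or whole
    contigs for the genome-wide null -- and recomputes the mean.  The
    percentile is the fraction of replicates strictly below `observed_mean`.
    Pass `contig_lengths` when the domain is a set of IESs shorter than the
    circles, so placements anchor their start in an IES (include-region
    shuffle semantics).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ivs = [_as_interval(c) for c in intervals]
    reps = []
    for placed in shuffle_intervals(ivs, domain, n, seed, contig_lengths):
        reps.append(count_reads_in_intervals(rna_segments, placed, unit).mean())
    return NullDistribution.from_replicates(observed_mean, reps)


def horizontal_rna_coverage(circles: Sequence,
                            rna_segments: Sequence[AlignmentSegment],
                            bins: int = 10):
    """Per-circle horizontal RNA coverage plus histogram and summary fractions.

    Returns (fractions array, histogram DataFrame, summary dict) where the
    summary reports the fraction of circles with zero coverage, > 20% and
    > 80% coverage.
    """
    import pandas as pd

    per_contig: dict[str, list[AlignmentSegment]] = defaultdict(list)
    for seg in rna_segments:
        if not (seg.unmapped or seg.secondary or seg.duplicate):
            per_contig[seg.contig].append(seg)
    fracs = np.array([
        horizontal_coverage(_as_interval(c), per_contig.get(_as_interval(c)[0], ()))
        for c in circles
    ])
    edges = np.linspace(0, 1, bins + 1)
    hist, _ = np.histogram(fracs, bins=edges)
    table = pd.DataFrame({
        "bin_lo": edges[:-1], "bin_hi": edges[1:],
        "n_circles": hist,
        "fraction": hist / max(len(fracs), 1),
    })
    summary = {
        "zero": float((fracs == 0).mean()) if len(fracs) else 0.0,
        "gt20": float((fracs > 0.2).mean()) if len(fracs) else 0.0,
        "gt80": float((fracs > 0.8).mean()) if len(fracs) else 0.0,
    }
    return fracs, table, summary


def subsample_normalize(segments_by_library: dict[str, Sequence[AlignmentSegment]],
                        seed: int = 0):
    """Depth-normalize libraries by binomial subsampling of read pairs.

    Each library is downsampled by (smallest library's mapped pairs / its
    mapped pairs); the smallest library passes unchanged.  Returns
    (subsampled segments per library, adjustment factors).
    """
    rng = np.random.default_rng(seed)
    pair_ids = {lib: sorted({s.read_id for s in segs if not s.unmapped})
                for lib, segs in segments_by_library.items()}
    totals = {lib: len(ids) for lib, ids in pair_ids.items()}
    if any(t == 0 for t in totals.values()):
        raise ValueError("library with zero mapped reads")
    smallest = min(totals.values())
    factors = {lib: smallest / t for lib, t in totals.items()}
    out = {}
    for lib, segs in segments_by_library.items():
        f = factors[lib]
        if f >= 1.0:
            out[lib] = list(segs)
            continue
        keep = {rid for rid in pair_ids[lib] if rng.random() < f}
        out[lib] = [s for s in segs if s.read_id in keep]
    return out, factors


@dataclass
class TranscriptionReport:
    """Bundle of per-circle transcription metrics for one RNA library."""

    library: str
    counts_per_bp: np.ndarray
    coverage: np.ndarray
    observed_mean: float
    null_ies: Optional[NullDistribution] = None
    null_genome: Optional[NullDistribution] = None

    def to_frame(self, circles):
        import pandas as pd

        rows = []
        for circ, cnt, cov in zip(circles, self.counts_per_bp, self.coverage):
            contig, start, end = _as_interval(circ)
            rows.append({"contig": contig, "start": start, "end": end,
                         "count_per_bp": cnt, "rna_coverage": cov})
        return pd.DataFrame(rows)


def transcription_report(circles, rna_segments, ies_intervals,
                         contig_lengths: dict[str, int], library: str,
                         n_shuffles: int = 1000, seed: int = 0,
                         unit: str = "pair") -> TranscriptionReport:
    """Full transcription analysis of circles for one RNA library."""
    counts = count_reads_in_intervals(rna_segments, circles, unit)
    observed = float(counts.mean())
    genome_domain = [(c, 0, L) for c, L in contig_lengths.items()]
    null_ies = permutation_percentile(observed, circles, rna_segments,
                                      ies_intervals, n_shuffles, seed, unit,
                                      contig_lengths=contig_lengths)
    null_genome = permutation_percentile(observed, circles, rna_segments,
                                         genome_domain, n_shuffles, seed + 1, unit)
    fracs, _, _ = horizontal_rna_coverage(circles, rna_segments)
    return TranscriptionReport(library=library, counts_per_bp=counts,
                               coverage=fracs, observed_mean=observed,
                               null_ies=null_ies, null_genome=null_genome)
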