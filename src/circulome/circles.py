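"""Assembly of junction calls into eccDNA isoforms and abundance filters.

Isoform merging is exact-coordinate: the heterogeneous, imprecise junctions
of germline-limited circles are the phenomenon, so two junctions differing by
a single base are distinct isoforms.  A window-based grouping is offered
separately for summary reporting only.

The high-confidence rule requires, per isoform, >= 25% horizontal read
coverage in both exonuclease-enriched mid-rearrangement replicates, <= 15%
coverage in both asexual replicates, and at least one junction-spanning read.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .align import AlignmentSegment
from .junctions import JunctionCall

MID_EXO_LIBRARIES = ("mid_r1", "mid_r2")
ASEXUAL_LIBRARIES = ("asexual_r1", "asexual_r2")


@dataclass
class CircleCall:
    contig: str
    start: int
    end: int
    isoform_id: str
    support: dict[str, int] = field(default_factory=dict)  # per-library junction reads
    coverage: dict[str, float] = field(default_factory=dict)  # per-library horizontal
    high_confidence: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def total_support(self) -> int:
        return sum(self.support.values())


def assemble_circles(junction_calls: Sequence[JunctionCall]) -> list[CircleCall]:
    """Merge junction calls with identical coordinates into circle isoforms."""
    grouped: dict[tuple, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for call in junction_calls:
        key = (call.contig, call.circle_start, call.circle_end)
        grouped[key][call.library] += len(call.supporting_read_ids)
    circles = []
    for i, key in enumerate(sorted(grouped)):
        contig, start, end = key
        circles.append(CircleCall(
            contig=contig, start=start, end=end, isoform_id=f"circle{i}",
            support=dict(grouped[key])))
    return circles


def horizontal_coverage(circle, segments: Sequence[AlignmentSegment]) -> float:
    """Fraction of circle-body positions overlapped by >= 1 mapped segment."""
    contig, start, end = (circle if isinstance(circle, tuple)
                          else (circle.contig, circle.start, circle.end))
    if end <= start:
        raise ValueError("zero-length circle")
    covered = np.zeros(end - start, dtype=bool)
    for seg in segments:
        if seg.unmapped or seg.contig != contig:
            continue
        a = max(seg.ref_start, start)
        b = min(seg.ref_end, end)
        if b > a:
            covered[a - start:b - start] = True
    return float(covered.mean())


def coverage_by_library(circles: Sequence[CircleCall],
                        segments_by_library: dict[str, Sequence[AlignmentSegment]],
                        ) -> None:
    """Fill each circle's per-library horizontal coverage in place."""
    # bucket segments per contig once per library
    for lib, segments in segments_by_library.items():
        per_contig: dict[str, list[AlignmentSegment]] = defaultdict(list)
        for seg in segments:
            if not seg.unmapped:
                per_contig[seg.contig].append(seg)
        for circ in circles:
            circ.coverage[lib] = horizontal_coverage(
                (circ.contig, circ.start, circ.end), per_contig.get(circ.contig, ()))


def call_high_confidence(circles: Sequence[CircleCall],
                         mid_exo_libraries: Sequence[str] = MID_EXO_LIBRARIES,
                         asexual_libraries: Sequence[str] = ASEXUAL_LIBRARIES,
                         min_mid_coverage: float = 0.25,
                         max_asexual_coverage: float = 0.15) -> list[CircleCall]:
    """Flag high-confidence circles (thresholds inclusive; see module doc)."""
    required = list(mid_exo_libraries) + list(asexual_libraries)
    for circ in circles:
        for lib in required:
            if lib not in circ.coverage:
                raise ValueError(f"circle {circ.isoform_id}: missing coverage "
                                 f"for required library {lib!r}")
        circ.high_confidence = (
            all(circ.coverage[lib] >= min_mid_coverage for lib in mid_exo_libraries)
            and all(circ.coverage[lib] <= max_asexual_coverage
                    for lib in asexual_libraries)
            and circ.total_support >= 1
        )
    return list(circles)


def rpm(raw: int, total_mapped: int) -> float:
    """Reads per million mapped, reported to one decimal."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return round(raw / total_mapped * 1e6, 1)


@dataclass
class LibraryStats:
    library: str
    total_mapped: int
    metrics: dict[str, int] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {"library": self.library, "mapped_reads": self.total_mapped}
        for name, raw in self.metrics.items():
            row[name] = raw
            row[name + "_rpm"] = rpm(raw, self.total_mapped)
        return row


def library_summary(stats: Sequence[LibraryStats]):
    """Per-library table of raw counts and RPMs (read-statistics report)."""
    import pandas as pd

    return pd.DataFrame([s.as_row() for s in stats])


def group_isoforms(circles: Sequence[CircleCall], window: int = 10):
    """Optional summary grouping of isoforms whose coordinates agree within
    `window` bp (never used for counting unique isoforms)."""
    groups: list[list[CircleCall]] = []
    for circ in sorted(circles, key=lambda c: (c.contig, c.start, c.end)):
        placed = False
        for g in groups:
            ref = g[0]
            if (ref.contig == circ.contig
                    and abs(ref.start - circ.start) <= window
                    and abs(ref.end - circ.end) <= window):
                g.append(circ)
                placed = True
                break
        if not placed:
            groups.append([circ])
    return groups


# ---------------------------------------------------------------------------
# export


def write_circles_bed(circles: Sequence[CircleCall], path: str) -> None:
    """BED6 + isoform id, total support, per-library coverage, flag."""
    with open(path, "w") as fh:
        for c in sorted(circles, key=lambda c: (c.contig, c.start, c.end)):
            cov = ",".join(f"{lib}:{v:.3f}" for lib, v in sorted(c.coverage.items()))
            fh.write(f"{c.contig}\t{c.start}\t{c.end}\t{c.isoform_id}\t"
                     f"{c.total_support}\t.\t{cov}\t{int(c.high_confidence)}\n")


def write_bedgraph(segments: Sequence[AlignmentSegment],
                   contig_lengths: dict[str, int], path: str,
                   subsample: float = 1.0, seed: int = 0) -> None:
    """Per-base depth track (optionally subsampled) for browser display."""
    rng = np.random.default_rng(seed)
    depth = {name: np.zeros(length, dtype=np.int32)
             for name, length in contig_lengths.items()}
    for seg in segments:
        if seg.unmapped:
            continue
        if subsample < 1.0 and rng.random() >= subsample:
            continue
        depth[seg.contig][seg.ref_start:seg.ref_end] += 1
    with open(path, "w") as fh:
        for name in sorted(depth):
            d = depth[name]
            boundaries = np.nonzero(np.diff(d))[0] + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(d)]])
            for s, e in zip(starts, ends):
                if d[s]:
                    fh.write(f"{name}\t{s}\t{e}\t{d[s]}\n")
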