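"""Detection of the three evidence classes of DNA circularity.

* TBE motif junction reads: the 33-mer telomeric-junction pattern
  ``GGTTTTGGGGTTTT.A.T.AAAACCCCAAAACC`` matched on raw read sequence
  (both strands), classified by the 5 bp central motif (GANTC/GANTG/GANTA).
* Split-read circle junctions: a read whose prefix maps downstream of its
  suffix on the same contig and strand (permuted order) spans a circle
  ligation point.
* 9 bp duplication read pairs: outward-facing mates whose 5' mapped ends
  overlap by exactly 9 bp with identical 9-mers -- the tagmentation signature
  of a single-cut circle.

Standard filters throughout: MAPQ >= 5, no duplicates/secondary records, and
calls within 150 nt of a contig end are discarded as assembly artifacts.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .align import AlignmentSegment, Read
from .dna import revcomp

TBE_JUNCTION_PATTERN = re.compile("GGTTTTGGGGTTTT.A.T.AAAACCCCAAAACC")

MIN_MAPQ = 5
CONTIG_END_MARGIN = 150

#: anchor motifs for TIR consensus building (phases of the telomeric repeat)
TIR_ANCHOR_LEFT = "AACCCCAAAACCCC"   # A2 C4 A4 C4
TIR_ANCHOR_RIGHT = "GGGGTTTTGGGGTT"  # G4 T4 G4 T2


@dataclass
class JunctionCall:
    contig: str
    circle_start: int
    circle_end: int
    evidence: str  # 'split_read' | 'nine_bp_dup' | 'tbe_motif'
    supporting_read_ids: list[str]
    library: str
    cut_position: Optional[int] = None  # shared 9-mer locus for 9 bp calls


@dataclass
class TbeJunctionCount:
    library: str
    counts: dict[str, int]  # keys GANTC / GANTG / GANTA / other
    total: int
    matching_read_ids: list[str] = field(default_factory=list)

    def rpm(self, total_mapped: int) -> float:
        from .circles import rpm

        return rpm(self.total, total_mapped)


# ---------------------------------------------------------------------------
# TBE motif junction reads


def count_tbe_junction_reads(reads: Iterable, library: str = "") -> TbeJunctionCount:
    """Count reads matching the TBE circular-junction pattern.

    Each read is searched on both strands and counts at most once; the class
    is the 5th base of the central NANTN motif (C, G or A; anything else is
    tallied as 'other').  `reads` yields objects with read_id/sequence
    attributes, or (read_id, sequence) tuples.
    """
    counts = Counter({"GANTC": 0, "GANTG": 0, "GANTA": 0, "other": 0})
    seen: set[str] = set()
    ids: list[str] = []
    for read in reads:
        if isinstance(read, tuple):
            read_id, seq = read
        else:
            read_id, seq = read.read_id, read.sequence
        if read_id in seen:
            continue
        # The junction context is quasi-palindromic (the two TIR motifs are
        # reverse complements), so the pattern can match either strand of a
        # junction read.  Classification uses the orientation whose central
        # 5-mer starts with G (the resolved junction strand), which makes the
        # per-class counts strand-symmetric.
        candidates = []
        for s in (seq, revcomp(seq)):
            match = TBE_JUNCTION_PATTERN.search(s)
            if match:
                candidates.append(match.group(0)[14:19])
        if not candidates:
            continue
        seen.add(read_id)
        ids.append(read_id)
        central = next((c for c in candidates if c[0] == "G"), candidates[0])
        cls_base = central[4]
        key = f"GANT{cls_base}" if cls_base in "CGA" else "other"
        counts[key] += 1
    return TbeJunctionCount(library=library, counts=dict(counts),
                            total=sum(counts.values()), matching_read_ids=ids)


# ---------------------------------------------------------------------------
# split-read circle junctions


def _passes_standard_filters(seg: AlignmentSegment) -> bool:
    return (not seg.duplicate and not seg.secondary and not seg.unmapped
            and seg.mapq >= MIN_MAPQ)


def detect_split_junctions(segments: Sequence[AlignmentSegment],
                           contig_lengths: dict[str, int],
                           library: str = "") -> list[JunctionCall]:
    """Call circle junctions from chimeric (primary + supplementary) reads.

    Mates are treated independently (paired reads collapsed to single-end).
    A call requires the read-prefix segment to map downstream of the
    read-suffix segment on the same contig and strand: the permuted mapping
    order that only a circular template produces.
    """
    for seg in segments:
        if seg.contig not in contig_lengths:
            raise ValueError(f"segment names unknown contig {seg.contig!r}")

    by_read: dict[tuple, list[AlignmentSegment]] = defaultdict(list)
    for seg in segments:
        if seg.secondary or seg.duplicate or seg.unmapped:
            continue
        by_read[(seg.read_id, seg.mate)].append(seg)

    calls: list[JunctionCall] = []
    for (read_id, mate), segs in by_read.items():
        if len(segs) != 2:
            continue
        prim = [s for s in segs if not s.supplementary]
        supp = [s for s in segs if s.supplementary]
        if len(prim) != 1 or len(supp) != 1:
            continue
        a, b = segs
        if a.contig != b.contig or a.strand != b.strand:
            continue
        if a.mapq < MIN_MAPQ or b.mapq < MIN_MAPQ:
            continue
        seg_first, seg_second = sorted(segs, key=lambda s: s.read_start)
        if a.strand == "+":
            # read prefix must map downstream of the read suffix
            if seg_first.ref_start <= seg_second.ref_start:
                continue
            start, end = seg_second.ref_start, seg_first.ref_end
        else:
            if seg_first.ref_start >= seg_second.ref_start:
                continue
            start, end = seg_first.ref_start, seg_second.ref_end
        clen = contig_lengths[a.contig]
        if start < CONTIG_END_MARGIN or end > clen - CONTIG_END_MARGIN:
            continue
        if end <= start:
            continue
        calls.append(JunctionCall(
            contig=a.contig, circle_start=start, circle_end=end,
            evidence="split_read", supporting_read_ids=[f"{read_id}/{mate}"],
            library=library))
    return calls


def canonical_junction(contig_seq: str, start: int, end: int) -> tuple[int, int]:
    """Shift a junction to its leftmost equivalent register.

    When the circularization point lies inside a flanking direct repeat, any
    register within the repeat describes the same circular molecule; the
    leftmost register is used as the canonical representative.
    """
    while start > 0 and end > 0 and contig_seq[start - 1] == contig_seq[end - 1]:
        start -= 1
        end -= 1
    return start, end


def canonicalize_calls(calls: Sequence[JunctionCall],
                       contigs: dict[str, str]) -> list[JunctionCall]:
    out = []
    for c in calls:
        s, e = canonical_junction(contigs[c.contig], c.circle_start, c.circle_end)
        out.append(JunctionCall(c.contig, s, e, c.evidence,
                                list(c.supporting_read_ids), c.library,
                                c.cut_position))
    return out


# ---------------------------------------------------------------------------
# 9 bp duplication read pairs


def detect_9bp_duplications(reads: Sequence[Read],
                            segments: Sequence[AlignmentSegment],
                            contig_lengths: dict[str, int],
                            library: str = "") -> list[JunctionCall]:
    """Call single-cut circles from the tagmentation 9 bp duplication.

    Requires both mates of a pair mapped (primary, full standard filters) on
    the same contig, opposite strands, oriented outward with their 5' mapped
    ends overlapping by exactly 9 bp, and the two 5'-terminal 9-mers identical
    in genome space.
    """
    seqs: dict[tuple, str] = {}
    mates_seen: dict[str, set] = defaultdict(set)
    for r in reads:
        seqs[(r.read_id, r.mate)] = r.sequence
        mates_seen[r.read_id].add(r.mate)
    if any(m != {1, 2} for m in mates_seen.values()):
        raise ValueError("9 bp duplication detection requires paired reads")

    primaries: dict[str, dict[int, AlignmentSegment]] = defaultdict(dict)
    for seg in segments:
        if seg.supplementary or not _passes_standard_filters(seg):
            continue
        primaries[seg.read_id][seg.mate] = seg

    calls: list[JunctionCall] = []
    for read_id, mates in sorted(primaries.items()):
        if set(mates) != {1, 2}:
            continue
        s1, s2 = mates[1], mates[2]
        if s1.contig != s2.contig or s1.strand == s2.strand:
            continue
        plus, minus = (s1, s2) if s1.strand == "+" else (s2, s1)
        # both 5' ends must be aligned from the first read base
        if plus.read_start != 0 or minus.read_start != 0:
            continue
        if minus.ref_end - plus.ref_start != 9:
            continue
        plus_seq = seqs[(read_id, plus.mate)]
        minus_seq = seqs[(read_id, minus.mate)]
        if len(plus_seq) < 9 or len(minus_seq) < 9:
            continue
        if plus_seq[:9] != revcomp(minus_seq[:9]):
            continue
        start = min(plus.ref_start, minus.ref_start)
        end = max(plus.ref_end, minus.ref_end)
        clen = contig_lengths[s1.contig]
        if start < CONTIG_END_MARGIN or end > clen - CONTIG_END_MARGIN:
            continue
        calls.append(JunctionCall(
            contig=s1.contig, circle_start=start, circle_end=end,
            evidence="nine_bp_dup", supporting_read_ids=[read_id],
            library=library, cut_position=plus.ref_start))
    return calls


# ---------------------------------------------------------------------------
# TIR consensus around the TSD


def _motif_matches(seq: str, motif: str, max_mismatch: int) -> list[tuple[int, int]]:
    """(position, mismatches) of all windows within the mismatch budget."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    m = len(motif)
    if len(arr) < m:
        return []
    n_win = len(arr) - m + 1
    mism = np.zeros(n_win, dtype=np.int32)
    for j, ch in enumerate(motif.encode()):
        mism += arr[j:j + n_win] != bytes([ch])
    hits = np.nonzero(mism <= max_mismatch)[0]
    return [(int(i), int(mism[i])) for i in hits]


def tir_consensus(tbe_flank_sequences: Sequence[str], max_mismatch: int = 2):
    """Per-position nucleotide frequencies at positions +-1..+-8 around the TSDs.

    Each element (with flanking genomic sequence) is anchored by the two
    partially conserved telomeric motifs; positions 1-4 / -1..-4 are the
    flanking bases (4 / -4 immediately outside the TSD), 5-7 / -5..-7 the
    A-N-T target-site duplication, 8 / -8 the first base internal to the TIR.
    Elements where either anchor is not found are skipped and counted.

    Returns (counts, n_used, n_skipped) with counts[position][base] tallies.
    """
    positions = [p for p in range(1, 9)] + [-p for p in range(1, 9)]
    counts = {p: Counter() for p in positions}
    n_used = n_skipped = 0
    for seq in tbe_flank_sequences:
        left_hits = _motif_matches(seq, TIR_ANCHOR_LEFT, max_mismatch)
        right_hits = _motif_matches(seq, TIR_ANCHOR_RIGHT, max_mismatch)
        if not left_hits or not right_hits:
            n_skipped += 1
            continue
        lm = min(m for _, m in left_hits)
        m_left = min(i for i, m in left_hits if m == lm)
        rm = min(m for _, m in right_hits)
        m_right = max(i for i, m in right_hits if m == rm)
        t = m_left - 2       # TIR start (anchor sits 2 bp inside the TIR)
        e = m_right + 16     # TIR end
        if t - 7 < 0 or e + 7 > len(seq) or e <= t:
            n_skipped += 1
            continue
        # left side: ... pos1 pos2 pos3 pos4 | A N T | TIR ...
        for p in range(1, 5):
            counts[p][seq[t - 8 + p]] += 1
        for p, off in ((5, -3), (6, -2), (7, -1)):
            counts[p][seq[t + off]] += 1
        counts[8][seq[t]] += 1
        # right side: ... TIR | A N T | pos-4 pos-3 pos-2 pos-1 ...
        counts[-8][seq[e - 1]] += 1
        for p, off in ((-5, 0), (-6, 1), (-7, 2)):
            counts[p][seq[e + off]] += 1
        for p in range(1, 5):
            counts[-p][seq[e + 7 - p]] += 1
        n_used += 1
    return counts, n_used, n_skipped


def tir_frequencies(counts: dict[int, Counter]):
    """Normalize tir_consensus counts to per-position base frequencies."""
    freqs = {}
    for pos, ctr in counts.items():
        total = sum(ctr.values())
        freqs[pos] = {b: ctr.get(b, 0) / total for b in "ACGT"} if total else {}
    return freqs


# ---------------------------------------------------------------------------
# export


def write_junction_bed(calls: Sequence[JunctionCall], path: str) -> None:
    """BED6 + evidence + library columns."""
    with open(path, "w") as fh:
        for i, c in enumerate(sorted(calls, key=lambda c: (c.contig, c.circle_start))):
            fh.write(f"{c.contig}\t{c.circle_start}\t{c.circle_end}\t"
                     f"junction{i}\t{len(c.supporting_read_ids)}\t.\t"
                     f"{c.evidence}\t{c.library}\n")


def write_tbe_counts_tsv(counts_by_library: dict[str, TbeJunctionCount],
                         totals: dict[str, int], path: str) -> None:
    import pandas as pd

    from .circles import rpm

    rows = []
    for lib, tc in counts_by_library.items():
        row = {"library": lib, **tc.counts, "total": tc.total,
               "rpm": rpm(tc.total, totals[lib])}
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
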