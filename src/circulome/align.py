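"""Sequence file io and a desk-scale ungapped split-read mapper.

The mapper replaces external aligners for simulated, error-free reads: exact
k-mer seeding with ungapped extension, one primary segment per read, and a
supplementary segment when the read prefix and suffix map to discontiguous
loci (a chimeric split, the raw signal of a circle junction).  Mapping quality
is binary -- 60 for a unique best placement, 0 for ties -- because the only
downstream use is the MAPQ >= 5 filter.  Real-data users can instead feed
external SAM through :func:`read_sam`; all downstream modules accept either.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Sequence

import pysam

from .dna import revcomp


@dataclass
class AlignmentSegment:
    """One (possibly partial) ungapped placement of a read on the reference.

    `read_start`/`read_end` are offsets into the read in its own orientation;
    `ref_start`/`ref_end` are 0-based half-open reference coordinates.
    """

    read_id: str
    mate: int
    contig: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    strand: str
    mapq: int
    read_length: int
    secondary: bool = False
    supplementary: bool = False
    duplicate: bool = False
    unmapped: bool = False


@dataclass(frozen=True)
class Read:
    read_id: str
    mate: int
    sequence: str


def pairs_to_reads(pairs) -> list[Read]:
    """Flatten simulator read pairs to single-end reads (mates independent)."""
    reads = []
    for p in pairs:
        reads.append(Read(p.pair_id, 1, p.mate1_seq))
        reads.append(Read(p.pair_id, 2, p.mate2_seq))
    return reads


# ---------------------------------------------------------------------------
# mapping


class GenomeIndex:
    """Exact k-mer index over the forward strand of every contig."""

    def __init__(self, contigs: dict[str, str], k: int = 15):
        if not contigs:
            raise ValueError("empty genome")
        self.contigs = contigs
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in contigs.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((name, i))

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}


def _extend_forward(genome: str, pos: int, seq: str, start: int) -> int:
    """Length of the exact match of seq[start:] at genome[pos:] (N never matches)."""
    n = 0
    limit = min(len(seq) - start, len(genome) - pos)
    while n < limit:
        g, s = genome[pos + n], seq[start + n]
        if g != s or g == "N" or s == "N":
            break
        n += 1
    return n


def _extend_backward(genome: str, end: int, seq: str, send: int) -> int:
    """Length of the exact match of seq[:send] ending at genome[:end]."""
    n = 0
    limit = min(send, end)
    while n < limit:
        g, s = genome[end - 1 - n], seq[send - 1 - n]
        if g != s or g == "N" or s == "N":
            break
        n += 1
    return n


def _best_prefix(index: GenomeIndex, seq: str):
    """All placements achieving the longest exact prefix match (k-mer seeded)."""
    k = index.k
    seed = seq[:k]
    best_len, hits = 0, []
    for contig, pos in index.index.get(seed, ()):
        n = k + _extend_forward(index.contigs[contig], pos + k, seq, k)
        if n > best_len:
            best_len, hits = n, [(contig, pos)]
        elif n == best_len:
            hits.append((contig, pos))
    return best_len, sorted(hits)


def _best_suffix(index: GenomeIndex, seq: str):
    """All placements achieving the longest exact suffix match."""
    k = index.k
    seed = seq[-k:]
    best_len, hits = 0, []
    for contig, pos in index.index.get(seed, ()):
        genome = index.contigs[contig]
        n = k + _extend_backward(genome, pos, seq, len(seq) - k)
        if n > best_len:
            best_len, hits = n, [(contig, pos + k - n)]
        elif n == best_len:
            hits.append((contig, pos + k - n))
    return best_len, sorted(hits)


def _map_oriented(index: GenomeIndex, seq: str):
    """Map one orientation; returns (kind, payload) in this orientation's
    read coordinates.  kind is 'full', 'split' or None."""
    L = len(seq)
    if L < index.k:
        return None, None
    plen, phits = _best_prefix(index, seq)
    if plen == L and phits:
        return "full", (plen, phits)
    slen, shits = _best_suffix(index, seq)
    if slen == L and shits:
        return "full", (slen, shits)
    if plen >= index.k and slen >= index.k and plen + slen >= L and phits and shits:
        return "split", (plen, phits, slen, shits)
    return None, None


def _segment(read: Read, contig: str, ref_start: int, ref_end: int,
             s_start: int, s_end: int, strand: str, mapq: int,
             supplementary: bool) -> AlignmentSegment:
    L = len(read.sequence)
    if strand == "+":
        read_start, read_end = s_start, s_end
    else:  # oriented coords are on the reverse complement
        read_start, read_end = L - s_end, L - s_start
    return AlignmentSegment(
        read_id=read.read_id, mate=read.mate, contig=contig,
        ref_start=ref_start, ref_end=ref_end,
        read_start=read_start, read_end=read_end,
        strand=strand, mapq=mapq, read_length=L,
        supplementary=supplementary)


def map_read(index: GenomeIndex, read: Read) -> list[AlignmentSegment]:
    """Map one read; 0, 1 (primary) or 2 (primary + supplementary) segments."""
    L = len(read.sequence)
    results = {}
    for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
        kind, payload = _map_oriented(index, seq)
        if kind:
            results[strand] = (kind, payload, seq)

    full_hits = []
    for strand, (kind, payload, seq) in results.items():
        if kind == "full":
            for contig, pos in payload[1]:
                full_hits.append((contig, pos, strand))
    if full_hits:
        full_hits.sort()
        mapq = 60 if len(full_hits) == 1 else 0
        contig, pos, strand = full_hits[0]
        return [_segment(read, contig, pos, pos + L, 0, L, strand, mapq, False)]

    splits = {s: p for s, (k, p, _) in results.items() if k == "split"}
    if not splits:
        return []
    # prefer the orientation with most of the read explained
    strand = max(splits, key=lambda s: splits[s][0] + splits[s][2])
    plen, phits, slen, shits = splits[strand]
    pq = 60 if len(phits) == 1 else 0
    sq = 60 if len(shits) == 1 else 0
    pcontig, ppos = phits[0]
    scontig, spos = shits[0]

    # Both matches are maximal, so they may overlap on the read; the overlap is
    # assigned to the suffix segment (the prefix is trimmed).  At a circle
    # junction flanked by a direct repeat this pins the split to the leftmost
    # equivalent register, making calls deterministic across reads.
    overlap = plen + slen - L  # >= 0 by construction
    boundary = L - slen
    if plen - overlap <= 0:
        # prefix fully contained in the suffix match; keep the suffix alone
        return [_segment(read, scontig, spos, spos + slen,
                         boundary, L, strand, sq, False)]
    prefix_primary = (plen - overlap) >= slen
    segs = [
        _segment(read, pcontig, ppos, ppos + plen - overlap,
                 0, boundary, strand, pq, not prefix_primary),
        _segment(read, scontig, spos, spos + slen,
                 boundary, L, strand, sq, prefix_primary),
    ]
    return segs


def map_reads(reads: Sequence[Read], genome: dict[str, str] | GenomeIndex,
              seed_kmer: int = 15) -> list[AlignmentSegment]:
    """Map reads against the reference; see module docstring for the model."""
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, seed_kmer)
    if not reads:
        raise ValueError("no reads to map")
    segments = []
    for read in reads:
        segments.extend(map_read(index, read))
    return segments


# ---------------------------------------------------------------------------
# duplicate marking


def mark_duplicates(segments: Sequence[AlignmentSegment]) -> list[AlignmentSegment]:
    """Flag PCR duplicates: read pairs whose primary placements share
    (contig, ref_start, strand) for both mates.  The representative kept is
    the lexicographically smallest read_id, independent of input order."""
    primaries: dict[str, dict[int, AlignmentSegment]] = {}
    for seg in segments:
        if seg.secondary or seg.supplementary or seg.unmapped:
            continue
        primaries.setdefault(seg.read_id, {})[seg.mate] = seg

    groups: dict[tuple, list[str]] = {}
    for read_id, mates in primaries.items():
        key = tuple(
            (mates[m].contig, mates[m].ref_start, mates[m].strand)
            if m in mates else None
            for m in (1, 2)
        )
        groups.setdefault(key, []).append(read_id)

    dup_ids = set()
    for key, ids in groups.items():
        ids.sort()
        dup_ids.update(ids[1:])

    out = []
    for seg in segments:
        if seg.read_id in dup_ids and not seg.duplicate:
            seg = AlignmentSegment(**{**vars(seg), "duplicate": True})
        out.append(seg)
    return out


# ---------------------------------------------------------------------------
# SAM io (text; flags 0x100 secondary / 0x400 duplicate / 0x800 supplementary)


def write_sam(segments: Sequence[AlignmentSegment],
              contig_lengths: dict[str, int], path: str) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length}
               for name, length in contig_lengths.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for seg in segments:
            if seg.contig not in contig_lengths:
                raise ValueError(f"segment names unknown contig {seg.contig!r}")
            a = pysam.AlignedSegment(fh.header)
            a.query_name = seg.read_id
            flag = 0x1 | (0x40 if seg.mate == 1 else 0x80)
            if seg.strand == "-":
                flag |= 0x10
            if seg.secondary:
                flag |= 0x100
            if seg.duplicate:
                flag |= 0x400
            if seg.supplementary:
                flag |= 0x800
            if seg.unmapped:
                flag |= 0x4
            a.flag = flag
            a.reference_id = fh.header.get_tid(seg.contig)
            a.reference_start = seg.ref_start
            a.mapping_quality = seg.mapq
            m = seg.read_end - seg.read_start
            # clip lengths are expressed in the stored (ref-forward) orientation
            lead = seg.read_start if seg.strand == "+" else seg.read_length - seg.read_end
            trail = seg.read_length - m - lead
            cigar = []
            if lead:
                cigar.append((4, lead))
            cigar.append((0, m))
            if trail:
                cigar.append((4, trail))
            a.cigartuples = cigar
            fh.write(a)


def read_sam(path: str) -> tuple[list[AlignmentSegment], dict[str, int]]:
    """Parse a SAM text file (internal or from an external aligner) into
    alignment segments.  Gapped CIGARs are accepted; the reference span is
    taken from the alignment, the read interval from the clipping."""
    segments = []
    with pysam.AlignmentFile(path, "r") as fh:
        lengths = dict(zip(fh.references, fh.lengths))
        for a in fh:
            if a.is_unmapped:
                continue
            if a.reference_name not in lengths:
                raise ValueError(f"record names unknown contig {a.reference_name!r}")
            L = a.infer_read_length()
            qs, qe = a.query_alignment_start, a.query_alignment_end
            if a.is_reverse:
                read_start, read_end = L - qe, L - qs
            else:
                read_start, read_end = qs, qe
            segments.append(AlignmentSegment(
                read_id=a.query_name,
                mate=2 if a.is_read2 else 1,
                contig=a.reference_name,
                ref_start=a.reference_start,
                ref_end=a.reference_end,
                read_start=read_start,
                read_end=read_end,
                strand="-" if a.is_reverse else "+",
                mapq=a.mapping_quality,
                read_length=L,
                secondary=a.is_secondary,
                supplementary=a.is_supplementary,
                duplicate=a.is_duplicate,
            ))
    return segments, lengths


# ---------------------------------------------------------------------------
# FASTA / FASTQ readers (Biopython-backed)


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def read_fastq(path: str) -> list[Read]:
    from Bio import SeqIO

    opener = gzip.open if path.endswith(".gz") else open
    reads = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            read_id, _, mate = rec.id.partition("/")
            reads.append(Read(read_id, int(mate) if mate else 1, str(rec.seq).upper()))
    return reads
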