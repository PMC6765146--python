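"""Synthetic germline genome, circular excision products and read simulator.

This module builds a toy ciliate germline (MIC) genome with the annotation
vocabulary the analysis consumes -- macronuclear-destined sequences (MDSs),
pointers (the short direct repeats joining MAC-consecutive MDSs), internally
eliminated sequences (IESs), telomere-bearing transposons (TBEs) with ANT
target-site duplications, and chromosome breakage sites -- then excises
circular DNA molecules from it and emulates tagmentation-based paired-end
sequencing (Circulome-seq) and RNA-seq, carrying exhaustive ground truth.

Coordinates are 0-based half-open throughout.

Key modelling points
--------------------
* TBE excision is precise: the circle junction carries one TSD copy plus the
  two genomic bases immediately flanking the TSDs (a 5 bp staggered cut
  centred on the ANT), so the junction 5-mer reads (+4 base) A-N-T (-4 base);
  with the default flank composition the consensus junction is GANTC/G/A.
* IES excision is imprecise: each cut is drawn from a truncated normal around
  the start of a pointer copy (non-scrambled IESs) or around the inter-MDS
  gap boundary (scrambled IESs / intergenic regions).
* Tagmentation makes 9 bp staggered cuts; every fragment end internal to a
  molecule carries a 9 bp duplication, so a circle cut exactly once yields a
  read pair whose two 5' 9-mers coincide in genome space.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .dna import draw_base, random_dna, revcomp

# Telomeric motif phases used to build and anchor TBE terminal inverted
# repeats.  Left TIRs start with A4C4A4C4, right TIRs end with G4T4G4T4, so
# both the partially conserved anchor motifs (A2C4A4C4 / G4T4G4T2) and the
# 33-mer junction pattern find their expected registers.
TIR_LEFT_START = "AAAACCCCAAAACCCC"
TIR_RIGHT_END = "GGGGTTTTGGGGTTTT"

#: Composition of the base immediately outside each TSD copy (consensus of
#: 2636 germline TBEs; drives the junction-class mix GANTC/GANTG/GANTA).
DEFAULT_FLANK_BASE_COMPOSITION = {"A": 0.22, "C": 0.19, "G": 0.52, "T": 0.07}

#: Relative circle abundance per developmental time point.  Circles are
#: rearrangement products: absent in asexual growth, peaking mid-rearrangement.
CIRCLE_ABUNDANCE = {"asexual": 0.0, "early": 0.1, "mid": 1.0, "late": 0.4}


class SizingError(ValueError):
    """Requested features do not fit on a contig."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic genome and sequencing experiment."""

    n_contigs: int = 3
    contig_length: int = 40_000
    n_mac_loci: int = 6
    mds_per_locus: int = 4
    ies_length_range: tuple[int, int] = (80, 300)
    pointer_length_range: tuple[int, int] = (3, 7)  # non-scrambled, mean ~5
    scrambled_pointer_length_range: tuple[int, int] = (9, 13)  # mean ~11
    fraction_scrambled: float = 0.25
    n_tbe: int = 4
    tbe_length: int = 4_000
    read_length: int = 75
    insert_size_mean_sd: tuple[float, float] = (400.0, 100.0)
    depth: float = 20.0
    cut_offset_sd: float = 6.0
    exo_linear_survival: float = 0.05
    mds_length_range: tuple[int, int] = (120, 300)
    flank_base_composition: dict = field(
        default_factory=lambda: dict(DEFAULT_FLANK_BASE_COMPOSITION)
    )
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_contigs, self.contig_length, self.n_mac_loci,
               self.mds_per_locus, self.read_length) <= 0:
            raise ValueError("counts and lengths must be positive")
        if self.n_tbe < 0 or self.tbe_length <= 0:
            raise ValueError("TBE parameters must be non-negative / positive")
        if self.ies_length_range[0] < 57:
            # 57 bp is the smallest circularly excised IES; shorter IESs are
            # below the circularization limit of double-stranded DNA.
            raise ValueError("ies_length_range minimum must be >= 57 bp")
        for prop in (self.fraction_scrambled, self.exo_linear_survival):
            if not 0.0 <= prop <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        for lo, hi in (self.ies_length_range, self.pointer_length_range,
                       self.scrambled_pointer_length_range,
                       self.mds_length_range):
            if lo <= 0 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")
        if self.cut_offset_sd < 0:
            raise ValueError("cut_offset_sd must be non-negative")


def write_config(config: SimConfig, path: str) -> None:
    """Persist a config as flat key=value lines."""
    with open(path, "w") as fh:
        for key, value in vars(config).items():
            fh.write(f"{key}={value}\n")


# ---------------------------------------------------------------------------
# genome annotations


@dataclass(frozen=True)
class Mds:
    contig: str
    start: int
    end: int
    locus: int
    index: int  # 1-based position of this MDS in the somatic (MAC) product
    orientation: str  # '+' or '-'


@dataclass(frozen=True)
class Pointer:
    contig: str
    start: int
    end: int
    sequence: str  # MAC-frame pointer sequence; identical for both copies
    locus: int
    pair_index: int  # joins MAC MDS pair (pair_index, pair_index + 1)
    copy: str  # 'left' (tail of MDS n) or 'right' (head of MDS n+1)
    strand: str = "+"


@dataclass(frozen=True)
class Tbe:
    contig: str
    start: int  # start of left TIR
    end: int  # end of right TIR
    tsd: str  # 3-mer matching A-N-T, duplicated on both flanks
    tir_left: tuple[int, int]
    tir_right: tuple[int, int]


@dataclass(frozen=True)
class Ies:
    """Inter-MDS germline-limited segment (gap between MIC-adjacent MDSs)."""

    contig: str
    start: int
    end: int
    locus: int
    left_mac_index: int  # MAC index of the MDS on the MIC-left side
    right_mac_index: int
    scrambled: bool  # flanking MDSs not MAC-consecutive / inverted
    pointer_pair: Optional[int]  # pointer pair index when non-scrambled


@dataclass
class GenomeModel:
    contigs: dict[str, str]
    mds_annotations: list[Mds]
    pointers: list[Pointer]
    tbes: list[Tbe]
    breakage_sites: list[tuple[str, int]]
    ies: list[Ies] = field(default_factory=list)
    intergenic: list[tuple[str, int, int]] = field(default_factory=list)
    mac_sequences: dict[int, str] = field(default_factory=dict)

    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def ies_intervals(self) -> list[tuple[str, int, int]]:
        return [(i.contig, i.start, i.end) for i in self.ies]


def stitch_mac(genome: GenomeModel, locus: int) -> str:
    """Reassemble a MAC locus from its MIC MDSs, honoring order/orientation.

    Consecutive MDSs overlap by their pointer; one copy is retained at each
    MDS-MDS junction, as in the rearranged somatic product.
    """
    parts = sorted(
        (m for m in genome.mds_annotations if m.locus == locus),
        key=lambda m: m.index,
    )
    if not parts:
        raise KeyError(f"locus {locus} has no MDS annotations")
    pointer_len = {
        p.pair_index: p.end - p.start
        for p in genome.pointers
        if p.locus == locus and p.copy == "left"
    }
    out = []
    for n, m in enumerate(parts, start=1):
        seg = genome.contigs[m.contig][m.start:m.end]
        if m.orientation == "-":
            seg = revcomp(seg)
        if n == 1:
            out.append(seg)
        else:
            out.append(seg[pointer_len[n - 1]:])
    return "".join(out)


# ---------------------------------------------------------------------------
# genome construction


def _build_locus(rng: np.random.Generator, config: SimConfig, locus: int,
                 scrambled: bool):
    """Return (mic_seq, mac_seq, local annotations) for one MAC locus.

    The MAC locus is generated first; MDSs are windows of it that overlap by
    their pointer, so the pointer sequence is duplicated on the MIC copy of
    both MAC-consecutive MDSs by construction.
    """
    k = config.mds_per_locus
    p_range = (config.scrambled_pointer_length_range if scrambled
               else config.pointer_length_range)
    p_lens = [int(rng.integers(p_range[0], p_range[1] + 1)) for _ in range(k - 1)]
    cores = [int(rng.integers(*config.mds_length_range)) for _ in range(k)]

    # MAC spans: MDS n = mac[a_n:b_n]; MDS n+1 starts p_n before b_n.
    spans = []
    a = 0
    for n in range(k):
        left = p_lens[n - 1] if n > 0 else 0
        right = p_lens[n] if n < k - 1 else 0
        b = a + left + cores[n] + right
        spans.append((a, b))
        a = b - right
    mac_seq = random_dna(rng, spans[-1][1])

    if scrambled:
        while True:
            order = [int(i) for i in rng.permutation(k)]
            if order != list(range(k)):
                break
        orient = ["-" if rng.random() < 0.3 else "+" for _ in range(k)]
    else:
        order = list(range(k))
        orient = ["+"] * k

    parts: list[str] = []
    mds_local: list[dict] = []  # local-offset annotations
    ies_local: list[dict] = []
    offset = 0
    for j, idx in enumerate(order):
        a, b = spans[idx]
        seg = mac_seq[a:b]
        if orient[idx] == "-":
            seg = revcomp(seg)
        parts.append(seg)
        mds_local.append({
            "start": offset, "end": offset + len(seg), "index": idx + 1,
            "orientation": orient[idx],
        })
        offset += len(seg)
        if j < k - 1:
            ies_len = int(rng.integers(config.ies_length_range[0],
                                       config.ies_length_range[1] + 1))
            nxt = order[j + 1]
            consecutive = (nxt == idx + 1 and orient[idx] == "+"
                           and orient[nxt] == "+")
            ies_local.append({
                "start": offset, "end": offset + ies_len,
                "left_mac_index": idx + 1, "right_mac_index": nxt + 1,
                "scrambled": not consecutive,
                "pointer_pair": idx + 1 if consecutive else None,
            })
            parts.append(random_dna(rng, ies_len))
            offset += ies_len

    pointer_local: list[dict] = []
    by_index = {m["index"]: m for m in mds_local}
    for n in range(1, k):  # pointer pair n joins MAC MDSs n and n+1
        a_next = spans[n][0]
        b_prev = spans[n - 1][1]
        p_seq = mac_seq[a_next:b_prev]
        for which, mac_idx in (("left", n), ("right", n + 1)):
            m = by_index[mac_idx]
            length = len(p_seq)
            if which == "left":  # last `length` MAC bases of MDS n
                local = ((m["end"] - length, m["end"]) if m["orientation"] == "+"
                         else (m["start"], m["start"] + length))
            else:  # first `length` MAC bases of MDS n+1
                local = ((m["start"], m["start"] + length) if m["orientation"] == "+"
                         else (m["end"] - length, m["end"]))
            pointer_local.append({
                "start": local[0], "end": local[1], "sequence": p_seq,
                "pair_index": n, "copy": which,
                "strand": m["orientation"],
            })
    return "".join(parts), mac_seq, mds_local, ies_local, pointer_local


def _build_tbe(rng: np.random.Generator, config: SimConfig):
    """Return (insert_seq, tsd, local tbe annotation).

    Insert layout: [B+4][ANT][TIR_L ... body ... TIR_R][ANT][B-4], with the
    TSD duplicated on both flanks and the two +-4 bases drawn from the
    configured flank composition.
    """
    tsd = "A" + random_dna(rng, 1) + "T"
    b_left = draw_base(rng, config.flank_base_composition)
    b_right = draw_base(rng, config.flank_base_composition)
    inner = config.tbe_length - len(TIR_LEFT_START) - len(TIR_RIGHT_END)
    if inner < 10:
        raise ValueError("tbe_length too short for terminal inverted repeats")
    element = TIR_LEFT_START + random_dna(rng, inner) + TIR_RIGHT_END
    insert = b_left + tsd + element + tsd + b_right
    return insert, element, tsd, b_left, b_right


def build_genome(config: SimConfig) -> GenomeModel:
    """Generate a MIC genome with MDS/pointer/TBE/breakage annotations."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    contig_names = [f"contig{i + 1}" for i in range(config.n_contigs)]
    # Round-robin feature assignment: loci first, then TBEs.
    features: dict[str, list] = {name: [] for name in contig_names}
    scrambled_flags = [
        i < round(config.fraction_scrambled * config.n_mac_loci)
        for i in range(config.n_mac_loci)
    ]
    rng.shuffle(scrambled_flags)
    for i in range(config.n_mac_loci):
        features[contig_names[i % config.n_contigs]].append(("locus", i, scrambled_flags[i]))
    for t in range(config.n_tbe):
        features[contig_names[t % config.n_contigs]].append(("tbe", t, None))

    genome = GenomeModel(contigs={}, mds_annotations=[], pointers=[],
                         tbes=[], breakage_sites=[])

    for name in contig_names:
        parts: list[str] = []
        offset = 0

        def _append(seq: str):
            nonlocal offset
            parts.append(seq)
            offset += len(seq)

        _append(random_dna(rng, int(rng.integers(400, 700))))
        prev_kind = None
        prev_locus_end = None
        for kind, ident, flag in features[name]:
            if kind == "locus":
                mic_seq, mac_seq, mds_loc, ies_loc, ptr_loc = _build_locus(
                    rng, config, ident, flag)
                if prev_kind == "locus":
                    # chromosome breakage site between two MAC loci
                    gap_start = prev_locus_end
                    genome.breakage_sites.append(
                        (name, (gap_start + offset) // 2))
                    genome.intergenic.append((name, gap_start, offset))
                base = offset
                for m in mds_loc:
                    genome.mds_annotations.append(Mds(
                        name, base + m["start"], base + m["end"],
                        ident, m["index"], m["orientation"]))
                for p in ptr_loc:
                    genome.pointers.append(Pointer(
                        name, base + p["start"], base + p["end"],
                        p["sequence"], ident, p["pair_index"], p["copy"],
                        p["strand"]))
                for i in ies_loc:
                    genome.ies.append(Ies(
                        name, base + i["start"], base + i["end"], ident,
                        i["left_mac_index"], i["right_mac_index"],
                        i["scrambled"], i["pointer_pair"]))
                genome.mac_sequences[ident] = mac_seq
                _append(mic_seq)
                prev_locus_end = offset
            else:
                insert, element, tsd, _, _ = _build_tbe(rng, config)
                el_start = offset + 4  # B+4 + TSD precede the element
                genome.tbes.append(Tbe(
                    name, el_start, el_start + len(element), tsd,
                    (el_start, el_start + len(TIR_LEFT_START)),
                    (el_start + len(element) - len(TIR_RIGHT_END),
                     el_start + len(element))))
                _append(insert)
            _append(random_dna(rng, int(rng.integers(400, 800))))
            prev_kind = kind
        if offset > config.contig_length:
            raise SizingError(
                f"contig {name}: features need {offset} bp but "
                f"contig_length is {config.contig_length}")
        _append(random_dna(rng, config.contig_length - offset))
        genome.contigs[name] = "".join(parts)

    return genome


# ---------------------------------------------------------------------------
# circular excision


@dataclass(frozen=True)
class CircularMolecule:
    molecule_id: str
    sequence: str
    origin_contig: str
    left_cut: int
    right_cut: int
    category: str  # tbe | non_scrambled_ies | scrambled_ies | intergenic
    junction_motif: Optional[str] = None  # central 5-mer for TBE circles
    topology: str = "relaxed_circle"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LinearMolecule:
    molecule_id: str
    sequence: str
    contig: str
    start: int
    end: int


def _noisy_cut(rng: np.random.Generator, center: int, sd: float,
               lo: int, hi: int) -> int:
    """Truncated-normal integer draw in [lo, hi] around `center`."""
    if sd == 0:
        return int(np.clip(center, lo, hi))
    for _ in range(100):
        c = int(round(rng.normal(center, sd)))
        if lo <= c <= hi:
            return c
    return int(np.clip(center, lo, hi))


def excise_circles(genome: GenomeModel, config: SimConfig, seed: int,
                   events_per_site: int = 1) -> list[CircularMolecule]:
    """Excise circular molecules from every annotated eliminated locus.

    TBEs excise precisely (identical junction for every event); IESs and
    intergenic regions excise with per-event cut noise of `cut_offset_sd`.
    """
    rng = np.random.default_rng(seed)
    circles: list[CircularMolecule] = []
    serial = 0

    pointer_map = {
        (p.locus, p.pair_index, p.copy): p for p in genome.pointers
    }

    for tbe in genome.tbes:
        seq = genome.contigs[tbe.contig]
        element = seq[tbe.start:tbe.end]
        # One resolved junction strand: G + TSD + X, with X copied from the
        # base immediately outside the TSD (the -4 flank position).  The
        # heteroduplex produced by the 5 bp staggered cut is not modeled.
        b_minus4 = seq[tbe.end + 3]
        motif = "G" + tbe.tsd + b_minus4
        for _ in range(events_per_site):
            circles.append(CircularMolecule(
                molecule_id=f"circ{serial}",
                sequence=element + motif,
                origin_contig=tbe.contig,
                left_cut=tbe.start - 1,
                right_cut=tbe.end + 4,
                category="tbe",
                junction_motif=motif,
            ))
            serial += 1

    for ies in genome.ies:
        seq = genome.contigs[ies.contig]
        clen = len(seq)
        if ies.scrambled or ies.pointer_pair is None:
            left_center, right_center = ies.start, ies.end
            category = "scrambled_ies"
        else:
            left_ptr = pointer_map[(ies.locus, ies.pointer_pair, "left")]
            right_ptr = pointer_map[(ies.locus, ies.pointer_pair, "right")]
            left_center, right_center = left_ptr.start, right_ptr.start
            category = "non_scrambled_ies"
        for _ in range(events_per_site):
            for _ in range(100):  # resample degenerate draws
                left = _noisy_cut(rng, left_center, config.cut_offset_sd, 0, clen)
                right = _noisy_cut(rng, right_center, config.cut_offset_sd, 0, clen)
                if right - left >= 1:
                    break
            circles.append(CircularMolecule(
                molecule_id=f"circ{serial}",
                sequence=seq[left:right],
                origin_contig=ies.contig,
                left_cut=left,
                right_cut=right,
                category=category,
            ))
            serial += 1

    for contig, start, end in genome.intergenic:
        seq = genome.contigs[contig]
        clen = len(seq)
        for _ in range(events_per_site):
            for _ in range(100):
                left = _noisy_cut(rng, start, config.cut_offset_sd, 0, clen)
                right = _noisy_cut(rng, end, config.cut_offset_sd, 0, clen)
                if right - left >= 1:
                    break
            circles.append(CircularMolecule(
                molecule_id=f"circ{serial}",
                sequence=seq[left:right],
                origin_contig=contig,
                left_cut=left,
                right_cut=right,
                category="intergenic",
            ))
            serial += 1

    return circles


def exonuclease_filter(molecules: Sequence, survival: float,
                       seed: int) -> list:
    """Digest linear molecules: circles survive, linears survive w.p. `survival`."""
    if not 0.0 <= survival <= 1.0:
        raise ValueError("survival must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    kept = []
    for mol in molecules:
        if isinstance(mol, CircularMolecule):
            kept.append(mol)
        elif survival >= 1.0 or rng.random() < survival:
            kept.append(mol)
    return kept


# ---------------------------------------------------------------------------
# tagmentation and read generation


@dataclass
class ReadPairTruth:
    pair_id: str
    mate1_seq: str
    mate2_seq: str
    origin_id: str
    origin_kind: str  # 'circle' | 'linear'
    library: str
    spans_junction: bool = False
    has_9bp_dup: bool = False
    truncated: bool = False
    n_cuts: int = 0
    frag_start: int = 0  # molecule coordinate of the fragment start
    frag_len: int = 0
    mate1_ref: Optional[tuple] = None  # (contig, start, end, strand)
    mate2_ref: Optional[tuple] = None
    category: Optional[str] = None


DUP_LEN = 9  # tagmentation staggered-cut length
MIN_FRAGMENT = 30


def tagment_circle(sequence: str, cuts: Sequence[int]) -> list[tuple[str, int]]:
    """Fragment a circular molecule at the given cut positions.

    Returns (fragment_sequence, fragment_start) tuples in molecule
    coordinates.  Every fragment carries the 9 bp downstream of its right cut
    duplicated at its end; a single cut linearizes the whole circle so both
    fragment ends share the same 9-mer.
    """
    L = len(sequence)
    cuts = sorted(set(int(c) % L for c in cuts))
    if not cuts:
        return []
    doubled = sequence + sequence + sequence[:DUP_LEN]
    frags = []
    for i, c in enumerate(cuts):
        nxt = cuts[(i + 1) % len(cuts)]
        span = (nxt - c) % L or L  # single cut -> whole circle
        frags.append((doubled[c:c + span + DUP_LEN], c))
    return frags


def tagment_linear(sequence: str, cuts: Sequence[int]) -> list[tuple[str, int]]:
    """Fragment a linear molecule; outer ends carry no duplication."""
    L = len(sequence)
    cuts = sorted(set(int(c) for c in cuts if 0 < c < L))
    bounds = [0] + cuts + [L]
    frags = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        end = min(b + DUP_LEN, L) if b != L else L
        frags.append((sequence[a:end], a))
    return frags


def _crosses(a: int, b: int, L: int) -> bool:
    """True if unwrapped molecule interval [a, b) strictly contains a
    junction point (a positive multiple of L)."""
    k = L
    while k < b:
        if a < k < b:
            return True
        k += L
    return False


def pair_from_fragment(fragment: str, read_length: int) -> tuple[str, str, bool]:
    """Sequence the two ends of a fragment (mate2 reverse-complemented)."""
    truncated = len(fragment) < read_length
    mate1 = fragment[:read_length]
    mate2 = revcomp(fragment[-read_length:]) if not truncated else revcomp(fragment)
    return mate1, mate2, truncated


def tagment_and_read(molecules: Sequence[CircularMolecule],
                     linear_background: Sequence[LinearMolecule],
                     config: SimConfig, library: str,
                     seed: int) -> list[ReadPairTruth]:
    """Tagment circular and linear molecules into ground-truthed read pairs.

    Callers model exonuclease enrichment by passing the linear background
    through :func:`exonuclease_filter` first (+exo libraries).
    """
    rng = np.random.default_rng(seed)
    insert_mean, insert_sd = config.insert_size_mean_sd
    max_insert = insert_mean + 4 * insert_sd
    pairs: list[ReadPairTruth] = []
    serial = 0

    def _emit(frags, mol, is_circle, n_cuts, L):
        nonlocal serial
        for frag, fstart in frags:
            if len(frag) < MIN_FRAGMENT or len(frag) > max_insert:
                continue
            m1, m2, trunc = pair_from_fragment(frag, config.read_length)
            spans = False
            mate1_ref = mate2_ref = None
            if is_circle:
                a1, b1 = fstart, fstart + len(m1)
                a2 = fstart + len(frag) - len(m2)
                b2 = fstart + len(frag)
                spans = _crosses(a1, b1, L) or _crosses(a2, b2, L)
            else:
                mate1_ref = (mol.contig, mol.start + fstart,
                             mol.start + fstart + len(m1), "+")
                mate2_ref = (mol.contig, mol.start + fstart + len(frag) - len(m2),
                             mol.start + fstart + len(frag), "-")
            pairs.append(ReadPairTruth(
                pair_id=f"{library}:p{serial}",
                mate1_seq=m1, mate2_seq=m2,
                origin_id=mol.molecule_id,
                origin_kind="circle" if is_circle else "linear",
                library=library,
                spans_junction=spans,
                has_9bp_dup=is_circle and n_cuts == 1,
                truncated=trunc,
                n_cuts=n_cuts,
                frag_start=fstart,
                frag_len=len(frag),
                mate1_ref=mate1_ref,
                mate2_ref=mate2_ref,
                category=getattr(mol, "category", None),
            ))
            serial += 1

    for mol in molecules:
        L = len(mol.sequence)
        if L < MIN_FRAGMENT:
            continue
        n_cuts = max(1, int(rng.poisson(L / insert_mean)))
        n_cuts = min(n_cuts, L)
        cuts = rng.choice(L, size=n_cuts, replace=False)
        _emit(tagment_circle(mol.sequence, cuts), mol, True, n_cuts, L)

    for mol in linear_background:
        L = len(mol.sequence)
        if L < MIN_FRAGMENT:
            continue
        n_cuts = int(rng.poisson(L / insert_mean))
        cuts = rng.choice(max(L - 1, 1), size=min(n_cuts, L - 1),
                          replace=False) + 1 if n_cuts else []
        _emit(tagment_linear(mol.sequence, cuts), mol, False, n_cuts, L)

    return pairs


def sample_linear_background(genome: GenomeModel, config: SimConfig,
                             seed: int, mean_length: int = 2000,
                             coverage_factor: float = 0.5) -> list[LinearMolecule]:
    """Random genomic windows standing in for sheared linear chromosomes and
    not-yet-rearranged precursor DNA (the -exo background)."""
    rng = np.random.default_rng(seed)
    names = list(genome.contigs)
    lengths = np.array([len(genome.contigs[n]) for n in names], dtype=float)
    total = lengths.sum()
    n_mol = max(1, int(total * config.depth * coverage_factor / mean_length))
    mols = []
    for i in range(n_mol):
        ci = rng.choice(len(names), p=lengths / total)
        contig = names[ci]
        clen = int(lengths[ci])
        length = int(np.clip(rng.normal(mean_length, mean_length / 4),
                             MIN_FRAGMENT, clen))
        start = int(rng.integers(0, clen - length + 1))
        mols.append(LinearMolecule(
            molecule_id=f"lin{i}", contig=contig, start=start,
            end=start + length,
            sequence=genome.contigs[contig][start:start + length]))
    return mols


# ---------------------------------------------------------------------------
# library grid


@dataclass(frozen=True)
class Library:
    label: str
    timepoint: str  # asexual | early | mid | late
    replicate: int
    exo: bool  # exonuclease-enriched?


#: Fixed experimental grid: asexual x2, early x2, mid x2 (+exo),
#: mid x1 (-exo), late x1.
LIBRARY_GRID = (
    Library("asexual_r1", "asexual", 1, True),
    Library("asexual_r2", "asexual", 2, True),
    Library("early_r1", "early", 1, True),
    Library("early_r2", "early", 2, True),
    Library("mid_r1", "mid", 1, True),
    Library("mid_r2", "mid", 2, True),
    Library("mid_noexo_r1", "mid", 1, False),
    Library("late_r1", "late", 1, True),
)


def simulate_library(genome: GenomeModel, circles: Sequence[CircularMolecule],
                     config: SimConfig, library: Library,
                     seed: int) -> list[ReadPairTruth]:
    """Simulate one Circulome-seq library from the shared circle pool."""
    rng = np.random.default_rng(seed)
    insert_mean = config.insert_size_mean_sd[0]
    scale = CIRCLE_ABUNDANCE[library.timepoint]
    copies_mean = config.depth * scale * insert_mean / (2 * config.read_length)
    molecules: list[CircularMolecule] = []
    for i, circ in enumerate(circles):
        for c in range(int(rng.poisson(copies_mean))):
            molecules.append(replace(circ, molecule_id=f"{circ.molecule_id}"))
    linear = sample_linear_background(genome, config,
                                      seed=int(rng.integers(2 ** 31)))
    if library.exo:
        linear = exonuclease_filter(linear, config.exo_linear_survival,
                                    seed=int(rng.integers(2 ** 31)))
    return tagment_and_read(molecules, linear, config, library.label,
                            seed=int(rng.integers(2 ** 31)))


def simulate_experiment(config: SimConfig, events_per_site: int = 1):
    """Build the genome, excise circles and simulate the full library grid.

    Returns (genome, circles, {library label: list[ReadPairTruth]}).
    """
    genome = build_genome(config)
    rng = np.random.default_rng(config.seed + 1)
    circles = excise_circles(genome, config, seed=int(rng.integers(2 ** 31)),
                             events_per_site=events_per_site)
    libraries = {}
    for lib in LIBRARY_GRID:
        libraries[lib.label] = simulate_library(
            genome, circles, config, lib, seed=int(rng.integers(2 ** 31)))
    return genome, circles, libraries


# ---------------------------------------------------------------------------
# RNA-seq simulation


@dataclass(frozen=True)
class TssModel:
    """Per-circle transcription model.

    Transcription starts near the circle junction (offset ~ N(0, tss_offset_sd)
    in circle coordinates), either strand, and may read through the junction on
    the circular template.
    """

    rate: float = 3.0  # expected transcripts per transcribed circle per depth unit
    transcribed_fraction: float = 0.3
    tss_offset_sd: float = 10.0
    transcript_length_range: tuple[int, int] = (200, 1200)
    bidirectional: bool = True
    #: explicit molecule_ids of the transcribed circles; when None, each
    #: circle transcribes with probability `transcribed_fraction`
    transcribed_ids: Optional[tuple[str, ...]] = None


@dataclass(frozen=True)
class RnaRead:
    read_id: str
    sequence: str
    library: str
    origin: str  # circle molecule_id or 'background'
    crosses_junction: bool = False


def simulate_rnaseq(circles: Sequence[CircularMolecule], tss_model: TssModel,
                    depth: float, seed: int, genome: Optional[GenomeModel] = None,
                    read_length: int = 75,
                    timepoints: Sequence[str] = ("pre", "mid"),
                    background_per_bp: float = 0.02,
                    noise_per_bp: float = 0.002) -> dict[str, list[RnaRead]]:
    """Simulate RNA-seq for pre- and mid-rearrangement time points.

    Circle-derived transcripts are emitted only at 'mid'.  Two backgrounds
    appear at every time point: genic transcription (reads sampled from MDS
    intervals at `background_per_bp`) and a low genome-wide noise floor
    (`noise_per_bp`, spurious transcription / library noise).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[RnaRead]] = {tp: [] for tp in timepoints}
    lo, hi = tss_model.transcript_length_range

    if tss_model.transcribed_ids is not None:
        transcribed = [c for c in circles
                       if c.molecule_id in tss_model.transcribed_ids
                       and len(c.sequence) >= read_length]
    else:
        transcribed = [
            c for c in circles
            if len(c.sequence) >= read_length
            and rng.random() < tss_model.transcribed_fraction
        ]

    serial = 0
    for tp in timepoints:
        if genome is not None:
            for m in genome.mds_annotations:
                span = m.end - m.start
                n_bg = rng.poisson(span * background_per_bp * depth / read_length)
                for _ in range(n_bg):
                    if span <= read_length:
                        continue
                    o = int(rng.integers(0, span - read_length))
                    seq = genome.contigs[m.contig][m.start + o:m.start + o + read_length]
                    out[tp].append(RnaRead(f"rna:{tp}:{serial}", seq, tp, "background"))
                    serial += 1
            for contig, cseq in genome.contigs.items():
                n_noise = rng.poisson(len(cseq) * noise_per_bp * depth / read_length)
                for _ in range(n_noise):
                    o = int(rng.integers(0, len(cseq) - read_length))
                    out[tp].append(RnaRead(
                        f"rna:{tp}:{serial}", cseq[o:o + read_length], tp,
                        "background"))
                    serial += 1
        if tp != "mid" or tss_model.rate <= 0:
            continue
        for circ in transcribed:
            L = len(circ.sequence)
            base = circ.sequence * 3
            n_tx = rng.poisson(tss_model.rate * depth)
            for _ in range(n_tx):
                tss = int(round(rng.normal(0, tss_model.tss_offset_sd))) % L
                length = int(rng.integers(lo, hi + 1))
                length = min(length, 2 * L)
                strand = "-" if (tss_model.bidirectional and rng.random() < 0.5) else "+"
                if strand == "+":
                    tx = base[L + tss:L + tss + length]
                else:
                    tx = revcomp(base[L + tss + 1 - length:L + tss + 1])
                if len(tx) < read_length:
                    continue
                n_reads = max(1, int(rng.poisson(len(tx) / (2 * read_length))))
                for _ in range(n_reads):
                    o = int(rng.integers(0, len(tx) - read_length + 1))
                    seq = tx[o:o + read_length]
                    # A read crosses the junction iff it is not contained in
                    # the linear representation of the circle (either strand).
                    crosses = (seq not in circ.sequence
                               and revcomp(seq) not in circ.sequence)
                    out[tp].append(RnaRead(
                        f"rna:{tp}:{serial}", seq, tp, circ.molecule_id, crosses))
                    serial += 1
    return out


# ---------------------------------------------------------------------------
# file export


def write_fasta(contigs: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def write_fastq_pairs(pairs: Sequence[ReadPairTruth], prefix: str) -> tuple[str, str]:
    """Write mate FASTQ files `<prefix>_1.fastq[.gz]` / `_2`."""
    suffix = ".fastq.gz"
    paths = (prefix + "_1" + suffix, prefix + "_2" + suffix)
    for mate, path in enumerate(paths, start=1):
        with gzip.open(path, "wt") as fh:
            for p in pairs:
                seq = p.mate1_seq if mate == 1 else p.mate2_seq
                fh.write(f"@{p.pair_id}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")
    return paths


def write_annotation_beds(genome: GenomeModel, prefix: str) -> None:
    """BED6(+) tracks for MDSs, pointers, TBEs and breakage sites."""
    with open(prefix + ".mds.bed", "w") as fh:
        for m in genome.mds_annotations:
            fh.write(f"{m.contig}\t{m.start}\t{m.end}\t"
                     f"locus{m.locus}_mds{m.index}\t0\t{m.orientation}\n")
    with open(prefix + ".pointers.bed", "w") as fh:
        for p in genome.pointers:
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\t"
                     f"locus{p.locus}_ptr{p.pair_index}_{p.copy}\t0\t{p.strand}"
                     f"\t{p.sequence}\n")
    with open(prefix + ".tbe.bed", "w") as fh:
        for i, t in enumerate(genome.tbes):
            fh.write(f"{t.contig}\t{t.start}\t{t.end}\ttbe{i}\t0\t+\t{t.tsd}\n")
    with open(prefix + ".breakage.bed", "w") as fh:
        for contig, pos in genome.breakage_sites:
            fh.write(f"{contig}\t{pos}\t{pos + 1}\tbreakage\t0\t.\n")


def write_truth_tsv(pairs: Sequence[ReadPairTruth], path: str) -> None:
    import pandas as pd

    pd.DataFrame([vars(p) for p in pairs]).to_csv(path, sep="\t", index=False)
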