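"""Characterization of high-confidence circles against rearrangement annotations.

Covers: distance from circle boundaries to the nearest MDS boundary (with a
shuffle null over the assembly), cut-site compartment (pointer / IES / MDS)
for boundaries near MDSs, cryptic direct repeats flanking the circularization
point, eliminated-sequence category (non-scrambled IES / scrambled IES /
intergenic), and the supporting statistics (interval shuffles, two-sample
Kolmogorov-Smirnov, chi-squared contingency).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .simulate import GenomeModel, Mds, Pointer

#: Fig-5A-style distance bins: [0,49], [50,249], [250,999], [1000,2000],
#: then >2000 bp or MDS-lacking contig.  Configurable; edges are a reporting
#: choice, not a claim about any external dataset.
DEFAULT_DISTANCE_EDGES = (0, 50, 250, 1000, 2001)
DISTANCE_BIN_LABELS = ("0-49", "50-249", "250-999", "1000-2000", ">2000/none")

NO_MDS = math.inf  # sentinel for circles on MDS-lacking contigs


@dataclass
class CutSiteAnnotation:
    circle_id: str
    side: str  # 'left' | 'right'
    position: int
    distance_to_mds: float
    compartment: Optional[str]  # 'pointer' | 'IES' | 'MDS' | None
    offset_from_pointer: Optional[int]
    within_50bp_window: bool
    unclassifiable: bool = False


@dataclass
class NullDistribution:
    observed: float
    replicates: np.ndarray
    n_shuffles: int
    mean: float
    sd: float
    percentile: float  # fraction of replicates strictly below the observed

    @classmethod
    def from_replicates(cls, observed: float, replicates) -> "NullDistribution":
        reps = np.asarray(list(replicates), dtype=float)
        return cls(observed=float(observed), replicates=reps,
                   n_shuffles=len(reps), mean=float(reps.mean()),
                   sd=float(reps.std(ddof=1)) if len(reps) > 1 else 0.0,
                   percentile=float((reps < observed).mean()))


# ---------------------------------------------------------------------------
# distances to MDS boundaries


def _mds_boundaries(mds_annotations: Sequence[Mds]) -> dict[str, np.ndarray]:
    per_contig: dict[str, list[int]] = {}
    for m in mds_annotations:
        per_contig.setdefault(m.contig, []).extend((m.start, m.end))
    return {c: np.unique(v) for c, v in per_contig.items()}


def _nearest(boundaries: np.ndarray, pos: int) -> float:
    return float(np.abs(boundaries - pos).min())


def distance_to_mds(circle, mds_annotations: Sequence[Mds],
                    _boundaries: Optional[dict] = None) -> float:
    """Minimum over both circle boundaries of the distance to the nearest MDS
    boundary on the same contig; inf sentinel when the contig has no MDS."""
    d = per_end_distances(circle, mds_annotations, _boundaries)
    return min(d)


def per_end_distances(circle, mds_annotations: Sequence[Mds],
                      _boundaries: Optional[dict] = None) -> tuple[float, float]:
    contig, start, end = (circle if isinstance(circle, tuple)
                          else (circle.contig, circle.start, circle.end))
    boundaries = _boundaries if _boundaries is not None else _mds_boundaries(mds_annotations)
    if contig not in boundaries or len(boundaries[contig]) == 0:
        return (NO_MDS, NO_MDS)
    b = boundaries[contig]
    return (_nearest(b, start), _nearest(b, end))


def bin_distances(distances: Sequence[float],
                  edges: Sequence[int] = DEFAULT_DISTANCE_EDGES,
                  labels: Sequence[str] = DISTANCE_BIN_LABELS):
    """Histogram of MDS distances as frequencies summing to 1.

    The last bin collects everything beyond the final edge, including the
    inf sentinel for MDS-lacking contigs.
    """
    distances = list(distances)
    if not distances:
        raise ValueError("no distances to bin")
    counts = Counter()
    for d in distances:
        label = labels[-1]
        for i in range(len(edges) - 1):
            if edges[i] <= d < edges[i + 1]:
                label = labels[i]
                break
        counts[label] += 1
    n = len(distances)
    return {label: counts.get(label, 0) / n for label in labels}


def mds_distance_null(circles, genome: GenomeModel, n_shuffles: int = 500,
                      seed: int = 0, edges=DEFAULT_DISTANCE_EDGES,
                      labels=DISTANCE_BIN_LABELS):
    """Observed distance-bin frequencies vs a shuffle null over the assembly.

    Returns a table with, per bin, the observed frequency and the null mean
    with a three-standard-deviation envelope.
    """
    import pandas as pd

    boundaries = _mds_boundaries(genome.mds_annotations)
    intervals = [c if isinstance(c, tuple) else (c.contig, c.start, c.end)
                 for c in circles]
    observed = bin_distances(
        [distance_to_mds(iv, genome.mds_annotations, boundaries) for iv in intervals],
        edges, labels)
    domain = [(name, 0, len(seq)) for name, seq in genome.contigs.items()]
    reps = {label: [] for label in labels}
    for rep in shuffle_intervals(intervals, domain, n_shuffles, seed):
        freqs = bin_distances(
            [distance_to_mds(iv, genome.mds_annotations, boundaries) for iv in rep],
            edges, labels)
        for label in labels:
            reps[label].append(freqs[label])
    rows = []
    for label in labels:
        arr = np.array(reps[label])
        rows.append({"bin": label, "observed": observed[label],
                     "null_mean": arr.mean(), "null_sd": arr.std(ddof=1),
                     "null_lo3sd": arr.mean() - 3 * arr.std(ddof=1),
                     "null_hi3sd": arr.mean() + 3 * arr.std(ddof=1)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cut-site compartments


def classify_cut_sites(circles, pointers: Sequence[Pointer],
                       mds_annotations: Sequence[Mds], window: int = 50):
    """Assign each qualifying circle boundary to pointer / IES / MDS.

    Only boundaries within `window` bp of an MDS boundary are classified.  The
    signed pointer offset is measured from the proximal edge of the nearest
    pointer copy: negative into the MDS, positive into the IES, 0 inside the
    pointer.  Returns (annotations, compartment counts, KS samples) where the
    KS samples are the |distance to the nearest MDS boundary| of cut sites
    inside IESs vs inside MDSs.
    """
    boundaries = _mds_boundaries(mds_annotations)
    mds_by_contig: dict[str, list[Mds]] = {}
    for m in mds_annotations:
        mds_by_contig.setdefault(m.contig, []).append(m)
    ptr_by_contig: dict[str, list[Pointer]] = {}
    for p in pointers:
        ptr_by_contig.setdefault(p.contig, []).append(p)

    annotations: list[CutSiteAnnotation] = []
    counts = Counter()
    ks_samples = {"IES": [], "MDS": []}

    for circ in circles:
        contig, start, end = (circ if isinstance(circ, tuple)
                              else (circ.contig, circ.start, circ.end))
        circle_id = getattr(circ, "isoform_id", f"{contig}:{start}-{end}")
        for side, pos in (("left", start), ("right", end)):
            if contig not in boundaries or len(boundaries[contig]) == 0:
                continue
            dist = _nearest(boundaries[contig], pos)
            within = dist <= window
            if not within:
                continue
            ptrs = ptr_by_contig.get(contig, [])
            if not ptrs:
                annotations.append(CutSiteAnnotation(
                    circle_id, side, pos, dist, None, None, True,
                    unclassifiable=True))
                counts["unclassifiable"] += 1
                continue
            nearest_ptr = min(
                ptrs, key=lambda p: max(p.start - pos, pos - (p.end - 1), 0))
            in_pointer = nearest_ptr.start <= pos < nearest_ptr.end
            in_mds = any(m.start <= pos < m.end for m in mds_by_contig.get(contig, ()))
            # Pointer copies sit at MDS/IES boundaries: one pointer edge faces
            # the MDS interior, the other the IES.  Offsets are measured from
            # the proximal edge: negative into the MDS, positive into the IES.
            if nearest_ptr.copy == "left":
                mds_edge, ies_edge = nearest_ptr.start, nearest_ptr.end
            else:
                mds_edge, ies_edge = nearest_ptr.end, nearest_ptr.start
            if in_pointer:
                compartment, offset = "pointer", 0
            elif in_mds:
                compartment, offset = "MDS", -int(abs(pos - mds_edge))
            else:
                compartment, offset = "IES", int(abs(pos - ies_edge))
            annotations.append(CutSiteAnnotation(
                circle_id, side, pos, dist, compartment, offset, True))
            counts[compartment] += 1
            if compartment in ks_samples:
                ks_samples[compartment].append(dist)
    return annotations, dict(counts), ks_samples


# ---------------------------------------------------------------------------
# flanking direct repeats (cryptic pointers)


def flanking_direct_repeat(genome, circle, cap: int = 25) -> tuple[int, bool]:
    """Length of the exact direct repeat flanking a circularization point.

    The junction register is fixed by the circle coordinates; the repeat is
    the maximal exact extension, in both directions from the junction point,
    of the agreement between the sequence context at the two cut sites:
    ``seq[start - a : start + b] == seq[end - a : end + b]`` with the repeat
    length a + b maximized, capped at `cap`.  Returns (length, truncated)
    where truncated marks a search clipped by a contig end.
    """
    contigs = genome.contigs if hasattr(genome, "contigs") else genome
    contig, start, end = (circle if isinstance(circle, tuple)
                          else (circle.contig, circle.start, circle.end))
    seq = contigs[contig]
    clen = len(seq)
    truncated = False
    a = 0
    while a < cap:
        if start - a - 1 < 0:
            truncated = True
            break
        if seq[start - a - 1] != seq[end - a - 1]:
            break
        a += 1
    b = 0
    while a + b < cap:
        if end + b >= clen:
            truncated = True
            break
        if seq[start + b] != seq[end + b]:
            break
        b += 1
    return min(a + b, cap), truncated


# ---------------------------------------------------------------------------
# eliminated-sequence categories


def classify_eliminated_type(circle, mds_annotations: Sequence[Mds],
                             breakage_sites=(), window: int = 50) -> Optional[dict]:
    """Category of the eliminated locus a circle removes.

    Requires both circle ends within `window` of an MDS boundary.  Flanking
    MDSs consecutive in the MAC (same locus, indices n/n+1, forward) =>
    non_scrambled_ies; same locus otherwise => scrambled_ies; different MAC
    loci => intergenic.  Also flags circles whose span contains >= 1 complete
    MDS (potentially MDS-bearing circles).
    """
    contig, start, end = (circle if isinstance(circle, tuple)
                          else (circle.contig, circle.start, circle.end))
    mds_here = [m for m in mds_annotations if m.contig == contig]
    if not mds_here:
        return None

    def interval_distance(m: Mds, pos: int) -> int:
        return min(abs(m.start - pos), abs(m.end - pos))

    left = min(mds_here, key=lambda m: (interval_distance(m, start), m.start))
    right = min(mds_here, key=lambda m: (interval_distance(m, end), m.start))
    if interval_distance(left, start) > window or interval_distance(right, end) > window:
        return None

    mds_bearing = any(start < m.start and m.end <= end for m in mds_here)
    if left.locus != right.locus:
        category = "intergenic"
    elif (right.index == left.index + 1 and left.orientation == "+"
          and right.orientation == "+"):
        category = "non_scrambled_ies"
    elif left.index == right.index:
        category = None  # both ends against the same MDS: not an elimination
    else:
        category = "scrambled_ies"
    if category is None:
        return None
    return {"category": category, "mds_bearing": mds_bearing,
            "left_mds": (left.locus, left.index),
            "right_mds": (right.locus, right.index)}


def table2_summary(sites_with_eccdna: dict[str, int],
                   total_eliminated_sites: dict[str, int]):
    """Per-category percentages plus the scrambled vs non-scrambled test.

    Percentage = sites with eccDNA / total eliminated sites x 100 (2 dp).
    The chi-squared test compares with/without eccDNA between scrambled and
    non-scrambled eliminated sites (2x2 contingency).
    """
    import pandas as pd

    rows = []
    for cat, total in total_eliminated_sites.items():
        with_ecc = sites_with_eccdna.get(cat, 0)
        rows.append({
            "category": cat,
            "eliminated_sites": total,
            "sites_with_eccdna": with_ecc,
            "percent_with_eccdna": round(with_ecc / total * 100, 2),
        })
    table = pd.DataFrame(rows)
    chi2 = p = None
    if {"non_scrambled", "scrambled"} <= set(total_eliminated_sites):
        a = sites_with_eccdna.get("non_scrambled", 0)
        b = total_eliminated_sites["non_scrambled"] - a
        c = sites_with_eccdna.get("scrambled", 0)
        d = total_eliminated_sites["scrambled"] - c
        chi2, p, _, _ = sps.chi2_contingency([[a, b], [c, d]])
    return table, chi2, p


# ---------------------------------------------------------------------------
# interval shuffles and tests


def shuffle_intervals(intervals: Sequence[tuple[str, int, int]],
                      domain: Sequence[tuple[str, int, int]],
                      n: int, seed: int,
                      contig_lengths: Optional[dict[str, int]] = None,
                      ) -> list[list[tuple[str, int, int]]]:
    """`n` length-preserving uniform placements of `intervals` on `domain`.

    With `contig_lengths` omitted, every interval is placed uniformly at
    random among all positions (across all domain segments that can hold it)
    where it fits entirely within a segment; an interval longer than every
    segment is an error.  With `contig_lengths` given, the interval *start*
    is placed uniformly within the domain and the interval only has to fit
    within its contig (the include-region semantics of the standard interval
    shuffling tool, needed when the domain is a set of short IESs).  Overlaps
    between placed intervals are permitted in both modes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    segs = [(c, s, e) for c, s, e in domain if e > s]
    seg_lens = np.array([e - s for _, s, e in segs], dtype=np.int64)
    replicates = []
    for _ in range(n):
        placed = []
        for contig, start, end in intervals:
            length = end - start
            if contig_lengths is None:
                slots = seg_lens - length + 1
            else:
                caps = np.array(
                    [min(e, contig_lengths[c] - length + 1) - s
                     for c, s, e in segs], dtype=np.int64)
                slots = np.minimum(seg_lens, caps)
            valid = slots > 0
            if not valid.any():
                raise ValueError(
                    f"interval of length {length} cannot be placed on the domain")
            weights = np.where(valid, slots, 0).astype(float)
            i = rng.choice(len(segs), p=weights / weights.sum())
            offset = int(rng.integers(0, slots[i]))
            c, s, _ = segs[i]
            placed.append((c, s + offset, s + offset + length))
        replicates.append(placed)
    return replicates


def ks_two_sample(sample_a: Sequence[float], sample_b: Sequence[float]):
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    D is the supremum distance between the two empirical CDFs.
    """
    res = sps.ks_2samp(sample_a, sample_b, method="asymp")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# export


def write_cut_site_tsv(annotations: Sequence[CutSiteAnnotation], path: str) -> None:
    import pandas as pd

    pd.DataFrame([vars(a) for a in annotations]).to_csv(path, sep="\t", index=False)
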