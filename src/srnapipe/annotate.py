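"""Sequence annotation: ncRNA classification, size fractions, repeat overlap.

Mapped small-RNA sequences are first screened against reference libraries of
known non-coding RNA classes (exact substring matching — small RNAs are
fragments of their precursors).  The unannotated remainder is profiled by
length and 5' base composition and split into the 18-25 nt (endo-siRNA
candidate) and 26-34 nt (piRNA) fractions; hits are intersected with the
repeat annotation to call TE-related sequences and their orientation.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .mapping import SmallRNASeq, WeightedHit
from .seqio import RepeatRecord

__all__ = [
    "NCRNA_PRECEDENCE",
    "FractionProfile",
    "TEAssignment",
    "annotate_ncRNA",
    "length_and_5p_profile",
    "intersect_repeats",
]

#: Annotation precedence when a sequence matches more than one library.
NCRNA_PRECEDENCE: Tuple[str, ...] = (
    "miRNA",
    "miRNA_precursor_fragment",
    "snoRNA",
    "snRNA",
    "miscRNA",
    "rRNA",
    "tRNA",
)

DEFAULT_FRACTIONS: Tuple[Tuple[int, int], ...] = ((18, 25), (26, 34))


def annotate_ncRNA(
    sequences: Sequence[SmallRNASeq],
    libraries: Dict[str, Iterable[str]],
    precedence: Sequence[str] = NCRNA_PRECEDENCE,
) -> Dict[str, str]:
    """Label each sequence by the first library containing it as a substring.

    ``libraries`` maps class label -> iterable of reference sequences.
    Sequences matching no library are labeled ``unannotated``.
    """
    unknown = set(libraries) - set(precedence)
    if unknown:
        raise ValueError(f"libraries with labels outside the precedence order: {unknown}")
    if not libraries:
        warnings.warn("empty ncRNA library set: everything will be unannotated", stacklevel=2)
    # one concatenated haystack per class keeps the substring test in C
    haystacks = {
        label: "#".join(s.upper().replace("U", "T") for s in seqs)
        for label, seqs in libraries.items()
    }
    labels: Dict[str, str] = {}
    for rec in sequences:
        label = "unannotated"
        for cls in precedence:
            hay = haystacks.get(cls)
            if hay and rec.seq in hay:
                label = cls
                break
        labels[rec.id] = label
    return labels


@dataclass
class FractionProfile:
    """Weighted length histogram and per-fraction 5' base composition."""

    length_hist: Dict[int, float]
    composition: Dict[str, Dict[str, float]]  # fraction name -> base -> share
    fraction_bounds: Dict[str, Tuple[int, int]]

    def to_frames(self) -> Tuple[pd.DataFrame, pd.DataFrame]:
        lh = pd.DataFrame(
            sorted(self.length_hist.items()), columns=["length", "weighted_count"]
        )
        rows = [
            {"fraction": frac, "base": b, "share": share}
            for frac, comp in self.composition.items()
            for b, share in comp.items()
        ]
        return lh, pd.DataFrame(rows, columns=["fraction", "base", "share"])


def _five_prime_base(seq: str) -> str:
    return "U" if seq[0] == "T" else seq[0]


def length_and_5p_profile(
    sequences: Sequence[SmallRNASeq],
    weights: Optional[Dict[str, float]] = None,
    fraction_bounds: Sequence[Tuple[int, int]] = DEFAULT_FRACTIONS,
    clustered_ids: Optional[Set[str]] = None,
) -> FractionProfile:
    """Weighted length histogram plus per-fraction 5' A/C/G/U composition.

    ``weights`` defaults to 1 per nonidentical sequence.  When
    ``clustered_ids`` is given, the short fraction is additionally split into
    clustered vs dispersed sub-profiles (the hallmark separating cluster-coded
    short piRNAs from interspersed siRNA candidates).
    """
    weights = weights or {}
    length_hist: Dict[int, float] = {}
    comp_acc: Dict[str, Dict[str, float]] = {}
    bounds: Dict[str, Tuple[int, int]] = {}

    def frac_names(rec: SmallRNASeq) -> List[str]:
        names = []
        for lo, hi in fraction_bounds:
            if lo <= len(rec.seq) <= hi:
                name = f"{lo}-{hi}"
                names.append(name)
                bounds[name] = (lo, hi)
                if clustered_ids is not None and (lo, hi) == min(fraction_bounds):
                    sub = "clustered" if rec.id in clustered_ids else "dispersed"
                    names.append(f"{name}_{sub}")
                    bounds[f"{name}_{sub}"] = (lo, hi)
        return names

    for rec in sequences:
        w = weights.get(rec.id, 1.0)
        length_hist[len(rec.seq)] = length_hist.get(len(rec.seq), 0.0) + w
        b = _five_prime_base(rec.seq)
        for name in frac_names(rec):
            comp_acc.setdefault(name, {x: 0.0 for x in "ACGU"})
            comp_acc[name][b] = comp_acc[name].get(b, 0.0) + w

    composition = {}
    for name, acc in comp_acc.items():
        total = sum(acc.values())
        composition[name] = {b: (v / total if total else 0.0) for b, v in acc.items()}
    return FractionProfile(length_hist, composition, bounds)


@dataclass(frozen=True)
class TEAssignment:
    seq_id: str
    chrom: str
    start: int
    end: int
    te_family: str
    te_class: str
    orientation: str  # sense | antisense
    in_cluster: bool
    weight: float


def intersect_repeats(
    hits: Sequence[WeightedHit],
    repeats: Sequence[RepeatRecord],
    clusters: Optional[Sequence[Tuple[str, int, int]]] = None,
    min_overlap_fraction: float = 0.5,
) -> Tuple[List[TEAssignment], pd.DataFrame]:
    """Call TE-related hits (majority-footprint overlap) and orientations.

    A hit is TE-related when at least ``min_overlap_fraction`` of its length
    overlaps one repeat locus (the best-overlapping locus wins); sense means
    hit strand equals the repeat's annotated strand.  The summary table gives
    weighted sense/antisense totals per family, split by cluster membership.
    """
    by_chrom: Dict[str, List[RepeatRecord]] = {}
    unsorted = False
    last: Dict[str, int] = {}
    for r in repeats:
        by_chrom.setdefault(r.chrom, []).append(r)
        if r.start < last.get(r.chrom, -1):
            unsorted = True
        last[r.chrom] = r.start
    if unsorted:
        warnings.warn("repeat annotation unsorted: sorting internally", stacklevel=2)
    starts: Dict[str, List[int]] = {}
    maxlen: Dict[str, int] = {}
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda r: (r.start, r.end))
        starts[chrom] = [r.start for r in by_chrom[chrom]]
        maxlen[chrom] = max(r.length for r in by_chrom[chrom])

    cluster_ivs: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, s, e in clusters or []:
        cluster_ivs.setdefault(chrom, []).append((s, e))

    assignments: List[TEAssignment] = []
    for h in hits:
        recs = by_chrom.get(h.chrom)
        if not recs:
            continue
        lo = bisect_left(starts[h.chrom], h.start - maxlen[h.chrom])
        best: Tuple[int, RepeatRecord] | None = None
        for r in recs[lo:]:
            if r.start >= h.end:
                break
            ov = min(h.end, r.end) - max(h.start, r.start)
            if ov > 0 and (best is None or ov > best[0]):
                best = (ov, r)
        if best is None or best[0] < min_overlap_fraction * h.length:
            continue
        r = best[1]
        in_cluster = any(
            s <= h.start and h.end <= e for s, e in cluster_ivs.get(h.chrom, [])
        )
        assignments.append(
            TEAssignment(
                h.seq_id, h.chrom, h.start, h.end, r.family, r.te_class,
                "sense" if h.strand == r.strand else "antisense",
                in_cluster, h.weight,
            )
        )

    rows: Dict[Tuple[str, str, bool], Dict[str, float]] = {}
    for a in assignments:
        key = (a.te_family, a.te_class, a.in_cluster)
        acc = rows.setdefault(key, {"sense": 0.0, "antisense": 0.0})
        acc[a.orientation] += a.weight
    summary = pd.DataFrame(
        [
            {
                "family": fam, "class": cls, "in_cluster": inc,
                "sense_weight": acc["sense"], "antisense_weight": acc["antisense"],
                "total_weight": acc["sense"] + acc["antisense"],
            }
            for (fam, cls, inc), acc in sorted(rows.items())
        ],
        columns=["family", "class", "in_cluster", "sense_weight",
                 "antisense_weight", "total_weight"],
    )
    return assignments, summary
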