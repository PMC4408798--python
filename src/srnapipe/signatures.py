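"""Biogenesis signatures: ping-pong 5'-overlaps and Dicer duplex geometry.

The ping-pong amplification loop leaves a diagnostic excess of opposite-
strand read pairs whose 5' ends overlap by exactly 10 bp; Dicer processing
of a double-stranded precursor instead leaves 18-22 bp overlaps arranged as
duplexes with 2 nt 3' overhangs.  Both signatures are computed on weighted
hits: a pair contributes the product of its two hit weights, which preserves
the per-sequence 1/hit-count normalization under marginalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mapping import WeightedHit

__all__ = [
    "OverlapHistogram",
    "DuplexCall",
    "overlap_histogram",
    "pingpong_partition",
    "call_duplexes",
]

MAX_OVERLAP = 30


@dataclass
class OverlapHistogram:
    """Weighted counts of 5'-end overlaps between opposite-strand hit pairs."""

    counts: Dict[int, float] = field(default_factory=dict)
    mode: str = "nonidentical"

    def __getitem__(self, overlap: int) -> float:
        return self.counts.get(overlap, 0.0)

    @property
    def total(self) -> float:
        return sum(self.counts.values())

    def mode_overlap(self) -> Optional[int]:
        """Overlap length carrying the most weight (ties to the smallest)."""
        if not self.counts or self.total == 0:
            return None
        return max(sorted(self.counts), key=lambda o: self.counts[o])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(o, self.counts.get(o, 0.0)) for o in range(1, MAX_OVERLAP + 1)],
            columns=["overlap_bp", "weighted_count"],
        )


def overlap_histogram(
    hits: Sequence[WeightedHit],
    max_overlap: int = MAX_OVERLAP,
    mode: str = "nonidentical",
) -> OverlapHistogram:
    """Histogram of 5' overlaps over all opposite-strand co-located pairs.

    The overlap ``o`` of a plus hit ``a`` and a minus hit ``b`` is the number
    of genomic bases their 5'-anchored prefixes share — the intersection of
    the two footprints (a ping-pong pair shares exactly the 10 bases behind
    both 5' ends; a Dicer duplex of length-L reads with 2 nt 3' overhangs
    shares L - 2).  Each co-located pair adds ``weight_a * weight_b`` to bin
    ``o``; the histogram is symmetric under swapping all strand labels.
    """
    minus: Dict[str, List[Tuple[int, int, float]]] = {}
    for h in hits:
        if h.strand == "-":
            minus.setdefault(h.chrom, []).append((h.start, h.end, h.weight))
    starts: Dict[str, np.ndarray] = {}
    ends: Dict[str, np.ndarray] = {}
    wts: Dict[str, np.ndarray] = {}
    max_len: Dict[str, int] = {}
    for chrom, rows in minus.items():
        rows.sort()
        starts[chrom] = np.array([r[0] for r in rows])
        ends[chrom] = np.array([r[1] for r in rows])
        wts[chrom] = np.array([r[2] for r in rows])
        max_len[chrom] = max(r[1] - r[0] for r in rows)
    counts: Dict[int, float] = {}
    for h in hits:
        if h.strand != "+" or h.chrom not in starts:
            continue
        s = starts[h.chrom]
        lo = int(np.searchsorted(s, h.start - max_len[h.chrom], "left"))
        hi = int(np.searchsorted(s, h.end, "left"))
        if lo == hi:
            continue
        o = np.minimum(h.end, ends[h.chrom][lo:hi]) - np.maximum(h.start, s[lo:hi])
        sel = (o >= 1) & (o <= max_overlap)
        for ov, w in zip(o[sel].tolist(), wts[h.chrom][lo:hi][sel].tolist()):
            counts[ov] = counts.get(ov, 0.0) + h.weight * w
    return OverlapHistogram(counts, mode)


def pingpong_partition(
    hit_sets: Dict[str, Sequence[WeightedHit]],
    max_overlap: int = MAX_OVERLAP,
) -> Tuple[Dict[str, OverlapHistogram], OverlapHistogram, pd.DataFrame]:
    """Per-fraction overlap histograms plus the pooled histogram.

    Pooling can only add pairs, so ``pooled[o] >= per-set[o]`` for every bin;
    an increase at 10 bp reveals ping-pong pairs formed across fractions.
    """
    singles = {name: overlap_histogram(hs, max_overlap) for name, hs in hit_sets.items()}
    pooled_hits: List[WeightedHit] = []
    for hs in hit_sets.values():
        pooled_hits.extend(hs)
    pooled = overlap_histogram(pooled_hits, max_overlap)
    for name, hist in singles.items():
        if pooled[10] + 1e-9 < hist[10]:
            raise AssertionError(f"pooled 10-bp count below fraction {name!r}: impossible")
    rows = []
    for o in range(1, max_overlap + 1):
        row = {"overlap_bp": o, "pooled": pooled[o]}
        row.update({name: hist[o] for name, hist in singles.items()})
        rows.append(row)
    return singles, pooled, pd.DataFrame(rows)


@dataclass(frozen=True)
class DuplexCall:
    """A candidate Dicer duplex: two reads on opposite arms of a hairpin."""

    id_a: str  # 5' arm read
    id_b: str  # 3' arm read
    overhang_3p_a: int  # bases a's 3' end extends past b's 5' end in the fold
    overhang_3p_b: int
    overlap: int  # paired bases shared by the two reads

    @property
    def canonical(self) -> bool:
        """Dicer-consistent geometry: both 3' overhangs 2 nt, overlap 18-22 bp."""
        return self.overhang_3p_a == 2 and self.overhang_3p_b == 2 and 18 <= self.overlap <= 22


def call_duplexes(
    hits: Sequence[Tuple[str, int, int]],
    pairing_map: np.ndarray,
    min_overlap: int = 10,
) -> Tuple[List[DuplexCall], List[str]]:
    """Detect duplex geometry among reads on a hairpin transcript.

    ``hits`` are ``(read_id, start, end)`` in transcript-local coordinates
    (all reads are sense to the transcript); ``pairing_map[i]`` gives the
    partner base of position ``i`` in the folded hairpin, -1 if unpaired.
    Reads whose footprint contains an unpaired (loop) base are excluded from
    duplex calling and returned separately.

    For arm-1 read a and arm-2 read b, a's 3' overhang is the number of bases
    a's 3' end extends past the pairing image of b's 5' end (and vice versa);
    the overlap is the length of the mutually paired region.
    """
    pairing_map = np.asarray(pairing_map)
    if pairing_map.ndim != 1 or (pairing_map < -1).any():
        raise ValueError("invalid pairing map")
    n = len(pairing_map)
    loop_spanning: List[str] = []
    arm: List[Tuple[str, int, int]] = []
    for rid, s, e in hits:
        if s < 0 or e > n or e <= s:
            raise ValueError(f"hit {rid} outside the transcript")
        if (pairing_map[s:e] == -1).any():
            loop_spanning.append(rid)
        else:
            arm.append((rid, s, e))

    arm.sort(key=lambda t: (t[1], t[2], t[0]))
    calls: List[DuplexCall] = []
    for i, (rid_a, sa, ea) in enumerate(arm):
        for rid_b, sb, eb in arm[i + 1 :]:
            if sb < ea:
                continue  # overlapping/same-arm footprints are not a duplex
            # pairing image of b on a's side of the stem (pairing_map decreases)
            img_lo, img_hi = int(pairing_map[eb - 1]), int(pairing_map[sb]) + 1
            overlap = min(ea, img_hi) - max(sa, img_lo)
            if overlap < min_overlap:
                continue
            oh_a = sb - int(pairing_map[ea - 1])  # a's 3' past b's 5' image
            oh_b = sa - img_lo  # b's 3' past a's 5' image
            calls.append(DuplexCall(rid_a, rid_b, oh_a, oh_b, overlap))
    return calls, loop_spanning
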