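"""Genomic piRNA cluster prediction and characterization.

Clusters are called from the weighted hits of unannotated sequences with a
sliding-window density scan: a window is "hot" when its summed hit weight
exceeds a multiple of the genome-average weight per window and enough
distinct sequences map inside; overlapping hot windows merge, the merged
interval is trimmed to its outermost hits, and candidates must then pass the
piRNA-likeness predicates (size, 1U-or-10A weighted bias, length window).
Accepted clusters are classified as monodirectional, bidirectional (divergent
strands around a central split point) or mixed, and characterized by TE
content and TE-divergence accumulation relative to the whole genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mapping import SmallRNASeq, WeightedHit
from .seqio import RepeatRecord, interval_union_bp

__all__ = [
    "ClusterParams",
    "PiRNACluster",
    "AccumulationCurve",
    "predict_clusters",
    "classify_topology",
    "cluster_te_content",
    "divergence_accumulation",
    "write_clusters_tsv",
    "write_clusters_bed",
]


@dataclass(frozen=True)
class ClusterParams:
    """Tunable thresholds of the cluster scan (all configurable)."""

    window: int = 5000
    step: int = 1000
    density_factor: float = 10.0
    min_nonidentical: int = 25
    min_size: int = 1000
    biased_fraction: float = 0.75  # weighted share with 5' U or position-10 A
    length_min: int = 24
    length_max: int = 34
    length_fraction: float = 0.75
    mono_fraction: float = 0.90
    bidir_fraction: float = 0.75
    # a candidate split must leave at least this weight share on each side,
    # so a handful of edge hits can never fake a divergent topology
    min_side_fraction: float = 0.2
    # isolated hits this far from the next hit inward are peeled off the
    # cluster edges before trimming to outermost hits
    edge_trim_gap: int = 500

    def __post_init__(self) -> None:
        if self.length_min > self.length_max:
            raise ValueError("length_min > length_max")
        if self.step > self.window:
            raise ValueError("step must not exceed window")
        for name in ("window", "step", "min_size", "min_nonidentical"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class PiRNACluster:
    chrom: str
    start: int
    end: int
    topology: str  # mono_plus | mono_minus | bidirectional | mixed
    split_point: Optional[int]
    n_nonidentical: int
    weighted_hits: float
    u1_or_10A_fraction: float

    @property
    def size(self) -> int:
        return self.end - self.start


def _is_biased(seq: str) -> bool:
    """The piRNA signature at sequence level: 5' U or position-10 A."""
    return seq[0] == "T" or (len(seq) >= 10 and seq[9] == "A")


def predict_clusters(
    hits: Sequence[WeightedHit],
    genome_lengths: Dict[str, int],
    reads: Dict[str, SmallRNASeq] | Sequence[SmallRNASeq],
    params: ClusterParams = ClusterParams(),
) -> List[PiRNACluster]:
    """Sliding-window cluster scan over weighted hits of unannotated reads."""
    if not isinstance(reads, dict):
        reads = {r.id: r for r in reads}
    if not hits:
        return []
    total_weight = sum(h.weight for h in hits)
    genome_bp = sum(genome_lengths.values())
    mean_window_weight = total_weight * params.window / genome_bp
    cutoff = params.density_factor * mean_window_weight

    by_chrom: Dict[str, List[WeightedHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)

    clusters: List[PiRNACluster] = []
    for chrom in sorted(by_chrom):
        chits = sorted(by_chrom[chrom], key=lambda h: (h.start, h.end, h.strand, h.seq_id))
        starts = np.array([h.start for h in chits])
        weights = np.array([h.weight for h in chits])
        cw = np.concatenate([[0.0], np.cumsum(weights)])
        L = genome_lengths[chrom]
        win_starts = np.arange(0, max(L - params.window, 0) + 1, params.step)
        lo = np.searchsorted(starts, win_starts, "left")
        hi = np.searchsorted(starts, win_starts + params.window, "left")
        hot_mask = (cw[hi] - cw[lo]) >= cutoff
        hot = []
        for wi in np.flatnonzero(hot_mask):
            ids = {chits[j].seq_id for j in range(lo[wi], hi[wi])}
            if len(ids) >= params.min_nonidentical:
                hot.append(int(win_starts[wi]))
        # merge overlapping hot windows into candidate intervals
        merged: List[Tuple[int, int]] = []
        for ws in hot:
            we = ws + params.window
            if merged and ws <= merged[-1][1]:
                merged[-1] = (merged[-1][0], we)
            else:
                merged.append((ws, we))
        for cs, ce in merged:
            sel = [h for h in chits if cs <= h.start and h.end <= ce]
            sel.sort(key=lambda h: (h.start, h.end))
            # peel sparse background off the edges: group hits into blocks
            # separated by > edge_trim_gap, drop featherweight edge blocks
            blocks: List[List[WeightedHit]] = []
            block_end = -1
            for h in sel:
                if not blocks or h.start - block_end > params.edge_trim_gap:
                    blocks.append([h])
                else:
                    blocks[-1].append(h)
                block_end = max(block_end, h.end)
            total_w = sum(h.weight for h in sel)
            while len(blocks) > 1 and sum(h.weight for h in blocks[0]) < 0.05 * total_w:
                blocks.pop(0)
            while len(blocks) > 1 and sum(h.weight for h in blocks[-1]) < 0.05 * total_w:
                blocks.pop()
            sel = [h for b in blocks for h in b]
            if not sel:
                continue
            start = min(h.start for h in sel)
            end = max(h.end for h in sel)
            if end - start < params.min_size:
                continue
            w = sum(h.weight for h in sel)
            biased = sum(h.weight for h in sel if _is_biased(reads[h.seq_id].seq))
            lengths_ok = sum(
                h.weight for h in sel if params.length_min <= h.length <= params.length_max
            )
            if biased / w < params.biased_fraction:
                continue
            if lengths_ok / w < params.length_fraction:
                continue
            topology, split = classify_topology(sel, params)
            clusters.append(
                PiRNACluster(
                    chrom, start, end, topology, split,
                    n_nonidentical=len({h.seq_id for h in sel}),
                    weighted_hits=w,
                    u1_or_10A_fraction=biased / w,
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.start))
    return clusters


def classify_topology(
    hits: Sequence[WeightedHit],
    params: ClusterParams = ClusterParams(),
) -> Tuple[str, Optional[int]]:
    """Mono / bidirectional / mixed strand topology of one cluster.

    Monodirectional when one strand carries at least ``mono_fraction`` of the
    weight.  Otherwise every boundary between adjacent hits is scored as a
    candidate split point for divergent transcription (minus-left/plus-right
    or plus-left/minus-right); the split maximizing the summed strand purity
    of the two sides wins (ties to the smallest coordinate), and the cluster
    is bidirectional when both sides reach ``bidir_fraction`` purity.
    """
    w_plus = sum(h.weight for h in hits if h.strand == "+")
    w_minus = sum(h.weight for h in hits if h.strand == "-")
    total = w_plus + w_minus
    if total == 0:
        return "mixed", None
    if w_plus / total >= params.mono_fraction:
        return "mono_plus", None
    if w_minus / total >= params.mono_fraction:
        return "mono_minus", None

    shits = sorted(hits, key=lambda h: (h.five_prime, h.seq_id))
    fp = np.array([h.five_prime for h in shits])
    w = np.array([h.weight for h in shits])
    is_plus = np.array([h.strand == "+" for h in shits])
    cum_w = np.concatenate([[0.0], np.cumsum(w)])
    cum_plus = np.concatenate([[0.0], np.cumsum(w * is_plus)])

    best: Optional[Tuple[float, int, float, float]] = None  # score, split, pL, pR
    for k in range(1, len(shits)):
        if fp[k] == fp[k - 1]:
            continue
        split = int(fp[k])  # left side: hits with 5' end < split
        wl, wr = cum_w[k], cum_w[-1] - cum_w[k]
        if min(wl, wr) < params.min_side_fraction * cum_w[-1]:
            continue
        pl_plus = cum_plus[k] / wl
        pr_plus = (cum_plus[-1] - cum_plus[k]) / wr
        for purity_l, purity_r in (
            (1 - pl_plus, pr_plus),  # minus left / plus right (divergent)
            (pl_plus, 1 - pr_plus),  # plus left / minus right
        ):
            score = purity_l + purity_r
            if best is None or score > best[0] + 1e-12:
                best = (score, split, purity_l, purity_r)
    if best is not None and best[2] >= params.bidir_fraction and best[3] >= params.bidir_fraction:
        return "bidirectional", best[1]
    return "mixed", None


def cluster_te_content(
    clusters: Sequence[PiRNACluster],
    repeats: Sequence[RepeatRecord],
    genome_lengths: Dict[str, int],
) -> pd.DataFrame:
    """Per-TE-class bp fractions inside clusters vs the whole genome.

    Overlapping repeat records of one class are flattened (bp union) before
    counting, so nested annotations are never double counted.
    """
    cluster_bp = sum(c.size for c in clusters)
    genome_bp = sum(genome_lengths.values())
    classes = sorted({r.te_class for r in repeats})
    rows = []
    for cls in classes:
        per_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for r in repeats:
            if r.te_class == cls:
                per_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        genome_cov = sum(interval_union_bp(ivs) for ivs in per_chrom.values())
        cl_cov = 0
        for c in clusters:
            clipped = [
                (max(s, c.start), min(e, c.end))
                for s, e in per_chrom.get(c.chrom, [])
                if s < c.end and e > c.start
            ]
            cl_cov += interval_union_bp(clipped)
        rows.append(
            {
                "te_class": cls,
                "cluster_fraction": cl_cov / cluster_bp if cluster_bp else 0.0,
                "genome_fraction": genome_cov / genome_bp,
            }
        )
    return pd.DataFrame(rows, columns=["te_class", "cluster_fraction", "genome_fraction"])


@dataclass
class AccumulationCurve:
    """Cumulative bp fraction by divergence, old (high %) to young (0 %)."""

    bins: np.ndarray  # divergence bin lower edges, descending
    genome_cum: np.ndarray
    cluster_cum: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "divergence_pct": self.bins,
                "genome_cum_fraction": self.genome_cum,
                "cluster_cum_fraction": self.cluster_cum,
            }
        )


def divergence_accumulation(
    repeats: Sequence[RepeatRecord],
    clusters: Sequence[PiRNACluster],
    families: Sequence[str],
    bin_width: float = 1.0,
) -> AccumulationCurve:
    """Accumulation of selected TE families over time, genome vs clusters.

    Divergence from the family consensus proxies insertion age; loci are
    accumulated from the most diverged (oldest) down to 0 %, separately for
    all loci and for those overlapping piRNA clusters.
    """
    sel = [r for r in repeats if r.family in set(families)]
    if not sel:
        warnings.warn(f"no repeat loci for families {list(families)}", stacklevel=2)
        empty = np.empty(0)
        return AccumulationCurve(empty, empty.copy(), empty.copy())

    def overlaps_cluster(r: RepeatRecord) -> bool:
        return any(c.chrom == r.chrom and r.start < c.end and c.start < r.end for c in clusters)

    max_div = max(r.divergence_pct for r in sel)
    edges = np.arange(np.ceil(max_div / bin_width) * bin_width, -bin_width / 2, -bin_width)
    genome_bp = np.zeros(len(edges))
    cluster_bp = np.zeros(len(edges))
    for r in sel:
        idx = np.searchsorted(-edges, -r.divergence_pct, "left")
        idx = min(idx, len(edges) - 1)
        genome_bp[idx] += r.length
        if overlaps_cluster(r):
            cluster_bp[idx] += r.length
    g_tot, c_tot = genome_bp.sum(), cluster_bp.sum()
    genome_cum = np.cumsum(genome_bp) / g_tot if g_tot else np.cumsum(genome_bp)
    cluster_cum = np.cumsum(cluster_bp) / c_tot if c_tot else np.cumsum(cluster_bp)
    return AccumulationCurve(edges, genome_cum, cluster_cum)


def write_clusters_tsv(clusters: Sequence[PiRNACluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart0\tend\ttopology\tsplit_point\tn_nonidentical\t"
            "weighted_hits\tu1_or_10A_fraction\n"
        )
        for c in clusters:
            split = "" if c.split_point is None else str(c.split_point)
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.topology}\t{split}\t"
                f"{c.n_nonidentical}\t{c.weighted_hits:.4f}\t{c.u1_or_10A_fraction:.4f}\n"
            )


def read_clusters_tsv(path: str | Path) -> List[PiRNACluster]:
    out: List[PiRNACluster] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise ValueError(f"{path}: not a clusters TSV")
        for line in fh:
            chrom, start, end, topo, split, n_ni, w, frac = line.rstrip("\n").split("\t")
            out.append(
                PiRNACluster(
                    chrom, int(start), int(end), topo,
                    int(split) if split else None,
                    int(n_ni), float(w), float(frac),
                )
            )
    return out


def write_clusters_bed(clusters: Sequence[PiRNACluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(clusters):
            strand = {"mono_plus": "+", "mono_minus": "-"}.get(c.topology, ".")
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\tcluster_{i + 1}|{c.topology}\t"
                f"{int(round(min(c.weighted_hits, 1000)))}\t{strand}\n"
            )
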