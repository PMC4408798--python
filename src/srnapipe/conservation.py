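"""Cross-species conservation of orthologous piRNA clusters.

Orthologous loci are found by exact k-mer seeding of cluster sequences
against the second genome, merging seeds on shared diagonals into ungapped
anchors and chaining co-linear anchors ("blocks of contiguous alignments in
correct order").  Chained regions are realigned with an affine-gap local
aligner, aligned columns are classified by piRNA-coding status (read
coverage per species) and motif membership, and per-class identity is
reported both plain and weighted by normalized read depth, with 2x2
chi-square significance against the all-columns baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align

from .mapping import GenomeIndex
from .stats import ContingencyTable, chi2_2x2

__all__ = [
    "HomologParams",
    "AlignParams",
    "Anchor",
    "HomologPair",
    "ClusterAlignment",
    "find_homologs",
    "align_pair",
    "classify_and_weight",
    "conservation_report",
]


@dataclass(frozen=True)
class HomologParams:
    k: int = 12
    max_seed_gap: int = 120  # bp between seeds merged into one ungapped anchor
    min_anchor: int = 30
    min_identity: float = 0.6
    min_total: int = 200  # total anchored bp required to accept a chain


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring for cluster-ortholog realignment.

    Gap penalties are deliberately stiff: orthologous piRNA clusters carry
    almost no true indels at these divergences, and with permissive gaps
    (e.g. the fasta36-style 12/4) the DP silently re-pairs the worst-matching
    stretches through compensating gap pairs, inflating measured identity of
    diverged residues by 2-3 points.  Stiff gaps keep per-column identity an
    unbiased estimate of the underlying substitution rate.
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 25.0
    gap_extend: float = 5.0


@dataclass(frozen=True)
class Anchor:
    """An ungapped seed-extended match: A-interval, B-interval, identity."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    identity: float

    @property
    def length(self) -> int:
        return self.a_end - self.a_start


@dataclass
class HomologPair:
    cluster_id: str
    chrom_b: str
    b_start: int
    b_end: int
    anchors: List[Anchor]

    @property
    def anchored_bp(self) -> int:
        return sum(a.length for a in self.anchors)


def _diagonal_anchors(
    qpos: np.ndarray, bpos: np.ndarray, seq_a: str, seq_b: str, params: HomologParams
) -> List[Anchor]:
    """Merge same-diagonal seed k-mers into ungapped anchors."""
    anchors: List[Anchor] = []
    diags: Dict[int, List[int]] = {}
    for q, b in zip(qpos.tolist(), bpos.tolist()):
        diags.setdefault(b - q, []).append(q)
    k = params.k
    for diag, qs in diags.items():
        qs.sort()
        run_start = prev = qs[0]
        for q in qs[1:] + [None]:
            if q is not None and q - prev <= params.max_seed_gap:
                prev = q
                continue
            a_s, a_e = run_start, prev + k
            if a_e - a_s >= params.min_anchor:
                sub_a = seq_a[a_s:a_e]
                sub_b = seq_b[a_s + diag : a_e + diag]
                ident = sum(x == y for x, y in zip(sub_a, sub_b)) / len(sub_a)
                if ident >= params.min_identity:
                    anchors.append(Anchor(a_s, a_e, a_s + diag, a_e + diag, ident))
            if q is not None:
                run_start = prev = q
    return anchors


def _best_chain(anchors: List[Anchor]) -> List[Anchor]:
    """Heaviest co-linear chain by total anchor bp (ties: smallest B start)."""
    anchors = sorted(anchors, key=lambda a: (a.a_start, a.b_start))
    n = len(anchors)
    score = [a.length for a in anchors]
    back: List[Optional[int]] = [None] * n
    for i in range(n):
        for j in range(i):
            if (
                anchors[j].a_end <= anchors[i].a_start
                and anchors[j].b_end <= anchors[i].b_start
            ):
                cand = score[j] + anchors[i].length
                if cand > score[i] or (
                    cand == score[i]
                    and back[i] is not None
                    and anchors[j].b_start < anchors[back[i]].b_start
                ):
                    score[i] = cand
                    back[i] = j
    if not anchors:
        return []
    best_i = max(
        range(n), key=lambda i: (score[i], -anchors[i].b_start)
    )
    chain = []
    cur: Optional[int] = best_i
    while cur is not None:
        chain.append(anchors[cur])
        cur = back[cur]
    return chain[::-1]


def find_homologs(
    clusters: Sequence,
    genome_a: Dict[str, str],
    genome_b: Dict[str, str],
    params: HomologParams = HomologParams(),
) -> Tuple[List[HomologPair], List[str]]:
    """Locate the homologous interval of each cluster in the second genome.

    ``clusters`` expose ``chrom``, ``start``, ``end`` (clusters-module
    records or simulation truth).  Returns accepted pairs and the ids of
    unmatched clusters.  The forward strand only is searched (the homolog
    model introduces substitutions and small indels, not inversions).
    """
    index = GenomeIndex(genome_b, k=params.k)
    pairs: List[HomologPair] = []
    unmatched: List[str] = []
    powers = 4 ** np.arange(params.k - 1, -1, -1, dtype=np.int64)
    code = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    for ci, cl in enumerate(clusters):
        cid = f"{cl.chrom}:{cl.start}-{cl.end}"
        seq_a = genome_a[cl.chrom][cl.start : cl.end]
        arr = code[np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)]
        if len(arr) < params.k:
            unmatched.append(cid)
            continue
        windows = np.lib.stride_tricks.sliding_window_view(
            np.where(arr >= 4, 0, arr).astype(np.int64), params.k
        )
        vals = windows @ powers
        best_pair: Optional[HomologPair] = None
        for chrom_b, seq_b in genome_b.items():
            sorted_vals = index._sorted[chrom_b]
            order = index._order[chrom_b]
            lo = np.searchsorted(sorted_vals, vals, "left")
            hi = np.searchsorted(sorted_vals, vals, "right")
            qpos_list, bpos_list = [], []
            for q in np.flatnonzero(hi > lo):
                for b_at in order[lo[q] : hi[q]]:
                    qpos_list.append(int(q))
                    bpos_list.append(int(b_at))
            if not qpos_list:
                continue
            anchors = _diagonal_anchors(
                np.array(qpos_list), np.array(bpos_list), seq_a, seq_b, params
            )
            chain = _best_chain(anchors)
            total = sum(a.length for a in chain)
            if total >= params.min_total:
                # project the full cluster extent through the chain ends, so
                # hard-to-anchor cluster edges still enter the alignment
                b_lo = max(0, chain[0].b_start - chain[0].a_start)
                b_hi = min(len(seq_b), chain[-1].b_end + (len(seq_a) - chain[-1].a_end))
                cand = HomologPair(cid, chrom_b, b_lo, b_hi, chain)
                if (
                    best_pair is None
                    or cand.anchored_bp > best_pair.anchored_bp
                    or (
                        cand.anchored_bp == best_pair.anchored_bp
                        and cand.b_start < best_pair.b_start
                    )
                ):
                    best_pair = cand
        if best_pair is None:
            unmatched.append(cid)
        else:
            pairs.append(best_pair)
    return pairs, unmatched


@dataclass
class ClusterAlignment:
    """Column-wise pairing of two homologous sequences.

    ``a_pos`` / ``b_pos`` give the source coordinate of each column (-1 in
    gap columns, which carry exactly one base); ``identical`` is set only on
    non-gap columns with equal residues.
    """

    seq_a: str
    seq_b: str
    a_pos: np.ndarray
    b_pos: np.ndarray
    identical: np.ndarray

    @property
    def n_columns(self) -> int:
        return len(self.a_pos)

    @property
    def non_gap(self) -> np.ndarray:
        return (self.a_pos >= 0) & (self.b_pos >= 0)

    def identity_pct(self) -> float:
        ng = self.non_gap
        return 100.0 * self.identical[ng].mean() if ng.any() else float("nan")


def align_pair(
    seq_a: str, seq_b: str, params: AlignParams = AlignParams()
) -> ClusterAlignment:
    """Affine-gap local alignment of two homologous cluster sequences."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    aln = aligner.align(seq_a, seq_b)[0]
    blocks_a, blocks_b = aln.aligned
    a_pos: List[int] = []
    b_pos: List[int] = []
    prev_a_end: Optional[int] = None
    prev_b_end: Optional[int] = None
    for (a_s, a_e), (b_s, b_e) in zip(blocks_a, blocks_b):
        if prev_a_end is not None:
            for i in range(prev_a_end, a_s):  # insertion in A (gap in B)
                a_pos.append(i)
                b_pos.append(-1)
            for j in range(prev_b_end, b_s):  # insertion in B (gap in A)
                a_pos.append(-1)
                b_pos.append(j)
        for i, j in zip(range(a_s, a_e), range(b_s, b_e)):
            a_pos.append(i)
            b_pos.append(j)
        prev_a_end, prev_b_end = a_e, b_e
    a_arr = np.array(a_pos, dtype=np.int64)
    b_arr = np.array(b_pos, dtype=np.int64)
    identical = np.zeros(len(a_arr), dtype=bool)
    for idx in np.flatnonzero((a_arr >= 0) & (b_arr >= 0)):
        identical[idx] = seq_a[a_arr[idx]] == seq_b[b_arr[idx]]
    return ClusterAlignment(seq_a, seq_b, a_arr, b_arr, identical)


CODING_CLASSES = ("coding_neither", "coding_one", "coding_both")


def classify_and_weight(
    aln: ClusterAlignment,
    coverage_a: np.ndarray,
    coverage_b: np.ndarray,
    total_reads_a: float,
    total_reads_b: float,
    motif_intervals: Optional[Dict[str, Sequence[Tuple[int, int]]]] = None,
) -> Tuple[np.ndarray, Dict[str, np.ndarray], np.ndarray]:
    """Per-column coding class, motif flags, and normalized read weights.

    ``coverage_a`` / ``coverage_b`` count reads covering each residue of the
    two sequences (alignment-local coordinates).  A column's weight is
    ``reads_A / T_A + reads_B / T_B``, correcting for the different total
    number of mapped reads per species.  ``motif_intervals`` maps a PWM id to
    A-sequence intervals; columns whose A residue falls inside are flagged.
    """
    coverage_a = np.asarray(coverage_a, dtype=float)
    coverage_b = np.asarray(coverage_b, dtype=float)
    reads_a = np.where(aln.a_pos >= 0, coverage_a[np.clip(aln.a_pos, 0, None)], 0.0)
    reads_b = np.where(aln.b_pos >= 0, coverage_b[np.clip(aln.b_pos, 0, None)], 0.0)
    for name, reads, total in (("A", reads_a, total_reads_a), ("B", reads_b, total_reads_b)):
        if reads.sum() > 0 and total <= 0:
            raise ValueError(f"species {name} has covered columns but zero total reads")
    cov_a = reads_a > 0
    cov_b = reads_b > 0
    classes = np.where(
        cov_a & cov_b, 2, np.where(cov_a | cov_b, 1, 0)
    )  # indexes CODING_CLASSES
    weights = (reads_a / total_reads_a if total_reads_a > 0 else 0.0 * reads_a) + (
        reads_b / total_reads_b if total_reads_b > 0 else 0.0 * reads_b
    )
    motif_flags: Dict[str, np.ndarray] = {}
    for pwm_id, ivs in (motif_intervals or {}).items():
        flag = np.zeros(aln.n_columns, dtype=bool)
        for s, e in ivs:
            flag |= (aln.a_pos >= s) & (aln.a_pos < e)
        motif_flags[pwm_id] = flag
    return classes, motif_flags, weights


def conservation_report(
    aln: ClusterAlignment,
    classes: np.ndarray,
    motif_flags: Dict[str, np.ndarray],
    weights: np.ndarray,
) -> pd.DataFrame:
    """Identity (plain and read-weighted) per residue class, with chi-square.

    Each class is tested against the all-aligned-columns baseline on a 2x2
    table (identical vs non-identical); for the weighted test, weights are
    rescaled to sum to the class column count so the table stays on the
    count scale.  Classes with no columns are omitted.
    """
    ng = aln.non_gap
    n_all = int(ng.sum())
    id_all = int(aln.identical[ng].sum())
    rows = []

    def add_class(name: str, mask: np.ndarray, use_weights: bool) -> None:
        mask = mask & ng
        n = int(mask.sum())
        if n == 0:
            return
        n_id = int(aln.identical[mask].sum())
        identity = 100.0 * n_id / n
        w = weights[mask]
        if use_weights and w.sum() > 0:
            w_scaled = w * (n / w.sum())
            wid = float(w_scaled[aln.identical[mask]].sum())
            weighted_identity = 100.0 * wid / n
            obs_id = int(round(wid))
        else:
            weighted_identity = identity
            obs_id = n_id
        if name == "all":
            chi2, p = 0.0, 1.0
        else:
            try:
                chi2, p = chi2_2x2(
                    ContingencyTable(obs_id, n - obs_id, id_all, n_all - id_all)
                )
            except ValueError:
                chi2, p = float("nan"), float("nan")
        rows.append(
            {
                "residue_class": name,
                "n_columns": n,
                "identity_pct": identity,
                "weighted_identity_pct": weighted_identity,
                "chi2": chi2,
                "p": p,
            }
        )

    add_class("all", np.ones(aln.n_columns, dtype=bool), use_weights=False)
    for code, name in enumerate(CODING_CLASSES):
        add_class(name, classes == code, use_weights=True)
    coding_any = classes >= 1
    add_class("coding_any_weighted", coding_any, use_weights=True)
    for pwm_id, flag in sorted(motif_flags.items()):
        add_class(f"motif_{pwm_id}", flag, use_weights=False)
    return pd.DataFrame(
        rows,
        columns=["residue_class", "n_columns", "identity_pct",
                 "weighted_identity_pct", "chi2", "p"],
    )
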