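"""PWM scanning and cluster-enrichment testing for transcription factor motifs.

The pipeline tests whether binding motifs of germline transcription factors
(A-Myb, RFX4) occur in piRNA clusters more often than their genomic frequency
predicts.  Scanning is log-odds against background base frequencies estimated
from the scanned sequence itself; enrichment is a 2x2 chi-square on scanned
positions (motif-hit positions vs non-hit positions, inside vs outside
clusters); bidirectional clusters additionally get a motif-position profile
relative to their central split point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .seqio import revcomp
from .stats import ContingencyTable, chi2_2x2

__all__ = [
    "PWM",
    "MotifHit",
    "EnrichmentResult",
    "consensus_pwm",
    "builtin_pwms",
    "parse_pwm_text",
    "parse_meme_minimal",
    "write_pwm_text",
    "scan_pwm",
    "motif_enrichment",
    "motif_position_profile",
]

# Synthetic stand-ins for the testis TF binding motifs scanned by the pipeline
# (real matrices are user-supplied inputs; these back the simulated world).
AMYB_CONSENSUS = "CAACGGTTAC"
RFX4_CONSENSUS = "GTTGCCATGGCAAC"

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class PWM:
    """Per-position base probabilities (rows A, C, G, T) with a score threshold.

    ``threshold`` is the fraction of the maximum attainable log-odds score a
    window must reach to be reported.
    """

    id: str
    matrix: np.ndarray  # shape (4, L)
    threshold: float = 0.8

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 4:
            raise ValueError("PWM matrix must be 4 x L with L >= 4")
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.id}: columns must sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    pwm_id: str
    chrom: str
    start: int
    end: int
    strand: str
    score: float


@dataclass(frozen=True)
class EnrichmentResult:
    pwm_id: str
    hits_in: int
    hits_out: int
    bp_in: int
    bp_out: int
    fold: float
    chi2: float
    p: float


def consensus_pwm(pwm_id: str, consensus: str, p_match: float = 0.85,
                  threshold: float = 0.8) -> PWM:
    """PWM concentrated on one consensus string (off-bases share 1 - p_match)."""
    L = len(consensus)
    m = np.full((4, L), (1.0 - p_match) / 3.0)
    for j, b in enumerate(consensus):
        m[_BASE_IDX[b], j] = p_match
    return PWM(pwm_id, m, threshold)


def builtin_pwms(threshold: float = 0.8) -> Dict[str, PWM]:
    """The two synthetic TF matrices that back the simulated world."""
    return {
        "AMYB": consensus_pwm("AMYB", AMYB_CONSENSUS, threshold=threshold),
        "RFX4": consensus_pwm("RFX4", RFX4_CONSENSUS, threshold=threshold),
    }


# ---------------------------------------------------------------------------
# parsers / writer


def parse_pwm_text(path: str | Path, pwm_id: str | None = None,
                   threshold: float = 0.8) -> PWM:
    """Read a plain probability matrix: 4 whitespace-separated rows (A, C, G, T).

    Rows may carry an ``A:``-style prefix; a leading ``>name`` line names the
    matrix.
    """
    rows: List[List[float]] = []
    name = pwm_id
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = name or line[1:].split()[0]
                continue
            parts = line.replace(":", " ").replace("|", " ").split()
            if parts[0].upper() in "ACGT" and len(parts[0]) == 1:
                parts = parts[1:]
            rows.append([float(x) for x in parts])
    if len(rows) != 4:
        raise ValueError(f"expected 4 matrix rows, got {len(rows)}")
    return PWM(name or Path(path).stem, np.array(rows), threshold)


def parse_meme_minimal(path: str | Path, threshold: float = 0.8) -> List[PWM]:
    """Parse MEME minimal format (letter-probability matrices, A C G T columns)."""
    pwms: List[PWM] = []
    name = None
    rows: List[List[float]] = []
    in_matrix = False

    def flush() -> None:
        nonlocal rows, in_matrix
        if name and rows:
            pwms.append(PWM(name, np.array(rows).T, threshold))
        rows, in_matrix = [], False

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                flush()
                name = line.split()[1]
            elif line.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix:
                if not line or not line[0].isdigit() and line[0] != "0" and not line[0] == ".":
                    in_matrix = False
                    continue
                rows.append([float(x) for x in line.split()[:4]])
    flush()
    return pwms


def write_pwm_text(pwm: PWM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.id}\n")
        for i, b in enumerate("ACGT"):
            fh.write(b + " " + " ".join(f"{x:.6f}" for x in pwm.matrix[i]) + "\n")


# ---------------------------------------------------------------------------
# scanning


def _base_frequencies(seqs: Iterable[str]) -> np.ndarray:
    counts = np.ones(4)  # tiny Laplace floor so log-odds stay finite
    for seq in seqs:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            counts[i] += int((arr == b).sum())
    return counts / counts.sum()


def _window_scores(seq: str, lom: np.ndarray) -> np.ndarray:
    L = lom.shape[1]
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        codes[arr == b] = i
    if len(codes) < L:
        return np.empty(0)
    lom5 = np.vstack([lom, np.full((1, L), -1e9)])  # non-ACGT kills a window
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return lom5[windows, np.arange(L)].sum(axis=1)


def scan_pwm(
    sequences: Dict[str, str] | str,
    pwm: PWM,
    threshold: float | None = None,
    pseudocount: float = 0.01,
    collapse: bool = True,
) -> List[MotifHit]:
    """Scan both strands; report windows scoring >= threshold x max log-odds.

    Background base frequencies are estimated from the scanned sequence.
    Overlapping same-strand hits of the same PWM within one motif length are
    collapsed to the best-scoring one (ties to the smallest coordinate).
    """
    if isinstance(sequences, str):
        sequences = {"seq": sequences}
    if threshold is None:
        threshold = pwm.threshold
    L = pwm.length
    bg = _base_frequencies(sequences.values())
    m = pwm.matrix + pseudocount
    m = m / m.sum(axis=0)
    lom = np.log2(m / bg[:, None])
    max_score = lom.max(axis=0).sum()
    cut = threshold * max_score

    hits: List[MotifHit] = []
    for chrom, seq in sequences.items():
        N = len(seq)
        for strand in "+-":
            scanned = seq if strand == "+" else revcomp(seq)
            scores = _window_scores(scanned, lom)
            raw = []
            for p in np.flatnonzero(scores >= cut):
                start = int(p) if strand == "+" else N - L - int(p)
                raw.append((start, float(scores[p])))
            raw.sort()
            if not collapse:
                hits.extend(
                    MotifHit(pwm.id, chrom, s, s + L, strand, sc) for s, sc in raw
                )
                continue
            # collapse same-strand hits within L bp, keeping the best score
            best: Tuple[int, float] | None = None
            for start, score in raw:
                if best is None or start - best[0] >= L:
                    if best is not None:
                        hits.append(MotifHit(pwm.id, chrom, best[0], best[0] + L, strand, best[1]))
                    best = (start, score)
                elif score > best[1]:
                    best = (start, score)
            if best is not None:
                hits.append(MotifHit(pwm.id, chrom, best[0], best[0] + L, strand, best[1]))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# enrichment and positional profile


def count_hits_in_intervals(
    hits: Sequence[MotifHit], intervals: Sequence[Tuple[str, int, int]]
) -> int:
    n = 0
    for h in hits:
        for chrom, s, e in intervals:
            if h.chrom == chrom and h.start >= s and h.end <= e:
                n += 1
                break
    return n


def motif_enrichment(
    pwm_id: str,
    hits_in: int,
    hits_total: int,
    bp_in: int,
    bp_total: int,
    motif_len: int,
) -> EnrichmentResult:
    """Chi-square enrichment of motif hits inside clusters vs the rest.

    2x2 table on scanned-position accounting: hit positions vs remaining
    positions, inside vs outside clusters.
    """
    if bp_in <= 0 or bp_total - bp_in <= 0:
        raise ValueError("cluster and non-cluster bp must both be positive")
    if hits_in > hits_total:
        raise ValueError("hits_in exceeds total hits")
    hits_out = hits_total - hits_in
    bp_out = bp_total - bp_in
    table = ContingencyTable(
        hits_in, max(bp_in - hits_in * motif_len, 0),
        hits_out, max(bp_out - hits_out * motif_len, 0),
    )
    chi2, p = chi2_2x2(table)
    dens_in = hits_in / bp_in
    dens_out = hits_out / bp_out
    fold = math.inf if dens_out == 0 else dens_in / dens_out
    return EnrichmentResult(pwm_id, hits_in, hits_out, bp_in, bp_out, fold, chi2, p)


def motif_position_profile(
    clusters: Sequence,
    hits: Sequence[MotifHit],
    bin_bp: int = 1000,
    span_bp: int = 25_000,
) -> pd.DataFrame:
    """Histogram of motif-start distances from bidirectional cluster centers.

    ``clusters`` must expose ``chrom``, ``topology`` and ``split_point`` (the
    clusters module's records) or ``split`` (simulation truth records).
    Returns a tidy frame (pwm, bin_center, count); empty with a warning-free
    zero-row frame when no bidirectional clusters exist.
    """
    centers = []
    for c in clusters:
        split = getattr(c, "split_point", None)
        if split is None:
            split = getattr(c, "split", None)
        if getattr(c, "topology", None) == "bidirectional" and split is not None:
            centers.append((c.chrom, int(split)))
    edges = np.arange(-span_bp, span_bp + bin_bp, bin_bp)
    rows = []
    pwm_ids = sorted({h.pwm_id for h in hits})
    for pwm_id in pwm_ids:
        counts = np.zeros(len(edges) - 1, dtype=int)
        for h in hits:
            if h.pwm_id != pwm_id:
                continue
            for chrom, center in centers:
                if h.chrom == chrom and -span_bp <= h.start - center < span_bp:
                    counts[(h.start - center + span_bp) // bin_bp] += 1
        for i, c in enumerate(counts):
            rows.append({"pwm": pwm_id, "bin_center": int((edges[i] + edges[i + 1]) // 2),
                         "count": int(c)})
    return pd.DataFrame(rows, columns=["pwm", "bin_center", "count"])
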