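"""Read placement on genomes and consensus sequences with hit-count weights.

Two mapping modes mirror the two analysis contexts of the pipeline:

* :func:`map_exact` — perfect full-length genome matches on either strand
  (the unit of all genome-wide analyses);
* :func:`map_mismatch` — Hamming-distance placements (no indels) against
  short consensus sequences, used when profiling reads along a TE consensus.

Every sequence that maps is then weighted by :func:`normalize_hits`:
a sequence with ``h`` genomic placements contributes weight ``m / h`` per
placement, where ``m`` is 1 (nonidentical-sequence counting) or the
collapsed read count (read counting).  Per-sequence weight totals are
conserved, so multi-mappers are never over-counted.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import numpy as np

from .seqio import revcomp

__all__ = [
    "SmallRNASeq",
    "GenomicHit",
    "WeightedHit",
    "GenomeIndex",
    "map_exact",
    "map_mismatch",
    "normalize_hits",
    "read_collapsed_fasta",
    "read_fastq_collapsed",
    "write_reads_fasta",
    "write_hits_tsv",
    "write_hits_bed",
]

_VALID_RE = re.compile(r"^[ACGT]+$")
MIN_READ_LEN, MAX_READ_LEN = 15, 50


@dataclass(frozen=True)
class SmallRNASeq:
    """A collapsed (nonidentical) small-RNA sequence with its read count."""

    id: str
    seq: str  # over {A,C,G,T}; U stored as T
    read_count: int = 1

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError(f"{self.id}: read_count must be >= 1")
        if not MIN_READ_LEN <= len(self.seq) <= MAX_READ_LEN:
            raise ValueError(f"{self.id}: length {len(self.seq)} outside [{MIN_READ_LEN},{MAX_READ_LEN}]")

    @property
    def is_valid(self) -> bool:
        return bool(_VALID_RE.match(self.seq))


@dataclass(frozen=True)
class GenomicHit:
    """One placement of a sequence, 0-based half-open, forward coordinates."""

    seq_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    mismatches: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the read's 5' end."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class WeightedHit(GenomicHit):
    """A genomic hit carrying a ``m / hit-count`` normalization weight."""

    weight: float = 1.0


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class GenomeIndex:
    """Sorted k-mer index over the forward strand of each chromosome.

    Minus-strand placements are found by looking up the reverse complement
    of the query, so only one strand needs indexing.
    """

    def __init__(self, genome: Dict[str, str], k: int = 12):
        if k < 4 or k > 31:
            raise ValueError("k must be in [4, 31]")
        self.k = k
        self.genome = genome
        self._sorted: Dict[str, np.ndarray] = {}
        self._order: Dict[str, np.ndarray] = {}
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        for chrom, seq in genome.items():
            if len(seq) < k:
                self._sorted[chrom] = np.empty(0, dtype=np.int64)
                self._order[chrom] = np.empty(0, dtype=np.int64)
                continue
            codes = _encode(seq)
            invalid = codes >= 4
            codes = np.where(invalid, 0, codes).astype(np.int64)
            windows = np.lib.stride_tricks.sliding_window_view(codes, k)
            vals = windows @ powers
            if invalid.any():  # poison k-mers containing non-ACGT bases
                bad = np.convolve(invalid.astype(np.int64), np.ones(k, dtype=np.int64), "valid") > 0
                vals = np.where(bad, -1, vals)
            order = np.argsort(vals, kind="stable")
            self._sorted[chrom] = vals[order]
            self._order[chrom] = order

    def positions(self, chrom: str, kmer: str) -> np.ndarray:
        """All start positions of ``kmer`` on the forward strand of ``chrom``."""
        codes = _encode(kmer)
        if (codes >= 4).any():
            return np.empty(0, dtype=np.int64)
        val = int(codes.astype(np.int64) @ (4 ** np.arange(self.k - 1, -1, -1, dtype=np.int64)))
        arr = self._sorted[chrom]
        lo = np.searchsorted(arr, val, "left")
        hi = np.searchsorted(arr, val, "right")
        return np.sort(self._order[chrom][lo:hi])


def _sorted_hits(hits: Iterable[GenomicHit]) -> List[GenomicHit]:
    return sorted(hits, key=lambda h: (h.chrom, h.start, h.strand, h.seq_id))


def map_exact(
    reads: Sequence[SmallRNASeq],
    genome: Dict[str, str],
    index: GenomeIndex | None = None,
) -> List[GenomicHit]:
    """All perfect full-length placements of each read on either strand.

    Reads containing non-ACGT symbols are skipped (one summary warning).
    """
    if index is None:
        index = GenomeIndex(genome)
    k = index.k
    hits: List[GenomicHit] = []
    skipped = 0
    for read in reads:
        if not read.is_valid:
            skipped += 1
            continue
        L = len(read.seq)
        rc = revcomp(read.seq)
        for chrom, seq in genome.items():
            for query, strand in ((read.seq, "+"), (rc, "-")):
                for pos in index.positions(chrom, query[:k]):
                    p = int(pos)
                    if p + L <= len(seq) and seq[p : p + L] == query:
                        hits.append(GenomicHit(read.id, chrom, p, p + L, strand, 0))
    if skipped:
        warnings.warn(f"skipped {skipped} reads containing non-ACGT symbols", stacklevel=2)
    return _sorted_hits(hits)


def _hamming_le(a: str, b: str, limit: int) -> int:
    """Hamming distance of equal-length strings, or limit+1 once exceeded."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def map_mismatch(
    reads: Sequence[SmallRNASeq],
    consensus: Dict[str, str],
    max_mm: int = 3,
) -> List[GenomicHit]:
    """All placements with Hamming distance <= ``max_mm`` (no indels).

    Uses pigeonhole seeding: a read with at most ``max_mm`` mismatches must
    contain one of ``max_mm + 1`` exact segments, which are located with
    plain substring search and verified by direct comparison.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    hits: List[GenomicHit] = []
    skipped = 0
    n_seg = max_mm + 1
    for read in reads:
        if not read.is_valid:
            skipped += 1
            continue
        L = len(read.seq)
        bounds = [round(i * L / n_seg) for i in range(n_seg + 1)]
        for name, target in consensus.items():
            T = len(target)
            if T < L:
                continue
            for query, strand in ((read.seq, "+"), (revcomp(read.seq), "-")):
                seen: set = set()
                for si in range(n_seg):
                    seg = query[bounds[si] : bounds[si + 1]]
                    off = bounds[si]
                    at = target.find(seg)
                    while at != -1:
                        start = at - off
                        if 0 <= start <= T - L and start not in seen:
                            mm = _hamming_le(query, target[start : start + L], max_mm)
                            if mm <= max_mm:
                                seen.add(start)
                                hits.append(GenomicHit(read.id, name, start, start + L, strand, mm))
                        at = target.find(seg, at + 1)
    if skipped:
        warnings.warn(f"skipped {skipped} reads containing non-ACGT symbols", stacklevel=2)
    return _sorted_hits(hits)


def normalize_hits(
    hits: Sequence[GenomicHit],
    reads: Sequence[SmallRNASeq] | Dict[str, SmallRNASeq],
    mode: str = "nonidentical",
) -> List[WeightedHit]:
    """Attach ``m / h`` weights; ``m`` is 1 or the read count by ``mode``.

    Sequences with zero hits simply do not appear (they cannot be weighted).
    """
    if mode not in ("nonidentical", "reads"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if not isinstance(reads, dict):
        reads = {r.id: r for r in reads}
    counts: Dict[str, int] = {}
    for h in hits:
        counts[h.seq_id] = counts.get(h.seq_id, 0) + 1
    out: List[WeightedHit] = []
    for h in hits:
        m = 1 if mode == "nonidentical" else reads[h.seq_id].read_count
        out.append(
            WeightedHit(h.seq_id, h.chrom, h.start, h.end, h.strand, h.mismatches,
                        weight=m / counts[h.seq_id])
        )
    return out


# ---------------------------------------------------------------------------
# I/O: collapsed FASTA dialect `>sr<id>_x<count>` and FASTQ collapsing


_COLLAPSED_RE = re.compile(r"_x(\d+)$")


def read_collapsed_fasta(path: str | Path) -> List[SmallRNASeq]:
    reads: List[SmallRNASeq] = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    reads.append(_make_read(name, "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            else:
                chunks.append(line.upper().replace("U", "T"))
    if name is not None:
        reads.append(_make_read(name, "".join(chunks)))
    return reads


def _make_read(header: str, seq: str) -> SmallRNASeq:
    m = _COLLAPSED_RE.search(header)
    count = int(m.group(1)) if m else 1
    return SmallRNASeq(header, seq, count)


def read_fastq_collapsed(path: str | Path, id_prefix: str = "sr") -> List[SmallRNASeq]:
    """Load FASTQ and collapse exact-identical sequences into counted records."""
    counts: Dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                s = line.strip().upper().replace("U", "T")
                counts[s] = counts.get(s, 0) + 1
    return [
        SmallRNASeq(f"{id_prefix}{j}_x{c}", s, c)
        for j, (s, c) in enumerate(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    ]


def write_reads_fasta(reads: Sequence[SmallRNASeq], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            header = r.id if _COLLAPSED_RE.search(r.id) else f"{r.id}_x{r.read_count}"
            fh.write(f">{header}\n{r.seq}\n")


def write_hits_tsv(hits: Sequence[WeightedHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tchrom\tstart0\tend\tstrand\tmismatches\tweight\n")
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\t"
                f"{h.mismatches}\t{h.weight:.6g}\n"
            )


def read_hits_tsv(path: str | Path) -> List[WeightedHit]:
    hits: List[WeightedHit] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("seq_id\t"):
            raise ValueError(f"{path}: not a hits TSV")
        for line in fh:
            seq_id, chrom, start, end, strand, mm, weight = line.rstrip("\n").split("\t")
            hits.append(
                WeightedHit(seq_id, chrom, int(start), int(end), strand, int(mm), float(weight))
            )
    return hits


def write_hits_bed(hits: Sequence[WeightedHit], path: str | Path) -> None:
    """BED6 with name = seq_id and score = round(1000 * weight)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.seq_id}\t"
                f"{int(round(1000 * h.weight))}\t{h.strand}\n"
            )
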