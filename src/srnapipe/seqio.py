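"""Sequence and interval I/O shared across the pipeline.

Conventions: genomes are ``dict[str, str]`` of upper-case DNA (U stored as T);
all coordinates are 0-based half-open; BED on disk matches this convention.
Collapsed small-RNA FASTA uses the ``>sr<id>_x<count>`` header dialect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "RepeatRecord",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "read_repeats_tsv",
    "write_repeats_tsv",
    "write_repeats_bed",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (keeps case, maps N -> N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatRecord:
    """One repeat/TE locus: family, class, strand and realized divergence."""

    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # '+' or '-'
    family: str
    te_class: str  # SINE, LINE, LTR, DNA, MITE, ...
    divergence_pct: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty repeat interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` dict (upper-cased)."""
    return {rec.id: str(rec.seq).upper().replace("U", "T") for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_REPEAT_HEADER = ["chrom", "start0", "end", "strand", "family", "class", "divergence_pct"]


def write_repeats_tsv(repeats: Sequence[RepeatRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_REPEAT_HEADER) + "\n")
        for r in repeats:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{r.family}\t"
                f"{r.te_class}\t{r.divergence_pct:.2f}\n"
            )


def write_repeats_bed(repeats: Sequence[RepeatRecord], path: str | Path) -> None:
    """BED6: name = family|class, score = round(10 * divergence)."""
    with open(path, "w") as fh:
        for r in repeats:
            score = int(round(10 * r.divergence_pct))
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.family}|{r.te_class}\t{score}\t{r.strand}\n"
            )


def read_repeats_tsv(path: str | Path) -> List[RepeatRecord]:
    """Read the tab-separated repeat table written by :func:`write_repeats_tsv`.

    Also tolerates the classic RepeatMasker ``.out`` column layout (whitespace
    separated, 15 columns, divergence in column 2, coordinates 1-based).
    """
    records: List[RepeatRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return records
    if lines[0].startswith("chrom\t"):
        for ln in lines[1:]:
            chrom, start, end, strand, family, te_class, div = ln.split("\t")
            records.append(
                RepeatRecord(chrom, int(start), int(end), strand, family, te_class, float(div))
            )
        return records
    # RepeatMasker .out: skip the two header lines if present
    body = [ln for ln in lines if not re.match(r"\s*(SW|score|\s*$)", ln)]
    for ln in body:
        parts = ln.split()
        if len(parts) < 11:
            continue
        div = float(parts[1])
        chrom = parts[4]
        start = int(parts[5]) - 1  # 1-based inclusive -> 0-based half-open
        end = int(parts[6])
        strand = "+" if parts[8] == "+" else "-"
        family = parts[9]
        te_class = parts[10].split("/")[0]
        records.append(RepeatRecord(chrom, start, end, strand, family, te_class, div))
    return records


def interval_union_bp(intervals: Iterable[tuple]) -> int:
    """Total bp covered by the union of (start, end) half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    total = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def _check_rc_roundtrip() -> None:  # pragma: no cover - module self-check
    assert revcomp("ACGT") == "ACGT"
    assert Seq("ACGTT").reverse_complement() == Seq(revcomp("ACGTT"))
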