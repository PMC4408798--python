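"""Secondary structure of TE transcripts vs small-RNA target sites.

Putative TE sense transcripts are folded to their minimum-free-energy
structure (ViennaRNA, lonely pairs disallowed), each base is flagged paired
or unpaired, and the paired-base content is summarized in 20 bp sliding
windows.  Small-RNA hits on the transcripts are then scored by the paired
fraction of their footprint, averaged per class (sense/antisense piRNAs vs
other sRNAs) with read-count weighting, and bootstrap resampling of the
sequence records provides standard deviations.

The folding engine is a pluggable contract (sequence -> dot-bracket string),
so unit tests can substitute a deterministic stub.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .seqio import RepeatRecord, revcomp

__all__ = [
    "FoldEngine",
    "FoldedTranscript",
    "StructureHit",
    "PairedFractionSummary",
    "viennarna_engine",
    "stub_engine",
    "dotbracket_paired",
    "fold_te_transcripts",
    "windowed_paired",
    "class_paired_fraction",
    "bootstrap_sd",
]

FoldEngine = Callable[[str], str]

HIT_CLASSES = ("piRNA_sense", "piRNA_antisense", "sRNA_sense", "sRNA_antisense")


def viennarna_engine(no_lonely_pairs: bool = True) -> FoldEngine:
    """MFE folding via the ViennaRNA Python bindings (T read as U)."""
    import RNA  # deferred: keeps the engine pluggable where RNA is absent

    md = RNA.md()
    md.noLP = 1 if no_lonely_pairs else 0

    def fold(seq: str) -> str:
        fc = RNA.fold_compound(seq, md)
        structure, _mfe = fc.mfe()
        return structure

    return fold


def stub_engine(structures: Dict[str, str]) -> FoldEngine:
    """Deterministic test engine: maps exact sequences to fixed dot-brackets."""

    def fold(seq: str) -> str:
        try:
            return structures[seq]
        except KeyError:
            raise RuntimeError("stub engine has no structure for this sequence")

    return fold


def dotbracket_paired(structure: str) -> np.ndarray:
    """Boolean paired flag per base; validates bracket balance."""
    paired = np.zeros(len(structure), dtype=bool)
    stack: List[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            paired[i] = paired[j] = True
        elif ch != ".":
            raise ValueError(f"unexpected structure symbol {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return paired


def dotbracket_pair_table(structure: str) -> np.ndarray:
    """Partner index per base (-1 unpaired), from a dot-bracket string."""
    table = np.full(len(structure), -1, dtype=np.int64)
    stack: List[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            table[i], table[j] = j, i
        elif ch != ".":
            raise ValueError(f"unexpected structure symbol {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return table


@dataclass
class FoldedTranscript:
    """A folded TE sense transcript with per-base paired state."""

    locus_id: str
    seq: str
    structure: str
    paired: np.ndarray

    @property
    def paired_fraction(self) -> float:
        return float(self.paired.mean()) if len(self.paired) else 0.0


def fold_te_transcripts(
    repeats: Sequence[RepeatRecord],
    genome: Dict[str, str],
    engine: Optional[FoldEngine] = None,
    max_fold_len: int = 10_000,
) -> Dict[str, FoldedTranscript]:
    """Fold the sense-strand transcript of each TE locus.

    Minus-strand loci are reverse complemented first.  Loci longer than
    ``max_fold_len`` are skipped with a warning; engine failures skip the
    locus.  Keys are ``family|chrom:start-end``.
    """
    if engine is None:
        engine = viennarna_engine()
    folded: Dict[str, FoldedTranscript] = {}
    skipped_long = 0
    for r in repeats:
        if r.length > max_fold_len:
            skipped_long += 1
            continue
        seq = genome[r.chrom][r.start : r.end]
        if r.strand == "-":
            seq = revcomp(seq)
        locus_id = f"{r.family}|{r.chrom}:{r.start}-{r.end}"
        try:
            structure = engine(seq)
        except Exception as exc:  # engine failure: skip, keep going
            warnings.warn(f"folding failed for {locus_id}: {exc}", stacklevel=2)
            continue
        folded[locus_id] = FoldedTranscript(locus_id, seq, structure, dotbracket_paired(structure))
    if skipped_long:
        warnings.warn(f"skipped {skipped_long} loci longer than {max_fold_len} bp", stacklevel=2)
    return folded


def windowed_paired(transcript: FoldedTranscript, window: int = 20) -> np.ndarray:
    """Paired-base count in each length-``window`` window (one per start).

    A transcript shorter than the window yields a single truncated window
    (with a warning).
    """
    paired = transcript.paired.astype(int)
    if len(paired) < window:
        warnings.warn(
            f"{transcript.locus_id}: shorter than window ({len(paired)} < {window})",
            stacklevel=2,
        )
        return np.array([paired.sum()])
    return np.convolve(paired, np.ones(window, dtype=int), "valid")


@dataclass(frozen=True)
class StructureHit:
    """A small-RNA placement on a folded transcript, in transcript coordinates."""

    locus_id: str
    start: int
    end: int
    hit_class: str  # piRNA_sense | piRNA_antisense | sRNA_sense | sRNA_antisense
    read_count: int = 1


@dataclass
class PairedFractionSummary:
    """Mean paired fraction (%) per small-RNA class, with bootstrap SDs."""

    class_mean_pct: Dict[str, float]
    class_n: Dict[str, int]
    overall_pct: float
    class_sd_pct: Dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "hit_class": cls,
                    "mean_paired_pct": self.class_mean_pct[cls],
                    "bootstrap_sd_pct": self.class_sd_pct.get(cls, float("nan")),
                    "n_hits": self.class_n[cls],
                }
                for cls in sorted(self.class_mean_pct)
            ]
        )


def _hit_fraction(folded: Dict[str, FoldedTranscript], h: StructureHit) -> float:
    ft = folded[h.locus_id]
    s, e = max(0, h.start), min(len(ft.paired), h.end)  # clip to the transcript
    if e <= s:
        raise ValueError(f"hit footprint outside transcript {h.locus_id}")
    return float(ft.paired[s:e].mean())


def class_paired_fraction(
    folded: Dict[str, FoldedTranscript],
    hits: Sequence[StructureHit],
    pooled_bases: bool = False,
) -> PairedFractionSummary:
    """Read-weighted mean paired fraction of hit footprints, per class.

    Default is per-hit averaging weighted by read count; ``pooled_bases``
    instead pools paired/total bases over all footprints of a class.  The
    overall reference is the unweighted paired fraction over all bases of
    all folded transcripts.
    """
    acc: Dict[str, List[Tuple[float, int, int]]] = {}
    for h in hits:
        frac = _hit_fraction(folded, h)
        s, e = max(0, h.start), min(len(folded[h.locus_id].paired), h.end)
        acc.setdefault(h.hit_class, []).append((frac, h.read_count, e - s))
    means: Dict[str, float] = {}
    ns: Dict[str, int] = {}
    for cls, items in acc.items():
        if pooled_bases:
            paired_bp = sum(f * ln * c for f, c, ln in items)
            total_bp = sum(ln * c for _f, c, ln in items)
            means[cls] = 100.0 * paired_bp / total_bp
        else:
            w = sum(c for _f, c, _ln in items)
            means[cls] = 100.0 * sum(f * c for f, c, _ln in items) / w
        ns[cls] = len(items)
    total_bases = sum(len(ft.paired) for ft in folded.values())
    paired_bases = sum(int(ft.paired.sum()) for ft in folded.values())
    overall = 100.0 * paired_bases / total_bases if total_bases else float("nan")
    return PairedFractionSummary(means, ns, overall)


def bootstrap_sd(
    folded: Dict[str, FoldedTranscript],
    hits: Sequence[StructureHit],
    n_reps: int = 100,
    seed: int = 0,
    pooled_bases: bool = False,
) -> Dict[str, float]:
    """Bootstrap SD of the per-class paired fractions.

    Resamples the sequence records (hits) with replacement to the original
    count, recomputes the statistic per replicate, and reports the SD across
    replicates.  Replicates missing a class contribute nothing to that
    class's SD.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    hits = list(hits)
    samples: Dict[str, List[float]] = {}
    for _ in range(n_reps):
        idx = rng.integers(0, len(hits), size=len(hits))
        rep = [hits[i] for i in idx]
        summary = class_paired_fraction(folded, rep, pooled_bases=pooled_bases)
        for cls, v in summary.class_mean_pct.items():
            samples.setdefault(cls, []).append(v)
    return {cls: float(np.std(vals)) for cls, vals in samples.items()}
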