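"""Synthetic small-RNA world with ground truth.

Generates a multi-chromosome genome seeded with transposon families at
controlled divergence, piRNA clusters emitting 1U-biased 26-34 nt reads with
planted ping-pong partners (exact 10 bp 5' overlap; the 10A bias of partners
follows automatically from the 5' U of the primary read), a hairpin MITE
emitting Dicer-duplex reads with 2 nt 3' overhangs, planted transcription
factor motif sites enriched in clusters, and a homologous second genome with
residue-class-specific substitution rates.  Every planted read's origin is
recorded, so downstream detectors can be scored against exact truth.

Randomness: a single :class:`numpy.random.Generator` seeded from
``SimConfig.seed`` is created by :func:`build_genome` and threaded through
the other operations via the returned :class:`GroundTruth`; there is no
global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .mapping import SmallRNASeq
from .motifs import AMYB_CONSENSUS, RFX4_CONSENSUS
from .seqio import RepeatRecord, revcomp

__all__ = [
    "TEFamily",
    "SimConfig",
    "GroundTruth",
    "build_genome",
    "plant_cluster_reads",
    "plant_hairpin_reads",
    "plant_background_reads",
    "derive_homolog",
    "transfer_reads_to_homolog",
    "perfect_hairpin_pairing",
    "write_truth_yaml",
]

BASES = "ACGT"
RESIDUE_CLASSES = ("non_coding", "piRNA_coding", "motif")  # class_map codes 0/1/2


@dataclass(frozen=True)
class TEFamily:
    """A transposon family to seed into the genome.

    For the MITE class the consensus is built as a perfect inverted repeat
    (stem-loop-stem) from ``SimConfig.hairpin_stem`` / ``hairpin_loop``;
    ``consensus_len`` is then derived, not taken from this record.
    """

    name: str
    te_class: str  # SINE | LINE | LTR | DNA | MITE
    consensus_len: int
    copies: int
    divergence_pct: float  # mean % divergence of copies from consensus

    def __post_init__(self) -> None:
        if self.te_class not in ("SINE", "LINE", "LTR", "DNA", "MITE"):
            raise ValueError(f"unknown TE class {self.te_class!r}")
        if self.consensus_len <= 0 or self.copies < 0 or self.divergence_pct < 0:
            raise ValueError(f"bad TE family spec {self}")


DEFAULT_FAMILIES: Tuple[TEFamily, ...] = (
    TEFamily("TuSINE", "SINE", 280, 50, 12.0),
    TEFamily("TuLINE", "LINE", 1500, 8, 18.0),
    TEFamily("MarDNA", "DNA", 600, 10, 15.0),
    TEFamily("MariN1", "MITE", 129, 12, 0.0),
)

DEFAULT_HOMOLOG_RATES: Dict[str, float] = {
    "piRNA_coding": 0.30,
    "non_coding": 0.40,
    "motif": 0.20,
}


@dataclass
class SimConfig:
    """All knobs of the synthetic world (defaults are the study conditions)."""

    seed: int = 1
    n_chrom: int = 3
    chrom_len: int = 300_000
    te_families: Tuple[TEFamily, ...] = DEFAULT_FAMILIES
    n_clusters: int = 4
    cluster_len: int = 10_000
    cluster_read_depth: int = 500
    u1_fraction: float = 0.85
    pingpong_fraction: float = 0.30
    hairpin_stem: int = 60
    hairpin_loop: int = 9
    duplex_read_len: int = 21
    motif_enrichment_fold: float = 3.0
    homolog_rates: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HOMOLOG_RATES))
    # secondary knobs
    bidir_fraction: float = 0.3  # fraction of clusters with bidirectional topology
    n_duplex_pairs: int = 150
    motif_sites_background: int = 60  # planted motif sites outside clusters
    read_len_range: Tuple[int, int] = (26, 34)
    count_cap: int = 10_000  # read-count distribution P(c) ~ c^-2, capped here
    indel_rate: float = 5e-4  # per-base indel probability outside clusters
    max_indel: int = 4
    background_per_kb: float = 0.0  # dispersed (non-cluster) reads per genomic kb

    def __post_init__(self) -> None:
        for name in ("n_chrom", "chrom_len", "n_clusters", "cluster_len",
                     "cluster_read_depth", "hairpin_stem", "hairpin_loop",
                     "duplex_read_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("u1_fraction", "pingpong_fraction", "bidir_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.chrom_len <= self.cluster_len:
            raise ValueError("chrom_len must exceed cluster_len")
        if self.read_len_range[0] > self.read_len_range[1]:
            raise ValueError("read_len_range inverted")


@dataclass
class ClusterTruth:
    chrom: str
    start: int
    end: int
    topology: str  # mono_plus | mono_minus | bidirectional
    split: Optional[int] = None  # for bidirectional: the central promoter point


@dataclass
class MotifSite:
    chrom: str
    start: int
    end: int
    pwm_id: str
    in_cluster: bool


Origin = Tuple[str, int, int, str, str]  # chrom, start, end, strand, kind


@dataclass
class GroundTruth:
    """Everything planted, recorded for downstream scoring."""

    cluster_intervals: List[ClusterTruth] = field(default_factory=list)
    te_loci: List[RepeatRecord] = field(default_factory=list)
    motif_sites: List[MotifSite] = field(default_factory=list)
    read_origins: Dict[str, List[Origin]] = field(default_factory=dict)
    pingpong_pairs: List[Tuple[str, str]] = field(default_factory=list)
    duplex_pairs: List[Tuple[str, str]] = field(default_factory=list)
    homolog_map: Dict[str, np.ndarray] = field(default_factory=dict)
    class_map: Dict[str, np.ndarray] = field(default_factory=dict)
    realized_sub_fraction: Dict[str, float] = field(default_factory=dict)
    rng: Optional[np.random.Generator] = None
    _next_id: int = 0

    def new_read_id(self) -> str:
        rid = f"sr{self._next_id}"
        self._next_id += 1
        return rid


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> Tuple[str, float]:
    """Substitute each base with probability ``rate`` (to a different base)."""
    if rate <= 0:
        return seq, 0.0
    arr = list(seq)
    mask = rng.random(len(arr)) < rate
    for i in np.flatnonzero(mask):
        old = arr[i]
        choices = [b for b in BASES if b != old]
        arr[i] = choices[rng.integers(0, 3)]
    realized = float(100.0 * mask.sum() / len(arr))
    return "".join(arr), realized


def _overlaps(ivs: List[Tuple[int, int]], s: int, e: int, margin: int = 0) -> bool:
    return any(s < oe + margin and os_ < e + margin for os_, oe in ivs)


def perfect_hairpin_pairing(stem: int, loop: int) -> np.ndarray:
    """Pairing map of a perfect inverted repeat: i pairs with L-1-i; loop -1."""
    total = 2 * stem + loop
    p = total - 1 - np.arange(total)
    p[stem : stem + loop] = -1
    return p


# ---------------------------------------------------------------------------
# build_genome


def build_genome(
    config: SimConfig,
) -> Tuple[Dict[str, str], List[RepeatRecord], GroundTruth]:
    """Plant TE copies, cluster intervals and motif sites into a random genome."""
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth(rng=rng)

    genome_bp = config.n_chrom * config.chrom_len
    mite_len = 2 * config.hairpin_stem + config.hairpin_loop
    te_bp = sum(
        (mite_len if f.te_class == "MITE" else f.consensus_len) * f.copies
        for f in config.te_families
    )
    if te_bp > genome_bp:
        raise ValueError(f"infeasible config: total TE bp {te_bp} > genome bp {genome_bp}")

    chroms = [f"chr{i + 1}" for i in range(config.n_chrom)]
    seqs = {c: bytearray(_rand_seq(rng, config.chrom_len), "ascii") for c in chroms}

    # family consensus sequences; the MITE is a perfect inverted repeat
    consensi: Dict[str, str] = {}
    for fam in config.te_families:
        if fam.te_class == "MITE":
            arm = _rand_seq(rng, config.hairpin_stem)
            consensi[fam.name] = arm + _rand_seq(rng, config.hairpin_loop) + revcomp(arm)
        else:
            consensi[fam.name] = _rand_seq(rng, fam.consensus_len)

    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    for fam in config.te_families:
        cons = consensi[fam.name]
        L = len(cons)
        for _ in range(fam.copies):
            for _try in range(300):
                chrom = chroms[rng.integers(0, len(chroms))]
                if config.chrom_len <= L:
                    raise ValueError("TE consensus longer than chromosome")
                s = int(rng.integers(0, config.chrom_len - L))
                if not _overlaps(occupied[chrom], s, s + L):
                    break
            else:
                raise ValueError(f"could not place copy of {fam.name}: genome too crowded")
            copy_div = fam.divergence_pct
            if copy_div > 0:  # independently drawn per-copy divergence
                copy_div = float(np.clip(rng.normal(copy_div, copy_div / 5.0), 0.0, 40.0))
            mutated, realized = _mutate(rng, cons, copy_div / 100.0)
            # MITEs stay on + so the planted duplex geometry is exact in genome coords
            strand = "+" if fam.te_class == "MITE" else ("+-"[rng.integers(0, 2)])
            inserted = mutated if strand == "+" else revcomp(mutated)
            seqs[chrom][s : s + L] = inserted.encode("ascii")
            occupied[chrom].append((s, s + L))
            truth.te_loci.append(
                RepeatRecord(chrom, s, s + L, strand, fam.name, fam.te_class, realized)
            )

    # cluster intervals: non-overlapping, well separated so they never merge
    n_bidir = int(round(config.bidir_fraction * config.n_clusters))
    placed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    for ci in range(config.n_clusters):
        for _try in range(500):
            chrom = chroms[rng.integers(0, len(chroms))]
            s = int(rng.integers(0, config.chrom_len - config.cluster_len))
            if not _overlaps(placed[chrom], s, s + config.cluster_len, margin=15_000):
                break
        else:
            raise ValueError("could not place clusters: reduce n_clusters or grow genome")
        placed[chrom].append((s, s + config.cluster_len))
        if ci < n_bidir:
            split = s + config.cluster_len // 2
            truth.cluster_intervals.append(
                ClusterTruth(chrom, s, s + config.cluster_len, "bidirectional", split)
            )
        else:
            topo = "mono_plus" if ci % 2 == 0 else "mono_minus"
            truth.cluster_intervals.append(
                ClusterTruth(chrom, s, s + config.cluster_len, topo, None)
            )

    _plant_motif_sites(seqs, occupied, truth, config, rng)

    genome = {c: bytes(b).decode("ascii") for c, b in seqs.items()}
    truth.te_loci.sort(key=lambda r: (r.chrom, r.start))
    return genome, sorted_repeats(truth.te_loci), truth


def sorted_repeats(records: Sequence[RepeatRecord]) -> List[RepeatRecord]:
    return sorted(records, key=lambda r: (r.chrom, r.start, r.end))


def _plant_motif_sites(
    seqs: Dict[str, bytearray],
    occupied: Dict[str, List[Tuple[int, int]]],
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> None:
    """Write exact motif consensus copies into the genome.

    Background sites are uniform outside clusters; in-cluster counts follow
    ``motif_enrichment_fold`` times the background per-bp density.  Sites
    avoid TE loci and each other so planted counts equal scannable counts.
    """
    consensus = {"AMYB": AMYB_CONSENSUS, "RFX4": RFX4_CONSENSUS}
    chroms = list(seqs)
    cluster_ivs: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    for cl in truth.cluster_intervals:
        cluster_ivs[cl.chrom].append((cl.start, cl.end))
    bp_in = sum(e - s for ivs in cluster_ivs.values() for s, e in ivs)
    bp_out = config.n_chrom * config.chrom_len - bp_in

    taken: Dict[str, List[Tuple[int, int]]] = {c: list(occupied[c]) for c in chroms}

    def place(pwm_id: str, in_cluster: bool) -> None:
        motif = consensus[pwm_id]
        L = len(motif)
        for _try in range(500):
            if in_cluster:
                cl = truth.cluster_intervals[rng.integers(0, len(truth.cluster_intervals))]
                chrom, s = cl.chrom, int(rng.integers(cl.start, cl.end - L))
            else:
                chrom = chroms[rng.integers(0, len(chroms))]
                s = int(rng.integers(0, config.chrom_len - L))
                if any(cs <= s < ce or cs < s + L <= ce for cs, ce in cluster_ivs[chrom]):
                    continue
            if _overlaps(taken[chrom], s, s + L):
                continue
            seqs[chrom][s : s + L] = motif.encode("ascii")
            taken[chrom].append((s, s + L))
            truth.motif_sites.append(MotifSite(chrom, s, s + L, pwm_id, in_cluster))
            return
        raise ValueError("could not place motif site: genome too crowded")

    for pwm_id in consensus:
        n_out = config.motif_sites_background
        density_out = n_out / bp_out if bp_out else 0.0
        n_in = int(round(config.motif_enrichment_fold * density_out * bp_in))
        for _ in range(n_out):
            place(pwm_id, in_cluster=False)
        for _ in range(n_in):
            place(pwm_id, in_cluster=True)


# ---------------------------------------------------------------------------
# read planting


def _sample_counts(rng: np.random.Generator, n: int, cap: int) -> np.ndarray:
    """Heavy-tailed collapsed read counts, P(c) proportional to c^-2, c <= cap."""
    c = np.arange(1, cap + 1, dtype=float)
    p = c**-2.0
    p /= p.sum()
    return rng.choice(np.arange(1, cap + 1), size=n, p=p)


def _collapse(
    planted: List[Tuple[str, int, Origin]],
    truth: GroundTruth,
    seq_of: Dict[str, str],
) -> List[SmallRNASeq]:
    """Collapse identical sequences, merging counts and origin provenance."""
    by_seq: Dict[str, List[str]] = {}
    for rid, _count, _origin in planted:
        by_seq.setdefault(seq_of[rid], []).append(rid)
    reads: List[SmallRNASeq] = []
    counts = {rid: c for rid, c, _ in planted}
    origins = {rid: o for rid, _, o in planted}
    for seq, rids in by_seq.items():
        keep = rids[0]
        total = sum(counts[r] for r in rids)
        truth.read_origins[keep] = [origins[r] for r in rids]
        reads.append(SmallRNASeq(keep, seq, total))
        # merged duplicates keep the surviving id in the pair lists
        if len(rids) > 1:
            alias = {r: keep for r in rids[1:]}
            truth.pingpong_pairs = [
                (alias.get(a, a), alias.get(b, b)) for a, b in truth.pingpong_pairs
            ]
            truth.duplex_pairs = [
                (alias.get(a, a), alias.get(b, b)) for a, b in truth.duplex_pairs
            ]
    reads.sort(key=lambda r: int(r.id[2:]))
    return reads


def _read_seq(genome: Dict[str, str], chrom: str, s: int, e: int, strand: str) -> str:
    sub = genome[chrom][s:e]
    return sub if strand == "+" else revcomp(sub)


def plant_cluster_reads(
    genome: Dict[str, str],
    truth: GroundTruth,
    config: SimConfig,
) -> List[SmallRNASeq]:
    """Emit 26-34 nt cluster reads with 1U bias and ping-pong partners.

    A fraction ``u1_fraction`` of primary reads starts with U (T on the
    template); the rest are rejection-sampled to start with a non-U base so
    the realized 5' U fraction equals the configured one.  With probability
    ``pingpong_fraction`` a primary read receives an opposite-strand partner
    whose 5' end overlaps it by exactly 10 bp; when the primary starts with
    U the partner's position 10 is the complementary A.
    """
    lmin, lmax = config.read_len_range
    if config.cluster_len < lmax:
        raise ValueError("cluster shorter than maximum read length")
    rng = truth.rng
    planted: List[Tuple[str, int, Origin]] = []
    seq_of: Dict[str, str] = {}

    def emit(chrom: str, s: int, e: int, strand: str, kind: str) -> str:
        rid = truth.new_read_id()
        seq_of[rid] = _read_seq(genome, chrom, s, e, strand)
        planted.append((rid, 1, (chrom, s, e, strand, kind)))
        return rid

    for cl in truth.cluster_intervals:
        chrom_len = len(genome[cl.chrom])
        for _ in range(config.cluster_read_depth):
            if cl.topology == "mono_plus":
                strand, lo, hi = "+", cl.start, cl.end
            elif cl.topology == "mono_minus":
                strand, lo, hi = "-", cl.start, cl.end
            else:  # bidirectional: divergent transcription from the split point
                if rng.random() < 0.5:
                    strand, lo, hi = "-", cl.start, cl.split
                else:
                    strand, lo, hi = "+", cl.split, cl.end
            L = int(rng.integers(lmin, lmax + 1))
            want_u1 = rng.random() < config.u1_fraction
            s = None
            for _try in range(200):
                cand = int(rng.integers(lo, hi - L + 1))
                fp_base = (
                    genome[cl.chrom][cand]
                    if strand == "+"
                    else revcomp(genome[cl.chrom][cand + L - 1])
                )
                if (fp_base == "T") == want_u1:
                    s = cand
                    break
            if s is None:
                s = int(rng.integers(lo, hi - L + 1))
            rid = emit(cl.chrom, s, s + L, strand, "primary")

            if rng.random() < config.pingpong_fraction:
                Lp = int(rng.integers(lmin, lmax + 1))
                if strand == "+":
                    ps, pe, pstrand = s + 10 - Lp, s + 10, "-"
                else:
                    ps, pe, pstrand = s + L - 10, s + L - 10 + Lp, "+"
                if 0 <= ps and pe <= chrom_len:
                    pid = emit(cl.chrom, ps, pe, pstrand, "partner")
                    truth.pingpong_pairs.append((rid, pid))

    counts = _sample_counts(rng, len(planted), config.count_cap)
    planted = [(rid, int(c), o) for (rid, _1, o), c in zip(planted, counts)]
    return _collapse(planted, truth, seq_of)


def plant_background_reads(
    genome: Dict[str, str],
    truth: GroundTruth,
    config: SimConfig,
) -> List[SmallRNASeq]:
    """Dispersed reads uniform over the genome outside cluster intervals.

    Emulates the low-level background of non-cluster small RNAs against
    which cluster prediction must discriminate; density is
    ``background_per_kb`` reads per kb, lengths uniform over 18-34 nt,
    random strand, no base bias.
    """
    rng = truth.rng
    cluster_ivs: Dict[str, List[Tuple[int, int]]] = {c: [] for c in genome}
    for cl in truth.cluster_intervals:
        cluster_ivs[cl.chrom].append((cl.start, cl.end))
    planted: List[Tuple[str, int, Origin]] = []
    seq_of: Dict[str, str] = {}
    for chrom, seq in genome.items():
        n = int(round(config.background_per_kb * len(seq) / 1000))
        placed = 0
        while placed < n:
            L = int(rng.integers(18, 35))
            s = int(rng.integers(0, len(seq) - L))
            if any(cs < s + L and s < ce for cs, ce in cluster_ivs[chrom]):
                continue
            strand = "+-"[rng.integers(0, 2)]
            rid = truth.new_read_id()
            seq_of[rid] = _read_seq(genome, chrom, s, s + L, strand)
            planted.append((rid, 1, (chrom, s, s + L, strand, "background")))
            placed += 1
    counts = _sample_counts(rng, len(planted), config.count_cap)
    planted = [(rid, int(c), o) for (rid, _1, o), c in zip(planted, counts)]
    return _collapse(planted, truth, seq_of)


def plant_hairpin_reads(
    genome: Dict[str, str],
    truth: GroundTruth,
    config: SimConfig,
) -> List[SmallRNASeq]:
    """Emit Dicer-duplex read pairs from the two arms of planted MITE loci.

    In the folded hairpin each read's 3' end extends exactly 2 nt past its
    partner's 5' end, and no read touches the loop.
    """
    L = config.duplex_read_len
    stem, loop = config.hairpin_stem, config.hairpin_loop
    if stem < L + 2:
        raise ValueError("hairpin stem shorter than duplex_read_len + 2")
    mites = [r for r in truth.te_loci if r.te_class == "MITE"]
    if not mites:
        raise ValueError("no MITE loci in the genome: cannot plant hairpin reads")
    total = 2 * stem + loop
    rng = truth.rng
    planted: List[Tuple[str, int, Origin]] = []
    seq_of: Dict[str, str] = {}
    # Dicer measures ~one duplex length from the 2 nt-overhang end of the
    # stem, so successive duplexes from one hairpin are phased: registers
    # start at 2 (leaving the terminal 3' overhang) and step by L
    registers = list(range(2, stem - L + 1, L))
    for _ in range(config.n_duplex_pairs):
        locus = mites[rng.integers(0, len(mites))]
        # both reads stay inside the transcript and both 3' overhangs come
        # out as exactly 2 nt (s2 = total - s1 - L + 2)
        s1 = registers[rng.integers(0, len(registers))]
        s2 = total - (s1 + L) + 2
        ga, gb = locus.start + s1, locus.start + s2
        rid_a = truth.new_read_id()
        seq_of[rid_a] = genome[locus.chrom][ga : ga + L]
        planted.append((rid_a, 1, (locus.chrom, ga, ga + L, "+", "duplex")))
        rid_b = truth.new_read_id()
        seq_of[rid_b] = genome[locus.chrom][gb : gb + L]
        planted.append((rid_b, 1, (locus.chrom, gb, gb + L, "+", "duplex")))
        truth.duplex_pairs.append((rid_a, rid_b))
    counts = _sample_counts(rng, len(planted), config.count_cap)
    planted = [(rid, int(c), o) for (rid, _1, o), c in zip(planted, counts)]
    return _collapse(planted, truth, seq_of)


# ---------------------------------------------------------------------------
# homologous genome


def derive_homolog(
    genome: Dict[str, str],
    truth: GroundTruth,
    config: SimConfig,
) -> Dict[str, str]:
    """Per-base substitution at residue-class rates, plus indels outside clusters.

    Residue classes: ``motif`` (planted motif sites), ``piRNA_coding`` (bases
    covered by at least one planted cluster read) and ``non_coding`` (the
    rest).  The per-base correspondence between the two genomes is retained
    in ``truth.homolog_map`` (-1 marks bases deleted in the homolog).
    """
    rates = dict(config.homolog_rates)
    for cls in RESIDUE_CLASSES:
        r = rates.get(cls)
        if r is None or not 0.0 <= r <= 1.0:
            raise ValueError(f"homolog rate for {cls!r} missing or outside [0, 1]")
    rng = truth.rng
    truth.class_map = {}
    homolog: Dict[str, str] = {}
    sub_counts = {cls: [0, 0] for cls in RESIDUE_CLASSES}  # [substituted, total]

    cluster_ivs: Dict[str, List[Tuple[int, int]]] = {c: [] for c in genome}
    for cl in truth.cluster_intervals:
        cluster_ivs[cl.chrom].append((cl.start, cl.end))

    for chrom, seq in genome.items():
        L = len(seq)
        cmap = np.zeros(L, dtype=np.uint8)
        for origins in truth.read_origins.values():
            for (c, s, e, _strand, kind) in origins:
                if c == chrom and kind in ("primary", "partner"):
                    cmap[s:e] = np.maximum(cmap[s:e], 1)
        for site in truth.motif_sites:
            if site.chrom == chrom:
                cmap[site.start : site.end] = 2
        truth.class_map[chrom] = cmap

        rate_per_base = np.choose(cmap, [rates["non_coding"], rates["piRNA_coding"], rates["motif"]])
        sub_mask = rng.random(L) < rate_per_base
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
        idx = np.searchsorted(np.sort(base_codes), arr)  # A<C<G<T is ASCII order
        shift = rng.integers(1, 4, size=L)
        new_idx = (idx + shift) % 4
        arr[sub_mask] = base_codes[new_idx[sub_mask]]
        for code, cls in enumerate(RESIDUE_CLASSES):
            sel = cmap == code
            sub_counts[cls][0] += int(sub_mask[sel].sum())
            sub_counts[cls][1] += int(sel.sum())

        # indels only outside clusters, so cluster columns stay well defined
        in_cluster = np.zeros(L, dtype=bool)
        for s, e in cluster_ivs[chrom]:
            in_cluster[s:e] = True
        indel_pos = np.flatnonzero((rng.random(L) < config.indel_rate) & ~in_cluster)
        deleted = np.zeros(L, dtype=bool)
        insertions: Dict[int, str] = {}
        for p in indel_pos:
            size = int(rng.integers(1, config.max_indel + 1))
            if rng.random() < 0.5:
                hi = min(L, p + size)
                if in_cluster[p:hi].any():
                    hi = p + int(np.argmax(in_cluster[p:hi]))
                deleted[p:hi] = True
            else:
                insertions[int(p)] = _rand_seq(rng, size)

        bmap = np.full(L, -1, dtype=np.int64)
        parts: List[str] = []
        bpos = 0
        sub_seq = arr.tobytes().decode("ascii")
        for i in range(L):
            if i in insertions:
                parts.append(insertions[i])
                bpos += len(insertions[i])
            if not deleted[i]:
                parts.append(sub_seq[i])
                bmap[i] = bpos
                bpos += 1
        homolog[chrom] = "".join(parts)
        truth.homolog_map[chrom] = bmap

    truth.realized_sub_fraction = {
        cls: (n_sub / n_tot if n_tot else 0.0) for cls, (n_sub, n_tot) in sub_counts.items()
    }
    return homolog


def transfer_reads_to_homolog(
    homolog: Dict[str, str],
    truth: GroundTruth,
    kinds: Tuple[str, ...] = ("primary", "partner"),
) -> List[SmallRNASeq]:
    """Project planted cluster reads through the homolog map onto genome B.

    The homologous species' read set: every planted read footprint is lifted
    over (clusters carry no indels, so footprints stay contiguous) and the
    genome-B sequence is read out, inheriting the original read count.
    """
    reads: List[SmallRNASeq] = []
    for rid, origins in sorted(truth.read_origins.items(), key=lambda kv: int(kv[0][2:])):
        chrom, s, e, strand, kind = origins[0]
        if kind not in kinds:
            continue
        bmap = truth.homolog_map[chrom]
        seg = bmap[s:e]
        if (seg < 0).any() or not (np.diff(seg) == 1).all():
            continue  # footprint broken by an indel: no homologous read
        bs, be = int(seg[0]), int(seg[-1]) + 1
        seq = homolog[chrom][bs:be]
        if strand == "-":
            seq = revcomp(seq)
        reads.append(SmallRNASeq(f"hb_{rid}", seq, 1))
    return reads


def write_truth_yaml(truth: GroundTruth, path: str | Path) -> None:
    """Structured text dump of the planted world (arrays omitted)."""
    doc = {
        "clusters": [
            {"chrom": c.chrom, "start": c.start, "end": c.end,
             "topology": c.topology, "split": c.split}
            for c in truth.cluster_intervals
        ],
        "te_loci": [
            {"chrom": r.chrom, "start": r.start, "end": r.end, "strand": r.strand,
             "family": r.family, "class": r.te_class,
             "divergence_pct": float(round(r.divergence_pct, 2))}
            for r in truth.te_loci
        ],
        "motif_sites": [
            {"chrom": m.chrom, "start": m.start, "end": m.end,
             "pwm": m.pwm_id, "in_cluster": m.in_cluster}
            for m in truth.motif_sites
        ],
        "n_reads": len(truth.read_origins),
        "pingpong_pairs": [list(p) for p in truth.pingpong_pairs],
        "duplex_pairs": [list(p) for p in truth.duplex_pairs],
        "realized_sub_fraction": {k: float(round(v, 5)) for k, v in truth.realized_sub_fraction.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
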