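"""Read placement: exact and mismatch mapping against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnapipe.mapping import (GenomicHit, SmallRNASeq, map_exact, map_mismatch,
                              normalize_hits, read_collapsed_fasta,
                              write_reads_fasta)
from srnapipe.seqio import revcomp

dna = st.text(alphabet="ACGT", min_size=15, max_size=40)


@settings(max_examples=50, derandomize=True)
@given(seq=dna)
def test_revcomp_is_an_involution(seq):
    assert revcomp(revcomp(seq)) == seq
    assert len(revcomp(seq)) == len(seq)


def _random_genome(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _oracle_exact(reads, genome):
    """Independent route: plain substring scanning with str.find."""
    hits = set()
    for r in reads:
        for chrom, seq in genome.items():
            for query, strand in ((r.seq, "+"), (revcomp(r.seq), "-")):
                at = seq.find(query)
                while at != -1:
                    hits.add((r.id, chrom, at, at + len(query), strand))
                    at = seq.find(query, at + 1)
    return hits


def _oracle_mismatch(reads, consensus, max_mm):
    """Independent route: numpy sliding-window Hamming distance."""
    hits = set()
    for r in reads:
        L = len(r.seq)
        for name, target in consensus.items():
            if len(target) < L:
                continue
            tarr = np.frombuffer(target.encode(), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(tarr, L)
            for query, strand in ((r.seq, "+"), (revcomp(r.seq), "-")):
                qarr = np.frombuffer(query.encode(), dtype=np.uint8)
                mm = (windows != qarr).sum(axis=1)
                for pos in np.flatnonzero(mm <= max_mm):
                    hits.add((r.id, name, int(pos), int(pos) + L, strand, int(mm[pos])))
    return hits


def test_forward_and_reverse_placements(rng):
    genome = {"chr1": _random_genome(rng, 2000)}
    fwd = SmallRNASeq("f", genome["chr1"][100:122])
    rev = SmallRNASeq("r", revcomp(genome["chr1"][300:322]))
    hits = map_exact([fwd, rev], genome)
    assert GenomicHit("f", "chr1", 100, 122, "+", 0) in hits
    assert GenomicHit("r", "chr1", 300, 322, "-", 0) in hits


def test_exact_matches_brute_force_scan(rng):
    genome = {"chr1": _random_genome(rng, 6000), "chr2": _random_genome(rng, 4000)}
    reads = []
    for i in range(100):  # planted (mappable) reads
        chrom = "chr1" if i % 2 else "chr2"
        L = int(rng.integers(18, 35))
        s = int(rng.integers(0, len(genome[chrom]) - L))
        seq = genome[chrom][s : s + L]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(SmallRNASeq(f"p{i}", seq))
    for i in range(100):  # random reads (mostly unmappable)
        reads.append(SmallRNASeq(f"r{i}", _random_genome(rng, int(rng.integers(18, 35)))))
    got = {(h.seq_id, h.chrom, h.start, h.end, h.strand) for h in map_exact(reads, genome)}
    assert got == _oracle_exact(reads, genome)


def test_mismatch_threshold_boundary(rng):
    target = _random_genome(rng, 120)
    seq = list(target[40:64])
    for j, b in ((2, "A"), (11, "C"), (20, "G")):
        seq[j] = b if seq[j] != b else "T"  # exactly 3 substitutions
    read = SmallRNASeq("m", "".join(seq))
    hit3 = map_mismatch([read], {"c": target}, max_mm=3)
    assert len(hit3) == 1 and hit3[0].start == 40 and hit3[0].mismatches == 3
    assert map_mismatch([read], {"c": target}, max_mm=2) == []


def test_mismatch_zero_equals_exact(rng):
    consensus = {"c": _random_genome(rng, 1500)}
    reads = [SmallRNASeq(f"x{i}", consensus["c"][s : s + 25])
             for i, s in enumerate(rng.integers(0, 1400, size=30))]
    mm0 = {(h.seq_id, h.chrom, h.start, h.strand) for h in map_mismatch(reads, consensus, 0)}
    ex = {(h.seq_id, h.chrom, h.start, h.strand) for h in map_exact(reads, consensus)}
    assert mm0 == ex


def test_mismatch_matches_brute_force(rng):
    consensus = {"c1": _random_genome(rng, 1200), "c2": _random_genome(rng, 800)}
    reads = []
    for i in range(40):
        src = consensus["c1" if i % 2 else "c2"]
        L = int(rng.integers(20, 31))
        s = int(rng.integers(0, len(src) - L))
        seq = list(src[s : s + L])
        for j in rng.choice(L, size=int(rng.integers(0, 4)), replace=False):
            seq[j] = "ACGT"[int(rng.integers(0, 4))]
        reads.append(SmallRNASeq(f"q{i}", "".join(seq)))
    got = {
        (h.seq_id, h.chrom, h.start, h.end, h.strand, h.mismatches)
        for h in map_mismatch(reads, consensus, 3)
    }
    assert got == _oracle_mismatch(reads, consensus, 3)


def test_strand_symmetry(rng):
    genome = {"chr1": _random_genome(rng, 3000)}
    reads = [SmallRNASeq(f"s{i}", genome["chr1"][s : s + 24])
             for i, s in enumerate(rng.integers(0, 2950, size=40))]
    rc_reads = [SmallRNASeq(r.id, revcomp(r.seq)) for r in reads]
    fwd = {(h.seq_id, h.start, h.end, h.strand) for h in map_exact(reads, genome)}
    rev = {(h.seq_id, h.start, h.end, {"+": "-", "-": "+"}[h.strand])
           for h in map_exact(rc_reads, genome)}
    assert fwd == rev


def test_non_acgt_reads_skipped_with_warning(rng):
    genome = {"chr1": _random_genome(rng, 500)}
    good = SmallRNASeq("g", genome["chr1"][10:35])
    bad = SmallRNASeq("b", "ACGTNACGTACGTACGTACGTACGT")
    with pytest.warns(UserWarning, match="skipped 1 reads"):
        hits = map_exact([good, bad], genome)
    assert {h.seq_id for h in hits} == {"g"}


def test_weight_normalization_and_conservation(rng):
    # one sequence with 4 genomic placements, one unique with read count 45
    unit = _random_genome(rng, 20)
    genome = {"chr1": unit + _random_genome(rng, 50) + unit + _random_genome(rng, 50)
              + unit + _random_genome(rng, 50) + unit + _random_genome(rng, 200)}
    multi = SmallRNASeq("multi", unit)
    uniq_seq = genome["chr1"][-40:-15]
    uniq = SmallRNASeq("uniq", uniq_seq, read_count=45)
    hits = map_exact([multi, uniq], genome)
    w_non = normalize_hits(hits, [multi, uniq], "nonidentical")
    multi_w = [h.weight for h in w_non if h.seq_id == "multi"]
    assert len(multi_w) == 4 and all(w == pytest.approx(0.25) for w in multi_w)
    assert sum(h.weight for h in w_non) == pytest.approx(2.0)  # one unit per sequence
    w_reads = normalize_hits(hits, [multi, uniq], "reads")
    assert [h.weight for h in w_reads if h.seq_id == "uniq"] == [pytest.approx(45)]
    assert sum(h.weight for h in w_reads) == pytest.approx(1 + 45)


def test_collapsed_fasta_roundtrip(tmp_path):
    reads = [SmallRNASeq("sr0_x7", "ACGTACGTACGTACGTACGTACGTA", 7),
             SmallRNASeq("sr1_x1", "TTTTACGTACGTACGTACGTACGTACGTT", 1)]
    path = tmp_path / "reads.fa"
    write_reads_fasta(reads, path)
    back = read_collapsed_fasta(path)
    assert [(r.id, r.seq, r.read_count) for r in back] == [
        (r.id, r.seq, r.read_count) for r in reads
    ]
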