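"""Cluster prediction, topology calls, TE content, divergence accumulation."""

import numpy as np
import pytest

from srnapipe.clusters import (ClusterParams, PiRNACluster, classify_topology,
                               cluster_te_content, divergence_accumulation,
                               predict_clusters)
from srnapipe.mapping import SmallRNASeq, WeightedHit
from srnapipe.seqio import RepeatRecord, interval_union_bp


def _read(i, length=30, first="T"):
    seq = first + "ACG" * ((length - 1) // 3 + 1)
    return SmallRNASeq(f"s{i}", seq[:length])


def _hit(i, start, strand, chrom="chr1", length=30, w=1.0):
    return WeightedHit(f"s{i}", chrom, start, start + length, strand, 0, w)


def _cluster_hits(n, lo, hi, strand="+", chrom="chr1", start_id=0, rng=None):
    rng = rng or np.random.default_rng(0)
    return [
        _hit(start_id + i, int(rng.integers(lo, hi - 30)), strand, chrom)
        for i in range(n)
    ]


def test_uniform_sparse_background_yields_nothing(rng):
    hits = [_hit(i, 10_000 * i, "+") for i in range(20)]  # 1 hit / 10 kb
    reads = [_read(i) for i in range(20)]
    assert predict_clusters(hits, {"chr1": 250_000}, reads) == []


def test_planted_cluster_recovered_with_tight_boundaries(rng):
    hits = _cluster_hits(300, 50_000, 60_000, "+", rng=rng)
    hits += [_hit(1000 + i, int(p), "+") for i, p in
             enumerate(rng.integers(0, 200_000, size=15))]  # sparse background
    reads = [_read(i) for i in range(300)] + [_read(1000 + i) for i in range(15)]
    found = predict_clusters(hits, {"chr1": 200_000}, reads)
    assert len(found) == 1
    c = found[0]
    assert abs(c.start - 50_000) <= 1000 and abs(c.end - 60_000) <= 1000
    assert c.topology == "mono_plus"
    assert c.u1_or_10A_fraction >= 0.75 and c.weighted_hits >= 250


def test_distant_clusters_never_merge(rng):
    hits = _cluster_hits(200, 20_000, 28_000, "+", rng=rng)
    hits += _cluster_hits(200, 78_000, 86_000, "-", start_id=500, rng=rng)
    reads = [_read(i) for i in range(200)] + [_read(500 + i) for i in range(200)]
    found = predict_clusters(hits, {"chr1": 200_000}, reads)
    assert len(found) == 2
    assert found[0].end < found[1].start
    assert {found[0].topology, found[1].topology} == {"mono_plus", "mono_minus"}


def test_failed_bias_predicate_rejects_cluster(rng):
    # dense but with 5' C reads and no position-10 A: not piRNA-like
    hits = _cluster_hits(300, 50_000, 60_000, "+", rng=rng)
    reads = [SmallRNASeq(f"s{i}", "C" + "CCG" * 10) for i in range(300)]
    assert predict_clusters(hits, {"chr1": 200_000}, reads) == []


def test_topology_all_plus_is_mono():
    hits = [_hit(i, 100 + 40 * i, "+") for i in range(30)]
    assert classify_topology(hits) == ("mono_plus", None)


def _brute_force_split(hits, params):
    """Exhaustive split scan over every coordinate between hits."""
    best = None
    positions = sorted({h.five_prime for h in hits})
    total = sum(h.weight for h in hits)
    for split in positions[1:]:
        left = [h for h in hits if h.five_prime < split]
        right = [h for h in hits if h.five_prime >= split]
        wl = sum(h.weight for h in left)
        wr = sum(h.weight for h in right)
        if min(wl, wr) < params.min_side_fraction * total:
            continue
        pl_minus = sum(h.weight for h in left if h.strand == "-") / wl
        pr_plus = sum(h.weight for h in right if h.strand == "+") / wr
        for score in (pl_minus + pr_plus, (1 - pl_minus) + (1 - pr_plus)):
            if best is None or score > best[0] + 1e-12:
                best = (score, split)
    return best


def test_bidirectional_split_matches_exhaustive_scan(rng):
    left = [_hit(i, int(p), "-") for i, p in enumerate(rng.integers(1000, 5000, size=60))]
    right = [_hit(100 + i, int(p), "+") for i, p in
             enumerate(rng.integers(5100, 9000, size=60))]
    hits = left + right
    params = ClusterParams()
    topo, split = classify_topology(hits, params)
    assert topo == "bidirectional"
    brute = _brute_force_split(hits, params)
    assert split == brute[1]
    # the true boundary lies between the left and right blocks
    assert 5000 <= split <= 5130


def test_interleaved_strands_are_mixed(rng):
    hits = [_hit(i, 1000 + 50 * i, "+-"[i % 2]) for i in range(60)]
    topo, split = classify_topology(hits)
    assert topo == "mixed" and split is None


def test_reported_clusters_satisfy_their_own_predicates(small_world, small_world_hits):
    reads = small_world["reads"]
    by_id = {r.id: r for r in reads}
    params = ClusterParams()
    lengths = {c: len(s) for c, s in small_world["genome"].items()}
    found = predict_clusters(small_world_hits, lengths, reads, params)
    assert found, "expected planted clusters to be recovered"
    for c in found:
        assert c.size >= params.min_size
        assert c.u1_or_10A_fraction >= params.biased_fraction
        assert c.n_nonidentical >= params.min_nonidentical


def test_invariance_under_rename_and_translation(small_world, small_world_hits):
    reads = small_world["reads"]
    lengths = {c: len(s) for c, s in small_world["genome"].items()}
    base = predict_clusters(small_world_hits, lengths, reads)
    shift = 1000
    moved = [
        WeightedHit(h.seq_id, "scaf_" + h.chrom, h.start + shift, h.end + shift,
                    h.strand, 0, h.weight)
        for h in small_world_hits
    ]
    lengths2 = {"scaf_" + c: n + shift for c, n in lengths.items()}
    found2 = predict_clusters(moved, lengths2, reads)
    got = [(c.chrom, c.start - shift, c.end - shift, c.topology) for c in found2]
    want = [("scaf_" + c.chrom, c.start, c.end, c.topology) for c in base]
    assert got == want


def _cl(chrom, start, end):
    return PiRNACluster(chrom, start, end, "mono_plus", None, 100, 100.0, 0.9)


def test_te_content_simple_fraction_and_flattening():
    clusters = [_cl("chr1", 10_000, 20_000)]
    lengths = {"chr1": 100_000}
    none = cluster_te_content(clusters, [], lengths)
    assert none.empty or (none["cluster_fraction"] == 0).all()
    repeats = [
        RepeatRecord("chr1", 12_000, 14_000, "+", "S1", "SINE", 5.0),
        RepeatRecord("chr1", 13_000, 14_500, "+", "S2", "SINE", 8.0),  # overlaps S1
    ]
    frame = cluster_te_content(clusters, repeats, lengths)
    sine = frame[frame.te_class == "SINE"].iloc[0]
    union_bp = interval_union_bp([(12_000, 14_000), (13_000, 14_500)])
    assert union_bp == 2500
    assert sine.cluster_fraction == pytest.approx(2500 / 10_000)
    assert sine.genome_fraction == pytest.approx(2500 / 100_000)


def test_te_content_two_kb_sine_in_ten_kb_cluster():
    frame = cluster_te_content(
        [_cl("chr1", 0, 10_000)],
        [RepeatRecord("chr1", 4000, 6000, "+", "S1", "SINE", 3.0)],
        {"chr1": 50_000},
    )
    assert frame.iloc[0].cluster_fraction == pytest.approx(0.2)


def test_accumulation_zero_divergence_step_function():
    repeats = [RepeatRecord("chr1", i * 1000, i * 1000 + 200, "+", "F", "SINE", 0.0)
               for i in range(5)]
    curve = divergence_accumulation(repeats, [], ["F"])
    assert curve.genome_cum[-1] == pytest.approx(1.0)
    assert (curve.genome_cum[curve.bins == 0.0] == pytest.approx(1.0))


def test_accumulation_monotone_and_complete(small_world):
    repeats = small_world["repeats"]
    clusters = [_cl(c.chrom, c.start, c.end) for c in small_world["truth"].cluster_intervals]
    fams = sorted({r.family for r in repeats if r.divergence_pct > 0})
    curve = divergence_accumulation(repeats, clusters, fams)
    assert (np.diff(curve.genome_cum) >= -1e-12).all()
    assert curve.genome_cum[-1] == pytest.approx(1.0)


def test_missing_family_warns_empty():
    with pytest.warns(UserWarning, match="no repeat loci"):
        curve = divergence_accumulation(
            [RepeatRecord("chr1", 0, 100, "+", "F", "SINE", 1.0)], [], ["absent"]
        )
    assert len(curve.bins) == 0


def test_invalid_params_raise():
    with pytest.raises(ValueError):
        ClusterParams(length_min=34, length_max=24)
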