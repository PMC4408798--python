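"""The synthetic world: determinism, planted signals, ground-truth bookkeeping."""

import numpy as np
import pytest

from srnapipe import simdata
from srnapipe.seqio import revcomp


def _tiny(**kw):
    base = dict(
        seed=5, n_chrom=2, chrom_len=60_000, n_clusters=2, cluster_len=5000,
        cluster_read_depth=150,
        te_families=(
            simdata.TEFamily("S1", "SINE", 200, 10, 10.0),
            simdata.TEFamily("M1", "MITE", 129, 4, 0.0),
        ),
        n_duplex_pairs=30, motif_sites_background=10,
    )
    base.update(kw)
    return simdata.SimConfig(**base)


def test_seed_determinism_is_bitwise():
    worlds = []
    for _ in range(2):
        cfg = _tiny()
        genome, repeats, truth = simdata.build_genome(cfg)
        reads = simdata.plant_cluster_reads(genome, truth, cfg)
        reads += simdata.plant_hairpin_reads(genome, truth, cfg)
        homolog = simdata.derive_homolog(genome, truth, cfg)
        worlds.append((genome, [(r.chrom, r.start, r.family) for r in repeats],
                       [(r.id, r.seq, r.read_count) for r in reads], homolog))
    assert worlds[0] == worlds[1]


def test_zero_divergence_copies_are_identical():
    cfg = _tiny(te_families=(simdata.TEFamily("S1", "SINE", 200, 8, 0.0),))
    genome, repeats, truth = simdata.build_genome(cfg)
    seqs = set()
    for r in repeats:
        s = genome[r.chrom][r.start : r.end]
        seqs.add(s if r.strand == "+" else revcomp(s))
        assert r.divergence_pct == 0.0
    assert len(seqs) == 1  # every copy equals the consensus


def test_zero_copies_give_empty_annotation():
    cfg = _tiny(te_families=(simdata.TEFamily("S1", "SINE", 200, 0, 10.0),))
    _genome, repeats, _truth = simdata.build_genome(cfg)
    assert repeats == []


def test_infeasible_te_load_raises():
    cfg = _tiny(te_families=(simdata.TEFamily("S1", "SINE", 5000, 100, 0.0),))
    with pytest.raises(ValueError, match="infeasible"):
        simdata.build_genome(cfg)


def test_full_u1_bias_on_primaries():
    cfg = _tiny(u1_fraction=1.0, pingpong_fraction=0.0)
    genome, _repeats, truth = simdata.build_genome(cfg)
    reads = simdata.plant_cluster_reads(genome, truth, cfg)
    by_id = {r.id: r for r in reads}
    for rid, origins in truth.read_origins.items():
        if origins[0][4] == "primary":
            assert by_id[rid].seq[0] == "T"


def test_pingpong_partner_rate_by_construction():
    cfg = _tiny(pingpong_fraction=0.5, cluster_read_depth=1000)
    genome, _repeats, truth = simdata.build_genome(cfg)
    simdata.plant_cluster_reads(genome, truth, cfg)
    n_primary = sum(1 for o in truth.read_origins.values() if o[0][4] == "primary")
    assert len(truth.pingpong_pairs) >= 0.45 * n_primary


def test_partner_geometry_and_10A():
    """Partners overlap the primary's 5' end by exactly 10 bp; U1 primaries
    imply an A at partner position 10 (complementarity)."""
    cfg = _tiny(pingpong_fraction=1.0, u1_fraction=1.0)
    genome, _repeats, truth = simdata.build_genome(cfg)
    reads = {r.id: r for r in simdata.plant_cluster_reads(genome, truth, cfg)}
    assert truth.pingpong_pairs
    for rid, pid in truth.pingpong_pairs:
        (c1, s1, e1, st1, _), (c2, s2, e2, st2, _) = (
            truth.read_origins[rid][0], truth.read_origins[pid][0],
        )
        assert c1 == c2 and st1 != st2
        if st1 == "+":
            assert e2 - s1 == 10  # minus partner 5' end at s1 + 9
        else:
            assert e1 - s2 == 10
        assert reads[pid].seq[9] == "A"


def test_pingpong_zero_matches_permuted_background(rng):
    """With no planted partners the exact-10 overlap count is background-level:
    compared against permuting minus-read 5' positions (permutation oracle)."""
    cfg = _tiny(pingpong_fraction=0.0, bidir_fraction=1.0, cluster_read_depth=600)
    genome, _repeats, truth = simdata.build_genome(cfg)
    simdata.plant_cluster_reads(genome, truth, cfg)

    plus5, minus5 = [], []
    for origins in truth.read_origins.values():
        for (c, s, e, st, kind) in origins:
            if kind != "primary":
                continue
            (plus5 if st == "+" else minus5).append((c, s if st == "+" else e - 1))

    def count10(minus_positions):
        plus_set = {}
        for c, p in plus5:
            plus_set.setdefault(c, set()).add(p)
        return sum(1 for c, m in minus_positions if (m - 9) in plus_set.get(c, ()))

    observed = count10(minus5)
    null = []
    by_chrom = {}
    for c, m in minus5:
        by_chrom.setdefault(c, []).append(m)
    for _ in range(60):
        perm = []
        for c, ms in by_chrom.items():
            lo, hi = min(ms), max(ms)
            perm.extend((c, int(x)) for x in rng.integers(lo, hi + 1, size=len(ms)))
        null.append(count10(perm))
    mu, sd = float(np.mean(null)), float(np.std(null))
    assert observed <= mu + 4 * max(sd, 1.0)


def test_hairpin_duplex_geometry_and_loop():
    cfg = _tiny()
    genome, repeats, truth = simdata.build_genome(cfg)
    simdata.plant_cluster_reads(genome, truth, cfg)
    simdata.plant_hairpin_reads(genome, truth, cfg)
    pm = simdata.perfect_hairpin_pairing(cfg.hairpin_stem, cfg.hairpin_loop)
    total = len(pm)
    mites = [(r.chrom, r.start, r.end) for r in repeats if r.te_class == "MITE"]
    for rid_a, rid_b in truth.duplex_pairs:
        (c, sa, ea, _sta, _), (c2, sb, eb, _stb, _) = (
            truth.read_origins[rid_a][0], truth.read_origins[rid_b][0],
        )
        locus = next((m for m in mites if m[0] == c and m[1] <= sa and ea <= m[2]), None)
        assert locus is not None, "duplex read outside any MITE locus"
        assert locus[1] <= sb and eb <= locus[2]
        la, lb = sa - locus[1], sb - locus[1]
        ea_l, eb_l = ea - locus[1], eb - locus[1]
        # both reads on stem arms, never the loop
        assert (pm[la:ea_l] >= 0).all() and (pm[lb:eb_l] >= 0).all()
        # 2 nt 3' overhangs on both sides of the folded duplex
        assert lb - pm[ea_l - 1] == 2
        assert la - pm[eb_l - 1] == 2


def test_hairpin_stem_too_short_raises():
    cfg = _tiny(hairpin_stem=20, duplex_read_len=21)
    genome, _repeats, truth = simdata.build_genome(cfg)
    with pytest.raises(ValueError, match="stem"):
        simdata.plant_hairpin_reads(genome, truth, cfg)


def test_homolog_zero_rates_identity():
    cfg = _tiny(homolog_rates={"piRNA_coding": 0.0, "non_coding": 0.0, "motif": 0.0},
                indel_rate=0.0)
    genome, _repeats, truth = simdata.build_genome(cfg)
    simdata.plant_cluster_reads(genome, truth, cfg)
    homolog = simdata.derive_homolog(genome, truth, cfg)
    assert homolog == genome
    for chrom, bmap in truth.homolog_map.items():
        assert (bmap == np.arange(len(genome[chrom]))).all()


def test_homolog_full_rates_substitute_everything():
    cfg = _tiny(homolog_rates={"piRNA_coding": 1.0, "non_coding": 1.0, "motif": 1.0},
                indel_rate=0.0)
    genome, _repeats, truth = simdata.build_genome(cfg)
    simdata.plant_cluster_reads(genome, truth, cfg)
    homolog = simdata.derive_homolog(genome, truth, cfg)
    for chrom in genome:
        assert all(a != b for a, b in zip(genome[chrom], homolog[chrom]))


def test_homolog_invalid_rate_raises():
    cfg = _tiny(homolog_rates={"piRNA_coding": 1.5, "non_coding": 0.4, "motif": 0.2})
    genome, _repeats, truth = simdata.build_genome(cfg)
    with pytest.raises(ValueError, match="rate"):
        simdata.derive_homolog(genome, truth, cfg)


def test_homolog_realized_rates_within_three_binomial_sd():
    cfg = _tiny(chrom_len=100_000)
    genome, _repeats, truth = simdata.build_genome(cfg)
    simdata.plant_cluster_reads(genome, truth, cfg)
    simdata.derive_homolog(genome, truth, cfg)
    for cls, rate in cfg.homolog_rates.items():
        realized = truth.realized_sub_fraction[cls]
        n = int((np.concatenate([truth.class_map[c] for c in genome])
                 == simdata.RESIDUE_CLASSES.index(cls)).sum())
        sd = np.sqrt(rate * (1 - rate) / n)
        assert abs(realized - rate) <= 3 * sd


def test_motif_columns_better_conserved_than_noncoding():
    cfg = _tiny(homolog_rates={"piRNA_coding": 0.3, "non_coding": 0.4, "motif": 0.05})
    genome, _repeats, truth = simdata.build_genome(cfg)
    simdata.plant_cluster_reads(genome, truth, cfg)
    homolog = simdata.derive_homolog(genome, truth, cfg)
    ident = {0: [0, 0], 2: [0, 0]}  # class code -> [identical, total]
    for chrom in genome:
        cmap, bmap = truth.class_map[chrom], truth.homolog_map[chrom]
        for i, code in enumerate(cmap):
            if code in (0, 2) and bmap[i] >= 0:
                ident[code][1] += 1
                ident[code][0] += genome[chrom][i] == homolog[chrom][bmap[i]]
    id_nc = ident[0][0] / ident[0][1]
    id_mo = ident[2][0] / ident[2][1]
    assert id_mo > id_nc


def test_read_provenance_unique_and_counts_heavy_tailed(small_world):
    truth, reads = small_world["truth"], small_world["reads"]
    assert len({r.id for r in reads}) == len(reads)
    assert set(r.id for r in reads) == set(truth.read_origins)
    counts = np.array([r.read_count for r in reads])
    assert counts.min() >= 1
    assert counts.max() > 10  # heavy tail reaches far beyond the median
    assert np.median(counts) <= 2


def test_truth_yaml_roundtrip(tmp_path, small_world):
    import yaml

    path = tmp_path / "truth.yaml"
    simdata.write_truth_yaml(small_world["truth"], path)
    doc = yaml.safe_load(path.read_text())
    assert doc["n_reads"] == len(small_world["truth"].read_origins)
    assert len(doc["clusters"]) == small_world["config"].n_clusters
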