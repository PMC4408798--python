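import numpy as np
import pytest

from srnapipe import simdata
from srnapipe.mapping import map_exact, normalize_hits


@pytest.fixture(scope="session")
def small_config():
    """A compact synthetic world: fast to build, still exercises everything."""
    return simdata.SimConfig(
        seed=11,
        n_chrom=2,
        chrom_len=150_000,
        n_clusters=2,
        cluster_len=8000,
        cluster_read_depth=300,
        te_families=(
            simdata.TEFamily("TuSINE", "SINE", 280, 20, 12.0),
            simdata.TEFamily("TuLINE", "LINE", 1200, 4, 18.0),
            simdata.TEFamily("MariN1", "MITE", 129, 6, 0.0),
        ),
        n_duplex_pairs=60,
        motif_sites_background=30,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    genome, repeats, truth = simdata.build_genome(small_config)
    reads = simdata.plant_cluster_reads(genome, truth, small_config)
    reads += simdata.plant_hairpin_reads(genome, truth, small_config)
    return {
        "config": small_config,
        "genome": genome,
        "repeats": repeats,
        "truth": truth,
        "reads": reads,
    }


@pytest.fixture(scope="session")
def small_world_hits(small_world):
    hits = map_exact(small_world["reads"], small_world["genome"])
    whits = normalize_hits(hits, small_world["reads"])
    return whits


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
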