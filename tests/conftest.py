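import pytest

import exoprof as xp


@pytest.fixture(scope="session")
def small_genome():
    """80 kb genome with 30 widely spaced planted sites (unit-test scale)."""
    g = xp.generate_genome(xp.GenomeSpec(length=80_000, seed=101))
    return xp.plant_motifs(g, n_sites=30, min_spacing=1300, seed=102)


@pytest.fixture(scope="session")
def big_genome():
    """300 kb genome with 200 planted sites (profiling scale)."""
    g = xp.generate_genome(xp.GenomeSpec(length=300_000, seed=1))
    return xp.plant_motifs(g, n_sites=200, min_spacing=1200, seed=2)


@pytest.fixture(scope="session")
def library_factory(big_genome):
    """Memoized library simulator over the shared 200-site genome."""
    genome, sites = big_genome
    cache = {}

    def make(version, seed=11, **overrides):
        key = (version, seed, tuple(sorted(overrides.items())))
        if key not in cache:
            cfg = xp.SimConfig.for_version(version, seed=seed, **overrides)
            records, truth = xp.simulate_library(genome, sites, cfg)
            cache[key] = (records, truth, cfg)
        return cache[key]

    return make
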