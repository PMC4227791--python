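"""Shared fixtures: one default synthetic dataset reused across the suite."""

import pytest

import gcckit
from gcckit import core, netstats, synth


@pytest.fixture(scope="session")
def default_spec():
    return gcckit.SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def genome(default_spec):
    return synth.generate_genome(default_spec)


@pytest.fixture(scope="session")
def annotations(default_spec, genome):
    return synth.generate_annotations(default_spec, genome)


@pytest.fixture(scope="session")
def fragments(genome, annotations):
    fr = core.digest_genome(genome)
    return synth.mark_unique_fragments(fr, annotations["repeat"])


@pytest.fixture(scope="session")
def network_g1(default_spec, fragments, annotations):
    return synth.generate_network(default_spec, fragments, annotations, "G1")


@pytest.fixture(scope="session")
def cutoff_g1(network_g1):
    return netstats.fdr_cutoff(network_g1, 0.05, n_permutations=30, seed=0)


@pytest.fixture(scope="session")
def filtered_g1(network_g1, fragments, cutoff_g1):
    return core.filter_network(network_g1, fragments, cutoff_g1,
                               require_unique=True, drop_adjacent=True)


@pytest.fixture(scope="session")
def toy_genome():
    """Tiny explicit genome for digestion and coordinate tests."""
    seqs = {
        "chrA": "AAATTAATCCGGGGATTAATGG",   # sites at 2 and 14
        "chrB": "CCCCCCCCCC",               # no site
    }
    return core.GenomeAssembly.from_sequences(seqs, order=["chrA", "chrB"])


@pytest.fixture(scope="session")
def toy_fragments(toy_genome):
    return core.digest_genome(toy_genome)


def make_random_network(rng, fragments, n_interactions, max_freq=8,
                        phase="G1"):
    """Uniformly random distinct fragment pairs with random frequencies."""
    ids = [f.id for f in fragments]
    freq = {}
    while len(freq) < n_interactions:
        a, b = rng.choice(ids, size=2, replace=False)
        key = (min(int(a), int(b)), max(int(a), int(b)))
        freq.setdefault(key, int(rng.integers(1, max_freq + 1)))
    return core.InteractionNetwork(phase, freq)
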