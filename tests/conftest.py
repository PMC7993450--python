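import pytest

import cobarscaf as cs


@pytest.fixture(scope="session")
def default_sim():
    """The reference simulation: 2 Mb genome, ~200 contigs (mean 10 kb),
    50 kb fragments at 10x physical coverage, one fragment per barcode,
    no chimeras."""
    params = cs.SimParams(rng_seed=1)
    genome, contigs, truth, alignments = cs.simulate_dataset(params)
    return params, genome, contigs, truth, alignments


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Full pipeline result on the reference simulation."""
    _, _, contigs, truth, alignments = default_sim
    result = cs.run_pipeline(contigs, alignments)
    return contigs, truth, alignments, result


@pytest.fixture(scope="session")
def small_sim():
    """A light 400 kb simulation for unit-level checks."""
    params = cs.SimParams(genome_length=400_000, rng_seed=7)
    genome, contigs, truth, alignments = cs.simulate_dataset(params)
    return params, genome, contigs, truth, alignments
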