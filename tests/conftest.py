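import pytest

from plasmidkit import synthdata


@pytest.fixture(scope="session")
def default_params():
    return synthdata.FamilyParams()


@pytest.fixture(scope="session")
def ancestor(default_params):
    """Full-size (~6.2 kb) ancestor with all planted elements."""
    return synthdata.generate_ancestor(default_params, seed=7)


@pytest.fixture(scope="session")
def family(default_params):
    """Five-plasmid family evolved from the full-size ancestor."""
    anc, truth0 = synthdata.generate_ancestor(default_params, seed=7)
    seqs, truth = synthdata.evolve_family(anc, truth0, default_params, seed=11)
    return seqs, truth


@pytest.fixture(scope="session")
def family_with_events(default_params):
    """Family with a methylase insertion (leaf C) and an R6 single-base
    deletion creating a premature stop (leaf E)."""
    import dataclasses

    params = dataclasses.replace(
        default_params, insertion_lineage="C", pseudogene_lineage="E"
    )
    anc, truth0 = synthdata.generate_ancestor(params, seed=7)
    seqs, truth = synthdata.evolve_family(anc, truth0, params, seed=11)
    return seqs, truth


@pytest.fixture(scope="session")
def small_params(default_params):
    """Quarter-scale family parameters for repeated simulations."""
    return default_params.scaled(0.3)


@pytest.fixture(scope="session")
def small_family(small_params):
    anc, truth0 = synthdata.generate_ancestor(small_params, seed=3)
    seqs, truth = synthdata.evolve_family(anc, truth0, small_params, seed=5)
    return seqs, truth
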