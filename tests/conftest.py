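from types import SimpleNamespace

import pytest

import v3cseq as v


@pytest.fixture(scope="session")
def synth():
    """Standard synthetic study conditions shared across tests.

    Toy host genome (4 x 800 kb, GC 0.41), its HindIII fragment library
    (~1,000 fragments), and an interaction truth of 10 planted fragments at
    20-fold enrichment over a background weight of 5.
    """
    cfg = v.default_genome_config(seed=1)
    genome = v.simulate_genome(cfg)
    library = v.digest(genome, "HindIII")
    planted = v.choose_planted_fragments(library, 10, seed=1)
    truth = v.InteractionTruth(planted, 20.0, 5.0)
    return SimpleNamespace(
        cfg=cfg, genome=genome, library=library, planted=planted, truth=truth
    )


@pytest.fixture(scope="session")
def klf4_pwm():
    return v.klf4_pwm()
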