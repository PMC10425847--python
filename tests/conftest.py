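import numpy as np
import pytest

import ciliaprofile as cp

SMALL_N_SPECIES = {
    "opisthokonta": 6,
    "amoebozoa": 3,
    "archaeplastida": 5,
    "rhizaria": 2,
    "alveolata": 4,
    "stramenopila": 4,
    "discicristata": 3,
    "cryptophyta_haptophyta": 3,
    "prokaryote": 3,
}


def small_sim_config(rng_seed: int = 7, **overrides) -> cp.SimulationConfig:
    """A 33-genome, noise-free simulation small enough for exact assertions."""
    kwargs = dict(
        rng_seed=rng_seed,
        n_species=dict(SMALL_N_SPECIES),
        n_background_genes=40,
        module_specs=(cp.ModuleSpec("cil", 12, "cilia"),),
        n_cilium_losses=3,
        n_motility_only_losses=0,
        background_loss_prob=0.02,
        false_negative_rate=0.0,
        false_positive_rate=0.0,
    )
    kwargs.update(overrides)
    return cp.SimulationConfig(**kwargs)


@pytest.fixture
def small_sim():
    return cp.simulate(small_sim_config())


@pytest.fixture
def toy_annotations():
    """12 species: 8 ciliated (2 with immotile cilia), 2 nonciliated
    eukaryotes, 2 prokaryote outgroups."""

    def ann(i, group, cil, mot):
        return cp.SpeciesAnnotation(
            species_id=f"sp{i:02d}", major_group=group,
            is_ciliated=cil, has_motile_cilia=mot,
        )

    return [
        ann(0, "opisthokonta", True, True),
        ann(1, "opisthokonta", True, True),
        ann(2, "opisthokonta", True, False),   # nematode-like
        ann(3, "opisthokonta", True, False),   # tick-like
        ann(4, "archaeplastida", True, True),
        ann(5, "archaeplastida", False, False),
        ann(6, "alveolata", True, True),
        ann(7, "stramenopila", True, True),
        ann(8, "stramenopila", True, True),
        ann(9, "amoebozoa", False, False),
        ann(10, "prokaryote", False, False),
        ann(11, "prokaryote", False, False),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
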