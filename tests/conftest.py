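import numpy as np
import pytest

from superpan.simulate import SV_TYPES, CladeConfig, evolve_clade, simulate_ancestor


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture(scope="session")
def small_clade():
    """8 genomes with gain/loss but no SVs: pangenome ground truth."""
    cfg = CladeConfig(
        n_genomes=8, genome_length=80_000, n_genes=30,
        substitution_rate_per_branch=0.001, family_loss_prob=0.08,
        family_gain_rate=1.0, seed=7,
    )
    ancestor = simulate_ancestor(cfg)
    genomes, truth = evolve_clade(ancestor, cfg)
    return cfg, ancestor, genomes, truth


@pytest.fixture(scope="session")
def sv_clade():
    """2 genomes with implanted SVs of all five types, no gain/loss,
    so truth coordinates live on the ancestor frame."""
    cfg = CladeConfig(
        n_genomes=2, genome_length=200_000, n_genes=30,
        substitution_rate_per_branch=0.005, family_loss_prob=0.0,
        family_gain_rate=0.0,
        sv_counts_per_branch={t: 2 for t in SV_TYPES},
        sv_size_ranges={t: (150, 3000) for t in SV_TYPES},
        seed=11,
    )
    ancestor = simulate_ancestor(cfg)
    genomes, truth = evolve_clade(ancestor, cfg)
    return cfg, ancestor, genomes, truth
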