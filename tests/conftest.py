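import pytest

from melanet import synth


@pytest.fixture(scope="session")
def small_interactome():
    """Planted interactome small enough for brute-force cross-checks."""
    cfg = synth.InteractomeConfig(
        rng_seed=7,
        n_seeds=40,
        n_core_seeds=20,
        n_satellite_seeds=6,
        n_pendant_pairs=2,
        n_true_bridges=25,
        n_decoy_nonbridges=8,
        n_low_confidence=20,
        n_low_quality=6,
        n_ubiquitin_decoys=3,
        n_flagged=4,
    )
    return synth.gen_interactome(cfg)


@pytest.fixture(scope="session")
def small_expression():
    cfg = synth.ExpressionConfig(
        rng_seed=3,
        n_genes=2000,
        planted=((1.0, 40), (2.5, 30), (-2.5, 30), (3.5, 15), (4.5, 10)),
    )
    return synth.gen_expression(cfg)


@pytest.fixture(scope="session")
def snp_fixture():
    return synth.gen_snp_fixture(synth.SnpConfig())
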