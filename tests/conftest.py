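"""Shared fixtures: small synthetic runs generated at test time."""

import pytest

from mhcamp.simulate import SimConfig, simulate_run


@pytest.fixture(scope="session")
def clean_run():
    """Error-free run: no substitutions, chimeras, indels or tag errors."""
    cfg = SimConfig(
        seed=101,
        n_individuals=6,
        replicate_fraction=0.5,
        coverage_mean=800,
        coverage_sd=100,
        substitution_rate=0.0,
        chimera_fraction=0.0,
        homopolymer_indel_rate=0.0,
        tag_corruption_rate=0.0,
        skew_sigma=0.0,
    )
    return simulate_run(cfg)


@pytest.fixture(scope="session")
def stress_run():
    """40 amplicons at coverage ~500 with 5% chimeric reads: the stress
    conditions used for end-to-end recall and chimera-flagging checks."""
    cfg = SimConfig(
        seed=3,
        n_individuals=32,
        replicate_fraction=0.25,
        coverage_mean=500,
        coverage_sd=100,
    )
    return simulate_run(cfg)


@pytest.fixture(scope="session")
def noisy_run():
    """Run under the default study conditions at reduced scale."""
    cfg = SimConfig(
        seed=202,
        n_individuals=12,
        replicate_fraction=0.5,
        coverage_mean=400,
        coverage_sd=80,
    )
    return simulate_run(cfg)
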