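import pytest
from hypothesis import HealthCheck, settings

from repeatscape.simulate import (
    DiagnosticMotifSpec,
    LtrFamilySpec,
    ReadSimSpec,
    SatFamilySpec,
    SimConfig,
    SubgenomeSpec,
    TelomereSpec,
)

settings.register_profile(
    "fixed", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("fixed")


def small_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """One triad of short chromosomes; fast enough for unit tests."""
    kwargs = dict(
        seed=seed,
        subgenomes=[
            SubgenomeSpec("B", 1, 150_000),
            SubgenomeSpec("C", 1, 120_000),
            SubgenomeSpec("D", 1, 100_000),
        ],
        ltr_families=[
            LtrFamilySpec(
                name="gypsy1", superfamily="Gypsy", consensus_length=1000,
                copies_per_chromosome={"B": 6, "C": 2, "D": 2},
                divergence_mean={"B": 0.07, "C": 0.18, "D": 0.22},
                divergence_sd={"B": 0.01, "C": 0.03, "D": 0.03},
            ),
        ],
        sat_families=[
            SatFamilySpec("satA", 20, {"B": 1, "C": 1, "D": 1}, 60),
            SatFamilySpec("satB", 57, {"B": 1, "C": 1, "D": 1}, 40),
        ],
        diagnostic_motif=DiagnosticMotifSpec(),
        telomere=TelomereSpec(),
        gene_density_per_mb=10.0,
        read_sim=ReadSimSpec(read_length=5000, n_reads=100),
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture
def small_sim():
    return small_sim_config()


@pytest.fixture
def small_genome():
    from repeatscape.simulate import build_genome

    cfg = small_sim_config()
    assembly, truth = build_genome(cfg)
    return cfg, assembly, truth
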