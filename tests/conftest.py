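"""Shared fixtures: one medium synthetic cohort reused across test modules."""

import pytest

from twinewas.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    """Study-condition cohort (33 MZ / 43 DZ / 20 singletons) with a
    moderate probe panel, two lymphocyte-coupled probes and two probes
    coupled into LDL for discordance-style checks."""
    return SimulationConfig(
        n_probes=250,
        seed=5,
        lymph_probes=(3, 4),
        lymph_coupling=0.3,
        couple_trait="LDL",
        couple_probes=(10, 11),
        couple_strength=1.2,
    )


@pytest.fixture(scope="session")
def bundle(default_cfg):
    return simulate_dataset(default_cfg)


@pytest.fixture(scope="session")
def age_rich_bundle():
    """Panel dominated by age-class probes, for direction/enrichment checks."""
    cfg = SimulationConfig(
        n_probes=400,
        frac_heritable=0.0,
        frac_meqtl=0.0,
        frac_age=0.75,
        seed=23,
    )
    return simulate_dataset(cfg)
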