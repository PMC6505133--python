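import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_karyotype():
    """Two ancestral chromosomes, one paracentric + one pericentric inversion
    and one fission in the grayling-like lineage, one fusion in the
    salmon-like lineage."""
    from salmokit.simulate import SimulationConfig, simulate_karyotype

    cfg = SimulationConfig(
        seed=42,
        n_ancestral_chromosomes=2,
        chromosome_length_bp=20_000_000,
        inversion_events=[
            ("1A", 4_000_000, 9_000_000, False),
            ("2A", 1_000_000, 5_000_000, True),
        ],
        fission_events=[("2B", 8_000_000)],
        fusion_events=[("1B", "2B")],
    )
    return simulate_karyotype(cfg)


@pytest.fixture(scope="session")
def small_family():
    """A 113-offspring family on an unrearranged two-chromosome genome with
    planted bad markers and four planted low-coverage offspring."""
    from salmokit.simulate import (SimulationConfig, simulate_karyotype,
                                   simulate_rad_family)

    cfg = SimulationConfig(seed=7, n_ancestral_chromosomes=1,
                           chromosome_length_bp=20_000_000,
                           markers_per_chromosome=600)
    sim = simulate_karyotype(cfg)
    return simulate_rad_family(sim.grayling, cfg, n_bad_offspring=4)
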