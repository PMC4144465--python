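import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mendelqc import (
    SimulationConfig,
    count_mies,
    extract_nuclear_families,
    simulate,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# Cheap scenario for structural tests: 12 trios, 4,000 variants on 2 Mb.
SMALL_CONFIG = dict(
    seed=11,
    n_families=12,
    n_variants=4_000,
    chrom_length=2_000_000,
    n_repeat_intervals=120,
    peak_width=60_000,
    repeat_density_blocks=10,
)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(SimulationConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def default_sim():
    """The generator's standard scenario (defaults, seed 0)."""
    return simulate(SimulationConfig(seed=0))


def _engine_bundle(sim):
    families = extract_nuclear_families(sim.pedigree)
    binary_idx = np.array(
        [i for i, v in enumerate(sim.variants) if v.is_binary]
    )
    binary = [sim.variants[i] for i in binary_idx]
    table = count_mies(binary, families)
    return {
        "sim": sim,
        "families": families,
        "binary": binary,
        "binary_idx": binary_idx,
        "mie": table,
        "truth_binary": sim.truth.iloc[binary_idx].reset_index(drop=True),
    }


@pytest.fixture(scope="session")
def small_bundle(small_sim):
    return _engine_bundle(small_sim)


@pytest.fixture(scope="session")
def default_bundle(default_sim):
    return _engine_bundle(default_sim)


@pytest.fixture(scope="session")
def sim_files(tmp_path_factory, small_sim):
    """The small scenario written out as VCF/PED/BED/truth files."""
    prefix = tmp_path_factory.mktemp("simdata") / "sim"
    return small_sim.write(prefix)
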