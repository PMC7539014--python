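import numpy as np
import pytest

from clonetrace import (
    ReadSimConfig,
    StageSpec,
    evolve_stage,
    generate_reads,
    initialize_population,
    make_library,
)


@pytest.fixture(scope="session")
def small_library():
    """20x20 module library at pairwise distance >= 5 (400 composite barcodes)."""
    return make_library(20, 20, min_pairwise_distance=5, seed=11)


@pytest.fixture(scope="session")
def small_population(small_library):
    """50 clones of ~200 cells with mild skew."""
    return initialize_population(small_library, n_clones=50, cells_per_clone=200,
                                 evenness=0.98, seed=12)


@pytest.fixture(scope="session")
def selected_population(small_population):
    """The small population after a selective primary-like stage."""
    stage = StageSpec("primary", bottleneck_size=4000, growth_generations=6,
                      fitness_scale=0.3)
    return evolve_stage(small_population, stage, seed=13)


@pytest.fixture()
def fastq_factory(small_library, tmp_path):
    """Write a simulated FASTQ for a population; returns (path, truth_df)."""

    def _make(pop, n_reads=2000, substitution_rate=0.0, fraction_low_quality=0.0,
              seed=0, name="reads.fastq"):
        cfg = ReadSimConfig(n_reads=n_reads, substitution_rate=substitution_rate,
                            fraction_low_quality=fraction_low_quality, seed=seed)
        path = tmp_path / name
        truth = generate_reads(pop, small_library, cfg, str(path))
        return str(path), truth

    return _make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
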