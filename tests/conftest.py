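import numpy as np
import pytest

from srnakit.reads import clean_reads, collapse_unique
from srnakit.simulate import SimulationConfig, generate_references, simulate_libraries


@pytest.fixture(scope="session")
def small_sim():
    """A 20-hairpin, 2 x 5000-read simulation with default isomiR rates."""
    cfg = SimulationConfig(n_hairpins=20, reads_per_library=5000, seed=11)
    refs = generate_references(cfg)
    reads_a, reads_b, truth = simulate_libraries(cfg, refs)
    return cfg, refs, reads_a, reads_b, truth


@pytest.fixture(scope="session")
def small_sim_tags(small_sim):
    cfg, refs, reads_a, reads_b, truth = small_sim
    inserts_a, summary_a = clean_reads(reads_a, cfg.adapter3)
    inserts_b, summary_b = clean_reads(reads_b, cfg.adapter3)
    return {
        "tags_a": collapse_unique(inserts_a),
        "tags_b": collapse_unique(inserts_b),
        "summary_a": summary_a,
        "summary_b": summary_b,
    }


@pytest.fixture(scope="session")
def pristine_sim():
    """All perturbations off: every read is a mature sequence + adapter."""
    cfg = SimulationConfig(
        n_hairpins=15,
        reads_per_library=4000,
        seed=23,
        frac_contaminant={},
        isomir_rates={k: 0.0 for k in ("trim5", "trim3", "ext3_templated", "nta3", "seed_substitution")},
        low_quality_fraction=0.0,
    )
    refs = generate_references(cfg)
    reads_a, reads_b, truth = simulate_libraries(cfg, refs)
    return cfg, refs, reads_a, reads_b, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
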