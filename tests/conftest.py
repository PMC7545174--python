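import numpy as np
import pytest

import fibmech as fm


@pytest.fixture(scope="session")
def benchmark_run():
    """Quasi-static harmonic benchmark ensemble with its analytic reference."""
    potential, steer, cfg = fm.synthetic.harmonic_benchmark(seed=1, n_replicates=100)
    ensemble = fm.generate_work_ensemble(potential, steer, cfg, strain_reference=10.0)
    reference = fm.analytic_pmf(potential, steer, strain_reference=10.0)
    return {
        "potential": potential,
        "steer": steer,
        "cfg": cfg,
        "ensemble": ensemble,
        "reference": reference,
    }


@pytest.fixture(scope="session")
def default_map():
    return fm.default_domain_map()


@pytest.fixture()
def all_hairpin_toy():
    """Toy structure whose eight contacts all sit on the strained hairpin."""
    return fm.build_toy_structure(n_contacts=8, n_hairpin=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
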