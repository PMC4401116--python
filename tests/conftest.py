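import numpy as np
import pytest

from duobar.calling import ReferenceDb
from duobar.pipeline import PipelineConfig, run_all
from duobar.simulate import SimConfig, simulate

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


@pytest.fixture(scope="session")
def clean_sim():
    """Small error-free run: no contamination, no chimeras, no endosymbionts."""
    cfg = SimConfig(
        n_plates=1, wells_per_plate=8, coverage=10,
        per_base_error=0.0, contaminant_frac=0.0, chimera_rate=0.0,
        endosymbiont_rate=0.0, n_references=12, seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def clean_result(clean_sim):
    return run_all(clean_sim.reads, clean_sim.mapping, clean_sim.primers,
                   PipelineConfig(),
                   reference_db=ReferenceDb(clean_sim.references))


@pytest.fixture(scope="session")
def noisy_sim():
    """One plate at study noise levels with all three artefact classes."""
    cfg = SimConfig(
        n_plates=1, wells_per_plate=24, coverage=50,
        per_base_error=0.001, contaminant_frac=0.25, chimera_rate=0.05,
        endosymbiont_rate=0.25, n_references=16, seed=7,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def noisy_result(noisy_sim):
    return run_all(noisy_sim.reads, noisy_sim.mapping, noisy_sim.primers,
                   PipelineConfig(),
                   reference_db=ReferenceDb(noisy_sim.references))
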