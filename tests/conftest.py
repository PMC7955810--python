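import numpy as np
import pytest

from hdxdyn.synth import (
    ExchangeModel,
    PerturbationSpec,
    SimulationConfig,
    generate_peptide_map,
    simulate_uptake,
)

AA_NO_PRO = list("ACDEFGHIKLMNQRSTVWY")


def random_sequence(n: int, seed: int, allow_proline: bool = False) -> str:
    rng = np.random.default_rng(seed)
    alphabet = AA_NO_PRO + (["P"] if allow_proline else [])
    return "".join(rng.choice(alphabet, size=n))


@pytest.fixture(scope="session")
def protein_sequence() -> str:
    return random_sequence(400, seed=0)


@pytest.fixture(scope="session")
def exchange_model(protein_sequence) -> ExchangeModel:
    return ExchangeModel.random(protein_sequence, seed=7)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def peptide_map(protein_sequence, sim_config):
    return generate_peptide_map(protein_sequence, sim_config)


@pytest.fixture(scope="session")
def perturbed_region(peptide_map):
    """A 15-residue region anchored on a mapped mid-protein peptide so that
    at least one peptide is fully contained in it."""
    pep = next(p for p in peptide_map if abs(p.start - 200) < 30 and p.length <= 15)
    return (pep.start, pep.start + 14)


@pytest.fixture(scope="session")
def two_state_dataset(exchange_model, peptide_map, sim_config, perturbed_region):
    spec = PerturbationSpec(*perturbed_region, pf_multiplier=0.1)
    return simulate_uptake(exchange_model, peptide_map, sim_config, perturbations=[spec])
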