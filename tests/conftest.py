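from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

import evostrain as es
from evostrain.fixtures import TOY_RATES

DATA = Path(__file__).parent / "data"

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def toy():
    """The default toy network and its wild-type FBA reference."""
    return es.make_toy_model()


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_reference(toy):
    return toy[1]


@pytest.fixture(scope="session")
def toy_space(toy_model):
    return es.build_target_space(toy_model)


@pytest.fixture(scope="session")
def merged_with_databank(toy_model):
    databank = es.make_databank(toy_model)
    return es.merge_databank(toy_model, databank)


@pytest.fixture(scope="session")
def toy_evaluator(toy, toy_space):
    """Session-scoped MiMBl/BPCY evaluator with a shared memo cache."""
    model, ref = toy
    spec = es.GenomeSpec.for_space(toy_space, ND=2)
    return es.FitnessEvaluator(model, toy_space, spec, TOY_RATES, reference=ref)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def l2_path():
    return DATA / "l2_toy.xml"


def make_evaluated(bits_list, fitnesses):
    """Individuals with pre-assigned fitness, for operator-level tests."""
    out = []
    for bits, f in zip(bits_list, fitnesses):
        ind = es.Individual(np.asarray(bits, dtype=np.uint8))
        ind.fitness = es.FitnessResult(F=f, F_hat=f, components={}, I=0)
        out.append(ind)
    return out
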